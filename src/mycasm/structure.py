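"""Alpha/beta diversity, ordination and host-factor attribution.

The attribution stack mirrors standard practice for microbiome surveys:
PERMANOVA with sequential (Type-I) sums of squares partitions the variance
of a distance matrix over an ordered factor list; Mantel, multiple
regression on distance matrices (MRM) and Procrustes/PROTEST provide
matrix-level confirmation that is robust to group-variance heterogeneity;
and a subsampled MRM design (one individual per host species, repeated)
checks that verdicts are not driven by unbalanced within-species
replication.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control, mannwhitneyu
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha as skbio_alpha
from skbio.diversity import beta_diversity as skbio_beta
from skbio.stats.ordination import pcoa as skbio_pcoa

from .core import CommunityTable, join_metadata

logger = logging.getLogger("mycasm")

ALPHA_INDICES = ("observed", "shannon", "simpson", "invsimpson")
BETA_METRICS = ("bray", "jaccard", "unifrac_unweighted", "unifrac_weighted")


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame          # samples x retained axes
    eigenvalues: np.ndarray            # retained (positive) eigenvalues, decreasing
    proportion_explained: np.ndarray
    negative_inertia_fraction: float   # |sum of dropped negative eigenvalues| / total |inertia|

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class MatrixRegressionResult:
    method: str
    coefficient: float          # MRM R^2, Mantel r, or Procrustes m^2
    p_value: float
    n_permutations: int
    details: pd.DataFrame | None = None


@dataclass
class PermutedMRMVerdict:
    factor: str
    metric: str
    coefficients: np.ndarray    # length n_perm_outer
    p_values: np.ndarray
    n_significant: int
    significant_overall: bool


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CommunityTable, indices=ALPHA_INDICES) -> pd.DataFrame:
    """Per-sample diversity indices (Shannon in natural log, Simpson = 1-D)."""
    unknown = set(indices) - set(ALPHA_INDICES)
    if unknown:
        raise ValueError(f"unknown alpha indices: {sorted(unknown)}")
    counts = table.counts
    out = {}
    for name in indices:
        vals = np.empty(counts.shape[0])
        for i, row in enumerate(counts):
            if row.sum() <= 0:
                warnings.warn(f"empty sample {table.sample_ids[i]!r}: alpha set to NaN",
                              stacklevel=2)
                vals[i] = np.nan
                continue
            if name == "observed":
                vals[i] = skbio_alpha.sobs(row)
            elif name == "shannon":
                vals[i] = skbio_alpha.shannon(row, base=np.e)
            elif name == "simpson":
                vals[i] = skbio_alpha.simpson(row)
            elif name == "invsimpson":
                vals[i] = skbio_alpha.enspie(row)
        out[name] = vals
    return pd.DataFrame(out, index=table.sample_ids)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def beta_diversity(
    table: CommunityTable, metric: str, tree: TreeNode | None = None
) -> DistanceMatrix:
    """Pairwise dissimilarity under one of the four supported metrics."""
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    if metric == "bray":
        rel = table.relative_abundance().to_numpy()
        return DistanceMatrix(squareform(pdist(rel, "braycurtis"), checks=False),
                              ids=table.sample_ids)
    if metric == "jaccard":
        inc = table.counts > 0
        return DistanceMatrix(squareform(pdist(inc, "jaccard"), checks=False),
                              ids=table.sample_ids)
    if tree is None:
        raise ValueError(f"{metric} requires a phylogeny")
    tip_names = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tip_names]
    if missing:
        raise ValueError(f"taxa absent from the phylogeny: {missing}")
    kind = "unweighted_unifrac" if metric == "unifrac_unweighted" else "weighted_unifrac"
    kwargs = {"normalized": True} if kind == "weighted_unifrac" else {}
    return skbio_beta(
        kind,
        table.counts,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        validate=True,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates (Gower centering + eigendecomposition).

    Negative eigenvalues (non-Euclidean input) are truncated; the fraction of
    negative inertia is reported so callers can judge the distortion.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = skbio_pcoa(dist, method="eigh")
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    pos = eig > max(eig.max(), 0) * 1e-12
    neg_frac = float(np.abs(eig[eig < 0]).sum() / max(np.abs(eig).sum(), 1e-300))
    eig_pos = eig[pos]
    order = np.argsort(eig_pos)[::-1]
    coords = coords[:, pos][:, order]
    eig_pos = eig_pos[order]
    prop = eig_pos / eig_pos.sum() if eig_pos.size else eig_pos
    if neg_frac > 0:
        logger.info("PCoA dropped %.2f%% negative inertia", 100 * neg_frac)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=list(dist.ids),
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eig_pos,
        proportion_explained=prop,
        negative_inertia_fraction=neg_frac,
    )


# ---------------------------------------------------------------------------
# PERMANOVA (sequential SS)
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()

def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    dist: DistanceMatrix,
    meta: pd.DataFrame,
    factors: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA over an ordered factor list.

    Sums of squares follow the hat-matrix formulation on the Gower-centered
    matrix; each factor's SS is the increment over the preceding model, so
    factor order matters for nested designs. p-values come from free
    permutation of sample labels, computed as (b + 1) / (m + 1).
    """
    ids = list(dist.ids)
    sub = meta.loc[ids, factors]
    if sub.isna().any().any():
        keep = sub.dropna().index.tolist()
        logger.info("permanova: %d samples dropped for missing factor values", len(ids) - len(keep))
        dist = dist.filter(keep)
        ids = keep
        sub = sub.loc[keep]
    n = len(ids)
    for f in factors:
        if sub[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    g = _gower_center(dist.data)
    ss_total = float(np.trace(g))

    designs = [np.ones((n, 1))]
    for k in range(len(factors)):
        dummies = pd.get_dummies(sub[factors[: k + 1]], drop_first=False).to_numpy(float)
        designs.append(np.column_stack([np.ones(n), dummies]))
    hats = [_hat(x) for x in designs]
    ranks = [np.linalg.matrix_rank(x) for x in designs]

    def _ss_terms(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([float(np.sum(h * gmat)) for h in hats])
        ss = np.diff(traces)
        ss_res = float(np.trace(gmat)) - traces[-1]
        return ss, ss_res

    ss_obs, ss_res_obs = _ss_terms(g)
    dfs = np.diff(ranks)
    df_res = n - ranks[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_obs / np.where(dfs > 0, dfs, np.nan)) / (ss_res_obs / df_res)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9E8)))
    exceed = np.zeros(len(factors))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = _ss_terms(gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_p / np.where(dfs > 0, dfs, np.nan)) / (ss_res_p / df_res)
        exceed += np.where(np.isnan(f_obs), 0, f_p >= f_obs - 1e-12)
    p = (exceed + 1) / (n_perm + 1)

    rows = []
    for i, f in enumerate(factors):
        rows.append(
            {
                "factor": f,
                "ss": ss_obs[i],
                "df": int(dfs[i]),
                "pseudo_F": float(f_obs[i]) if np.isfinite(f_obs[i]) else np.nan,
                "r_squared": ss_obs[i] / ss_total,
                "p_value": float(p[i]) if dfs[i] > 0 else np.nan,
            }
        )
    rows.append(
        {
            "factor": "Residual",
            "ss": ss_res_obs,
            "df": int(df_res),
            "pseudo_F": np.nan,
            "r_squared": ss_res_obs / ss_total,
            "p_value": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("factor")


# ---------------------------------------------------------------------------
# Mantel / MRM / Procrustes
# ---------------------------------------------------------------------------

def _matched_condensed(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, list]:
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different samples")
    ids = list(d1.ids)
    d2 = d2.filter(ids)
    return d1.condensed_form(), d2.condensed_form(), ids


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> MatrixRegressionResult:
    """Pearson correlation of distance triangles; p by matrix permutation."""
    x, y, ids = _matched_condensed(d1, d2)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a distance triangle")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    n = len(ids)
    sq2 = squareform(y, checks=False)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x317)))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(sq2[np.ix_(perm, perm)], checks=False)
        if abs(np.corrcoef(x, yp)[0, 1]) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MatrixRegressionResult("mantel", r_obs, p, n_perm)


def factor_dissimilarity(meta: pd.DataFrame, column: str, ids=None) -> DistanceMatrix:
    """0/1 dissimilarity: 1 when two samples differ in a categorical level."""
    values = meta[column] if ids is None else meta.loc[list(ids), column]
    arr = values.to_numpy()
    d = (arr[:, None] != arr[None, :]).astype(float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(values.index))


def expand_species_distance(species_dm: DistanceMatrix, species_of: pd.Series) -> DistanceMatrix:
    """Sample-level matrix whose entries are distances between host species."""
    ids = list(species_of.index)
    sp = species_of.to_numpy()
    lookup = {s: i for i, s in enumerate(species_dm.ids)}
    idx = np.array([lookup[s] for s in sp])
    d = species_dm.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=ids)


def mrm_fit(
    response: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
) -> MatrixRegressionResult:
    """Multiple regression on distance matrices with permutation inference.

    OLS of the response triangle on predictor triangles. The response matrix
    rows/columns are permuted jointly; per-coefficient p-values use the
    pseudo-t method (fraction of permuted |t| >= observed |t|), the model
    p-value the permuted R^2 distribution.
    """
    names = list(predictors)
    y = response.condensed_form()
    cols = []
    for name in names:
        _, xc, _ = _matched_condensed(response, predictors[name])
        cols.append(xc)
    x = np.column_stack([np.ones_like(y)] + cols)
    if np.linalg.cond(x.T @ x) > 1e10:
        raise ValueError("collinear predictor matrices")

    def _fit(yvec):
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ yvec)
        resid = yvec - x @ beta
        dof = len(yvec) - x.shape[1]
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(np.diag(xtx_inv) * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        sst = float(((yvec - yvec.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
        return beta, t, r2

    beta_obs, t_obs, r2_obs = _fit(y)
    n = len(response.ids)
    sq = squareform(y, checks=False)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x3A3)))
    t_exceed = np.zeros(x.shape[1])
    r2_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(sq[np.ix_(perm, perm)], checks=False)
        _, t_p, r2_p = _fit(yp)
        t_exceed += np.abs(t_p) >= np.abs(t_obs) - 1e-12
        r2_exceed += r2_p >= r2_obs - 1e-12
    p_coef = (t_exceed + 1) / (n_perm + 1)
    p_model = (r2_exceed + 1) / (n_perm + 1)
    details = pd.DataFrame(
        {"coefficient": beta_obs, "t": t_obs, "p_value": p_coef},
        index=["intercept"] + names,
    )
    return MatrixRegressionResult("mrm", float(r2_obs), float(p_model), n_perm, details)


def _procrustes_m2(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Procrustes m^2 (translation, scaling, rotation, reflection)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.sqrt((a**2).sum())
    nb = np.sqrt((b**2).sum())
    if na == 0 or nb == 0:
        raise ValueError("degenerate (rank-0) configuration")
    a, b = a / na, b / nb
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(max(1.0 - s.sum() ** 2, 0.0))


def procrustes_protest(
    ord1: OrdinationResult | np.ndarray,
    ord2: OrdinationResult | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> MatrixRegressionResult:
    """PROTEST: Procrustes m^2 with row-permutation significance."""
    a = ord1.coordinates.to_numpy() if isinstance(ord1, OrdinationResult) else np.asarray(ord1, float)
    b = ord2.coordinates.to_numpy() if isinstance(ord2, OrdinationResult) else np.asarray(ord2, float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("configurations must cover the same samples")
    k = min(a.shape[1], b.shape[1])
    a, b = a[:, :k], b[:, :k]
    m2_obs = _procrustes_m2(a, b)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x960)))
    count = 0
    for _ in range(n_perm):
        if _procrustes_m2(a, b[rng.permutation(b.shape[0])]) <= m2_obs + 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MatrixRegressionResult("protest", m2_obs, p, n_perm)


# ---------------------------------------------------------------------------
# permuted one-individual-per-species MRM
# ---------------------------------------------------------------------------

def permuted_mrm(
    table: CommunityTable,
    meta: pd.DataFrame,
    metrics=("bray",),
    factors=("species", "family", "gut_type", "domestication"),
    tree: TreeNode | None = None,
    host_tree_distance: DistanceMatrix | None = None,
    n_perm_outer: int = 100,
    n_perm_inner: int = 199,
    p_threshold: float = 0.05,
    min_significant: int = 75,
    seed: int = 0,
) -> dict[tuple[str, str], PermutedMRMVerdict]:
    """Repeatedly subsample one individual per species and re-run MRM.

    Each of ``n_perm_outer`` rounds draws one sample per host species,
    recomputes each community distance matrix and regresses it on each host
    factor separately. A factor is significant overall for a metric when its
    p-value clears ``p_threshold`` in at least ``min_significant`` rounds.

    With one individual per species, the 0/1 "same species" predictor is
    constant, so when ``host_tree_distance`` (patristic distances between
    species) is supplied the ``species`` factor uses it instead — the
    phylosymbiosis reading of host-species distance.
    """
    meta = join_metadata(table, meta)
    species_groups = meta.groupby("species").groups
    if len(species_groups) < 2:
        raise ValueError("need at least 2 host species")
    empty = [sp for sp, idx in species_groups.items() if len(idx) == 0]
    if empty:
        raise ValueError(f"species with zero samples: {empty}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xAB)))
    records: dict[tuple[str, str], list[tuple[float, float]]] = {
        (f, m): [] for f in factors for m in metrics
    }
    for _ in range(n_perm_outer):
        chosen = [str(rng.choice(list(idx))) for idx in species_groups.values()]
        sub_table = table.subset(sample_ids=chosen).drop_empty_taxa()
        sub_meta = meta.loc[chosen]
        for metric in metrics:
            resp = beta_diversity(sub_table, metric, tree=tree)
            for factor in factors:
                if factor == "species" and host_tree_distance is not None:
                    pred = expand_species_distance(host_tree_distance, sub_meta["species"])
                else:
                    pred = factor_dissimilarity(sub_meta, factor)
                if pred.condensed_form().std() == 0:
                    records[(factor, metric)].append((np.nan, np.nan))
                    continue
                res = mrm_fit(resp, {factor: pred}, n_perm=n_perm_inner,
                              seed=int(rng.integers(2**31 - 1)))
                records[(factor, metric)].append((res.coefficient, res.p_value))
    out = {}
    for (factor, metric), vals in records.items():
        coefs = np.array([v[0] for v in vals])
        ps = np.array([v[1] for v in vals])
        n_sig = int(np.nansum(ps < p_threshold))
        out[(factor, metric)] = PermutedMRMVerdict(
            factor=factor,
            metric=metric,
            coefficients=coefs,
            p_values=ps,
            n_significant=n_sig,
            significant_overall=n_sig >= min_significant,
        )
    return out


# ---------------------------------------------------------------------------
# grouped rank-sum comparisons
# ---------------------------------------------------------------------------

def group_rank_sum(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """All pairwise two-sided rank-sum tests between groups, BH-adjusted."""
    levels = sorted(groups.dropna().unique())
    rows = []
    for i, ga in enumerate(levels):
        for gb in levels[i + 1:]:
            va = values[groups == ga].dropna()
            vb = values[groups == gb].dropna()
            if len(va) == 0 or len(vb) == 0:
                continue
            stat, p = mannwhitneyu(va, vb, alternative="two-sided")
            rows.append({"group_a": ga, "group_b": gb, "statistic": float(stat),
                         "p_value": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = false_discovery_control(df["p_value"], method="bh")
    return df
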