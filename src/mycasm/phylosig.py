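"""Cophylogenetic inference: PACo, global phylogenetic signal and LIPA.

PACo (Procrustes Application to Cophylogenetic analysis) embeds host and
symbiont distance matrices by principal coordinates, duplicates rows per
host-symbiont association link and superimposes the symbiont configuration
onto the host configuration by least squares; small residuals mean the
symbiont community tracks the host phylogeny. Global per-genus signal uses
Abouheif's Cmean, Moran's I (inverse-patristic weights) and Pagel's lambda,
and LIPA (a per-tip local Moran statistic) localizes which host tips carry
the association, with the conventional strength bands (0.2-0.4 weak,
0.4-1 moderate, >= 1 strong).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, false_discovery_control
from skbio import DistanceMatrix, TreeNode

from .core import CommunityTable, attach_individuals, join_metadata, patristic_distances, tree_height
from .structure import expand_species_distance, pcoa

logger = logging.getLogger("mycasm")


@dataclass
class PACoResult:
    link_residuals: pd.DataFrame      # columns: host, symbiont, residual (squared)
    per_sample_residual: pd.Series    # mean residual per host
    m2: float                         # global sum of squared residuals
    p_value: float                    # NaN when n_perm == 0
    n_permutations: int
    # per-host residual z-scored against its permutation-null mean and sd;
    # raw PACo residuals carry geometric host-position components (offset
    # and spread) that this standardization removes
    per_sample_residual_centered: pd.Series | None = None


@dataclass
class SignalResult:
    genus: str
    cmean: float
    moran_i: float
    pagel_lambda: float
    p_values: dict[str, float]


@dataclass
class PACoSubsampleResult:
    residuals: pd.DataFrame           # subsample, sample_id, species, family, gut_type, residual
    comparisons: pd.DataFrame         # grouping-level within/between rank-sum tests
    n_failed: int


# ---------------------------------------------------------------------------
# PACo
# ---------------------------------------------------------------------------

def _paco_embedding(dist: DistanceMatrix, inertia: float = 0.999) -> tuple[np.ndarray, list]:
    ord_res = pcoa(dist)
    cum = np.cumsum(ord_res.proportion_explained)
    k = int(np.searchsorted(cum, inertia) + 1)
    return ord_res.coordinates.to_numpy()[:, :k], list(ord_res.sample_ids)


def _superimpose_residuals(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted squared per-row residuals after LS superimposition of y onto x.

    Minimizes sum_l w_l ||x_l - s (y_l @ R) - t||^2 over translation t,
    scale s and rotation R; returns w_l * ||residual_l||^2 per link.
    """
    wt = w / w.sum()
    xc = x - (x * wt[:, None]).sum(axis=0)
    yc = y - (y * wt[:, None]).sum(axis=0)
    sw = np.sqrt(wt)[:, None]
    xs, ys = xc * sw, yc * sw
    ynorm = (ys**2).sum()
    if ynorm <= 0 or (xs**2).sum() <= 0:
        raise ValueError("degenerate configuration: all links identical")
    u, s, vt = np.linalg.svd(ys.T @ xs)
    rot = u @ vt
    scale = s.sum() / ynorm
    return ((xs - scale * (ys @ rot)) ** 2).sum(axis=1)


def paco_fit(
    host_dist: DistanceMatrix,
    symbiont_dist: DistanceMatrix,
    association: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    center_residuals: int = 0,
) -> PACoResult:
    """Procrustes cophylogeny over an association matrix (hosts x symbionts).

    Nonzero association entries define the links and act as link weights: a
    0/1 matrix gives classic unweighted PACo, while passing abundances
    weights each link's residual by its abundance (useful when presence is
    near-saturated and only abundance carries host information). The
    permutation null shuffles which host each row of links belongs to (host
    rows of the association matrix), preserving the link count; the p-value
    is the fraction of permuted global residual sums at or below the
    observed one.
    """
    assoc = association.copy()
    keep_h = assoc.index[(assoc > 0).any(axis=1)]
    keep_s = assoc.columns[(assoc > 0).any(axis=0)]
    if len(keep_h) < len(assoc.index) or len(keep_s) < len(assoc.columns):
        warnings.warn("hosts/symbionts without links dropped from PACo", stacklevel=2)
    assoc = assoc.loc[keep_h, keep_s]
    if assoc.shape[0] < 3 or assoc.shape[1] < 2:
        raise ValueError("association matrix too small for PACo")
    hcoords, hids = _paco_embedding(host_dist.filter(list(assoc.index)))
    scoords, sids = _paco_embedding(symbiont_dist.filter(list(assoc.columns)))
    k = max(hcoords.shape[1], scoords.shape[1])
    hcoords = np.pad(hcoords, ((0, 0), (0, k - hcoords.shape[1])))
    scoords = np.pad(scoords, ((0, 0), (0, k - scoords.shape[1])))
    hindex = {h: i for i, h in enumerate(hids)}
    sindex = {s: i for i, s in enumerate(sids)}

    amat = assoc.to_numpy()
    hi, si = np.nonzero(amat > 0)
    hrows = np.array([hindex[assoc.index[i]] for i in hi])
    srows = np.array([sindex[assoc.columns[j]] for j in si])
    link_w = amat[hi, si].astype(float)
    resid = _superimpose_residuals(hcoords[hrows], scoords[srows], link_w)
    m2_obs = float(resid.sum())

    p = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9AC0)))
        n_host = len(hids)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_host)
            r = _superimpose_residuals(hcoords[perm[hrows]], scoords[srows], link_w)
            if r.sum() <= m2_obs + 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)

    links = pd.DataFrame(
        {
            "host": [assoc.index[i] for i in hi],
            "symbiont": [assoc.columns[j] for j in si],
            "residual": resid,
        }
    )
    per_sample = links.groupby("host")["residual"].mean()

    centered = None
    if center_residuals > 0:
        # host-wise null calibration: per permutation, each host coordinate
        # carries the link set of one random host; grouping permuted link
        # residuals by coordinate owner yields the null distribution of the
        # host's mean residual. Both its mean (geometric offset) and sd
        # (position-dependent spread) are divided out.
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCE47)))
        null_means = np.full((center_residuals, len(hids)), np.nan)
        for b in range(center_residuals):
            perm = rng.permutation(len(hids))
            owners = perm[hrows]
            r = _superimpose_residuals(hcoords[owners], scoords[srows], link_w)
            tot = np.zeros(len(hids))
            cnt = np.zeros(len(hids))
            np.add.at(tot, owners, r)
            np.add.at(cnt, owners, 1.0)
            null_means[b] = np.divide(tot, cnt, out=np.full(len(hids), np.nan),
                                      where=cnt > 0)
        mu = pd.Series(np.nanmean(null_means, axis=0), index=hids)
        sd = pd.Series(np.nanstd(null_means, axis=0, ddof=1), index=hids)
        sd = sd.where(sd > 0, other=sd[sd > 0].median() if (sd > 0).any() else 1.0)
        centered = (per_sample - mu.reindex(per_sample.index)) / sd.reindex(per_sample.index)
    return PACoResult(links, per_sample, m2_obs, p, n_perm, centered)


def paco_subsample(
    table: CommunityTable,
    meta: pd.DataFrame,
    host_tree: TreeNode,
    symbiont_tree: TreeNode,
    n_subsamples: int = 100,
    seed: int = 0,
) -> PACoSubsampleResult:
    """PACo residual distributions under one-individual-per-species subsampling.

    Each subsample runs PACo on presence/absence links between the chosen
    samples and the genera they carry (host side: species patristic
    distances). Per-sample residuals are pooled; for each grouping level
    (species, family, gut type) the absolute residual differences of sample
    pairs within vs between groups are compared by a two-sided rank-sum test
    with BH adjustment across levels.
    """
    meta = join_metadata(table, meta)
    if meta["species"].nunique() < 2:
        raise ValueError("need at least 2 host species")
    host_dm = patristic_distances(host_tree)
    sym_dm = patristic_distances(symbiont_tree)
    species_groups = meta.groupby("species").groups
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5AB5)))
    records = []
    n_failed = 0
    for b in range(n_subsamples):
        chosen = [str(rng.choice(list(idx))) for idx in species_groups.values()]
        sub = table.subset(sample_ids=chosen).drop_empty_taxa()
        assoc = sub.relative_abundance()  # abundance-weighted links
        sp_of = meta.loc[chosen, "species"]
        relabeled = expand_species_distance(host_dm, sp_of)
        assoc.index = [str(i) for i in assoc.index]
        try:
            fit = paco_fit(relabeled, sym_dm, assoc, n_perm=0, seed=b,
                           center_residuals=20)
        except ValueError as exc:
            logger.warning("PACo subsample %d failed: %s", b, exc)
            n_failed += 1
            continue
        for sid, r in fit.per_sample_residual.items():
            records.append(
                {
                    "subsample": b,
                    "sample_id": sid,
                    "species": meta.loc[sid, "species"],
                    "family": meta.loc[sid, "family"],
                    "gut_type": meta.loc[sid, "gut_type"],
                    "residual": float(r),
                    "residual_centered": float(fit.per_sample_residual_centered[sid]),
                }
            )
    residuals = pd.DataFrame(records)
    comparisons = _within_between_comparisons(residuals)
    return PACoSubsampleResult(residuals, comparisons, n_failed)


def _within_between_comparisons(
    residuals: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Do residuals agree more within than between groups?

    Works on per-sample mean centered residuals (one value per sample, so
    subsample reuse does not pseudo-replicate the test). The statistic is
    median(|Δ| between groups) - median(|Δ| within groups) over sample
    pairs; its null distribution comes from permuting group labels over the
    exchangeable blocks (samples for the species level, species for the
    family and gut-type levels). BH adjustment across the three levels.
    """
    per_sample = (
        residuals.groupby("sample_id")
        .agg(residual=("residual_centered", "mean"), species=("species", "first"),
             family=("family", "first"), gut_type=("gut_type", "first"))
    )
    r = per_sample["residual"].to_numpy()
    n = len(per_sample)
    ii, jj = np.triu_indices(n, k=1)
    diffs = np.abs(r[ii] - r[jj])
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD1FF)))

    def _stat(labels):
        same = labels[ii] == labels[jj]
        if same.all() or (~same).all():
            return np.nan
        return float(np.median(diffs[~same]) - np.median(diffs[same]))

    species = per_sample["species"].to_numpy()
    rows = []
    for level in ("species", "family", "gut_type"):
        labels = per_sample[level].to_numpy()
        obs = _stat(labels)
        if not np.isfinite(obs):
            rows.append({"grouping": level, "statistic": np.nan,
                         "median_within": np.nan, "median_between": np.nan,
                         "p_value": np.nan})
            continue
        count = 0
        if level == "species":
            for _ in range(n_perm):
                count += _stat(labels[rng.permutation(n)]) >= obs - 1e-12
        else:
            # keep individuals with their species; shuffle which species
            # carries which family / gut-type label
            uniq = pd.unique(species)
            level_of = {s: per_sample[level][species == s].iloc[0] for s in uniq}
            for _ in range(n_perm):
                shuffled = dict(zip(uniq, rng.permutation([level_of[s] for s in uniq])))
                count += _stat(np.array([shuffled[s] for s in species])) >= obs - 1e-12
        same = labels[ii] == labels[jj]
        rows.append(
            {
                "grouping": level,
                "statistic": obs,
                "median_within": float(np.median(diffs[same])),
                "median_between": float(np.median(diffs[~same])),
                "p_value": (count + 1) / (n_perm + 1),
            }
        )
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    df.loc[ok, "p_adjusted"] = false_discovery_control(df.loc[ok, "p_value"], method="bh")
    return df


# ---------------------------------------------------------------------------
# proximity weights
# ---------------------------------------------------------------------------

def inverse_patristic_weights(tree: TreeNode, epsilon_scale: float = 1e-6) -> pd.DataFrame:
    """Row-normalized 1/patristic-distance weights (zero diagonal).

    Zero off-diagonal distances (conspecific individuals attached at zero
    length) are floored at ``epsilon_scale x tree height`` so the inverse is
    finite.
    """
    dm = patristic_distances(tree)
    d = dm.data.copy()
    eps = epsilon_scale * max(tree_height(tree), 1e-12)
    off = ~np.eye(d.shape[0], dtype=bool)
    d[off & (d < eps)] = eps
    with np.errstate(divide="ignore"):
        w = np.where(off, 1.0 / d, 0.0)
    w = w / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(w, index=list(dm.ids), columns=list(dm.ids))


def abouheif_proximity(tree: TreeNode) -> pd.DataFrame:
    """Abouheif proximity: 1 / product of child counts of internal nodes on
    the tip-to-tip path (the standard construction), row-normalized."""
    tips = list(tree.tips())
    names = [t.name for t in tips]
    ancestors = {}
    for tip in tips:
        path = []
        node = tip.parent
        while node is not None:
            path.append(id(node))
            node = node.parent
        ancestors[tip.name] = path
    nchild = {}
    for node in tree.traverse(include_self=True):
        if not node.is_tip():
            nchild[id(node)] = len(node.children)
    n = len(tips)
    a = np.zeros((n, n))
    anc_sets = {name: set(p) for name, p in ancestors.items()}
    for i in range(n - 1):
        pi = ancestors[names[i]]
        for j in range(i + 1, n):
            shared = anc_sets[names[i]] & anc_sets[names[j]]
            # MRCA = first shared ancestor on i's path
            mrca = next(nid for nid in pi if nid in shared)
            prod = nchild[mrca]
            for nid in pi:
                if nid == mrca:
                    break
                prod *= nchild[nid]
            for nid in ancestors[names[j]]:
                if nid == mrca:
                    break
                prod *= nchild[nid]
            a[i, j] = a[j, i] = 1.0 / prod
    a = a / a.sum(axis=1, keepdims=True)
    return pd.DataFrame(a, index=names, columns=names)


# ---------------------------------------------------------------------------
# global signal statistics
# ---------------------------------------------------------------------------

def _moran(z: np.ndarray, w: np.ndarray) -> float:
    return float(z @ (w @ z) / (z @ z))


def _brownian_covariance(tree: TreeNode) -> pd.DataFrame:
    """C[i, j] = root-to-MRCA path length (Brownian trait covariance)."""
    tips = [t.name for t in tree.tips()]
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    c = np.zeros((n, n))

    def _walk(node, depth):
        if node.is_tip():
            c[index[node.name], index[node.name]] = depth
            return [index[node.name]]
        groups = []
        for child in node.children:
            groups.append(_walk(child, depth + (child.length or 0.0)))
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        c[a, b] = c[b, a] = depth
        return [x for g in groups for x in g]

    _walk(tree, 0.0)
    return pd.DataFrame(c, index=tips, columns=tips)


def _lambda_loglik(x: np.ndarray, c: np.ndarray, lam: float) -> float:
    n = len(x)
    v = lam * c + (1 - lam) * np.diag(np.diag(c))
    try:
        chol = np.linalg.cholesky(v + 1e-12 * np.trace(v) / n * np.eye(n))
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    ones = np.ones(n)
    vi_x = np.linalg.solve(v + 1e-12 * np.trace(v) / n * np.eye(n), x)
    vi_1 = np.linalg.solve(v + 1e-12 * np.trace(v) / n * np.eye(n), ones)
    mu = float(ones @ vi_x / (ones @ vi_1))
    r = x - mu
    sigma2 = float(r @ np.linalg.solve(v + 1e-12 * np.trace(v) / n * np.eye(n), r)) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _make_lambda_loglik(x: np.ndarray, c: np.ndarray):
    """Log-likelihood closure; uses a one-time eigendecomposition when the
    tree is ultrametric (diag(c) constant), since lam*C + (1-lam)*h*I then
    shares C's eigenvectors."""
    diag = np.diag(c)
    if np.allclose(diag, diag[0], rtol=1e-8):
        h = float(diag[0])
        evals, evecs = np.linalg.eigh(c)
        xr = evecs.T @ x
        ones_r = evecs.T @ np.ones(len(x))
        n = len(x)

        def loglik(lam: float) -> float:
            ev = lam * evals + (1 - lam) * h
            if (ev <= 0).any():
                return -np.inf
            logdet = float(np.log(ev).sum())
            mu = float((ones_r * xr / ev).sum() / (ones_r**2 / ev).sum())
            rr = xr - mu * ones_r
            sigma2 = float((rr**2 / ev).sum()) / n
            if sigma2 <= 0:
                return -np.inf
            return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

        return loglik
    return lambda lam: _lambda_loglik(x, c, lam)


def fit_pagel_lambda(trait: pd.Series, tree: TreeNode) -> tuple[float, float]:
    """ML Pagel's lambda in [0, 1] with a likelihood-ratio p against lambda=0."""
    c_df = _brownian_covariance(tree)
    x = trait.loc[c_df.index].to_numpy(dtype=float)
    if len(x) < 3:
        return float("nan"), float("nan")
    loglik = _make_lambda_loglik(x, c_df.to_numpy())
    res = minimize_scalar(
        lambda lam: -loglik(lam), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-4},
    )
    cand = [(0.0, loglik(0.0)), (1.0, loglik(1.0)), (float(res.x), -float(res.fun))]
    lam_hat, ll_hat = max(cand, key=lambda t: t[1])
    lr = max(2.0 * (ll_hat - loglik(0.0)), 0.0)
    p = float(chi2.sf(lr, df=1))
    return float(lam_hat), p


def global_phylo_signal(
    trait: pd.Series,
    tree: TreeNode,
    n_perm: int = 999,
    seed: int = 0,
    genus: str = "",
    weights: pd.DataFrame | None = None,
    abouheif: pd.DataFrame | None = None,
) -> SignalResult:
    """Abouheif's Cmean, Moran's I and Pagel's lambda for one genus trait.

    Moran's I uses row-normalized inverse-patristic weights; Cmean is the
    Moran statistic under the Abouheif proximity matrix. Permutation
    p-values (upper tail) for both; likelihood-ratio p for lambda.
    Precomputed weight matrices can be passed to amortize cost over genera.
    """
    w = (weights if weights is not None else inverse_patristic_weights(tree))
    a = (abouheif if abouheif is not None else abouheif_proximity(tree))
    tips = list(w.index)
    x = trait.loc[tips].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"constant trait{f' for genus {genus}' if genus else ''}")
    z = (x - x.mean()) / x.std(ddof=0)
    wm, am = w.to_numpy(), a.to_numpy()
    i_obs = _moran(z, wm)
    c_obs = _moran(z, am)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x519)))
    perms = np.array([rng.permutation(len(z)) for _ in range(n_perm)])
    zp = z[perms]  # n_perm x n
    i_perm = np.einsum("pi,pi->p", zp, zp @ wm.T) / (z @ z)
    c_perm = np.einsum("pi,pi->p", zp, zp @ am.T) / (z @ z)
    p_i = (1 + int((i_perm >= i_obs - 1e-12).sum())) / (n_perm + 1)
    p_c = (1 + int((c_perm >= c_obs - 1e-12).sum())) / (n_perm + 1)

    if len(tips) <= 2:
        lam, p_lam = float("nan"), float("nan")
    else:
        lam, p_lam = fit_pagel_lambda(pd.Series(x, index=tips), tree)
    return SignalResult(
        genus=genus,
        cmean=c_obs,
        moran_i=i_obs,
        pagel_lambda=lam,
        p_values={"cmean": p_c, "moran_i": p_i, "pagel_lambda": p_lam},
    )


# ---------------------------------------------------------------------------
# LIPA
# ---------------------------------------------------------------------------

def lipa(
    trait: pd.Series,
    tree: TreeNode,
    n_perm: int = 999,
    seed: int = 0,
    genus: str = "",
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-tip local Moran statistic I_i = z_i * sum_j w_ij z_j.

    The trait is centered and scaled by the population standard deviation,
    so the tip mean of LIPA equals global Moran's I exactly. Per-tip
    p-values come from permuting trait values over tips (upper tail).
    """
    w = weights if weights is not None else inverse_patristic_weights(tree)
    tips = list(w.index)
    x = trait.loc[tips].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"constant trait{f' for genus {genus}' if genus else ''}")
    z = (x - x.mean()) / x.std(ddof=0)
    wm = w.to_numpy()
    i_obs = z * (wm @ z)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x11A)))
    perms = np.array([rng.permutation(len(z)) for _ in range(n_perm)])
    zp = z[perms]
    i_perm = zp * (zp @ wm.T)
    p = (1 + (i_perm >= i_obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1)
    return pd.DataFrame({"tip_id": tips, "genus": genus, "lipa": i_obs, "p_value": p})


def strength_band(mean_lipa: float, significant: bool) -> str:
    """Band a mean LIPA value: none (<0.2 or not significant), weak
    [0.2, 0.4), moderate [0.4, 1), strong (>= 1)."""
    if not significant or not np.isfinite(mean_lipa) or mean_lipa < 0.2:
        return "none"
    if mean_lipa < 0.4:
        return "weak"
    if mean_lipa < 1.0:
        return "moderate"
    return "strong"


def lipa_summarize(
    results: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Mean LIPA per (genus x species) and (genus x family) with bands.

    A group counts as significant when any member tip's permutation p-value
    clears ``alpha`` (tips are the evidence carriers; group means only grade
    the strength).
    """
    df = results.merge(
        meta[["species", "family"]], left_on="tip_id", right_index=True, how="left"
    )
    rows = []
    for level in ("species", "family"):
        grouped = df.groupby(["genus", level])
        for (genus, grp_name), grp in grouped:
            mean_val = float(grp["lipa"].mean())
            sig = bool((grp["p_value"] < alpha).any())
            rows.append(
                {
                    "genus": genus,
                    "level": level,
                    "group": grp_name,
                    "mean_lipa": mean_val,
                    "min_p": float(grp["p_value"].min()),
                    "strength": strength_band(mean_val, sig),
                }
            )
    return pd.DataFrame(rows)


def abundance_trait(
    table: CommunityTable, genus: str, pseudocount: float = 1e-6, transform: str = "log10"
) -> pd.Series:
    """Per-sample trait for signal/LIPA: log10(relative abundance + pseudocount)."""
    rel = table.relative_abundance()[genus]
    if transform == "log10":
        return np.log10(rel + pseudocount)
    if transform == "none":
        return rel
    raise ValueError(f"unknown transform {transform!r}")


def per_sample_host_tree(species_tree: TreeNode, meta: pd.DataFrame) -> TreeNode:
    """Host tree with one tip per sample (wrapper over core.attach_individuals)."""
    return attach_individuals(species_tree, meta)
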