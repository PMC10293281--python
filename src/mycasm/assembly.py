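"""Null-model partitioning of stochastic vs deterministic community assembly.

Three complementary statistics, all referenced to randomized communities:

* **NST** — the normalized stochasticity ratio. Observed pairwise
  dissimilarity ``D`` is compared with its null expectation ``E(D)``; the
  per-pair normalized selection strength is ``(E(D)-D)/E(D)`` when the pair
  is more similar than expected and ``(D-E(D))/(Dmax-E(D))`` otherwise
  (``Dmax=1`` for Jaccard and Bray-Curtis). NST is the pair mean of
  ``1 - selection strength`` in percent; >50% reads as predominantly
  stochastic assembly. Group values carry a bootstrap distribution.
* **βNRI** — the z-score of abundance-weighted between-sample mean pairwise
  phylogenetic distance (βMPD) against tip-shuffling nulls; |βNRI| > 2
  signals selection (negative: homogeneous, positive: heterogeneous).
* **RC_Bray** — the Raup-Crick position of observed Bray-Curtis within the
  taxonomic null distribution, rescaled to [-1, 1]; |RC| > 0.95 signals
  dispersal-driven deviation, ties counted at half weight.

Pairs with |βNRI| <= 2 are classified by RC_Bray into dispersal limitation
(RC > 0.95), homogenizing dispersal (RC < -0.95) or drift (otherwise),
giving the five-way process partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .core import CommunityTable, patristic_distances

logger = logging.getLogger("mycasm")

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class NullModelConfig:
    """Null-model settings shared by NST, βNRI and RC_Bray."""

    n_null: int = 999
    seed: int = 0
    richness_constraint: str = "fixed_per_sample"
    taxon_draw_weights: str = "occupancy_proportional"
    abundance_fill: str = "regional_relative_abundance"

    def __post_init__(self):
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")
        if self.richness_constraint != "fixed_per_sample":
            raise ValueError("only the fixed_per_sample richness constraint is implemented")
        if self.taxon_draw_weights != "occupancy_proportional":
            raise ValueError("only occupancy_proportional taxon draws are implemented")
        if self.abundance_fill != "regional_relative_abundance":
            raise ValueError("only regional_relative_abundance fill is implemented")

    def spawn_rngs(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class NSTResult:
    group_id: str
    index_used: str
    sample_ids: list[str]
    st_pairwise: np.ndarray       # condensed, Zhou-style stochasticity ratio
    nst_pairwise: np.ndarray      # condensed, normalized (0..1)
    nst_point: float              # percent
    nst_bootstrap: np.ndarray     # percents, length n_boot


@dataclass
class AssemblyPartition:
    pairs: pd.DataFrame  # columns: sample_a, sample_b, bnri, rc_bray, process
    fractions: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# null community generation
# ---------------------------------------------------------------------------

def generate_null_community(
    table: CommunityTable, rng: np.random.Generator
) -> CommunityTable:
    """One taxonomic-null realization of the whole table.

    Each null sample keeps its observed richness and total reads: taxa are
    drawn without replacement with probability proportional to dataset
    occupancy, each drawn taxon receives one read, and the remaining reads
    are distributed multinomially in proportion to the regional (dataset)
    relative abundances of the drawn taxa.
    """
    if not table.is_integer():
        raise ValueError("null models require integer read counts")
    counts = np.round(table.counts).astype(np.int64)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    if pool.size == 0:
        raise ValueError("empty regional pool")
    draw_w = occupancy[pool] / occupancy[pool].sum()
    regional = counts.sum(axis=0).astype(float)

    null = np.zeros_like(counts)
    for si in range(counts.shape[0]):
        richness = int((counts[si] > 0).sum())
        total = int(counts[si].sum())
        if richness == 0:
            continue
        if richness > pool.size:
            raise ValueError(
                f"sample {table.sample_ids[si]!r} richness {richness} exceeds pool size {pool.size}"
            )
        if richness == pool.size:
            chosen = pool
        else:
            chosen = pool[rng.choice(pool.size, size=richness, replace=False, p=draw_w)]
        fill_p = regional[chosen]
        fill_p = fill_p / fill_p.sum()
        null[si, chosen] = 1 + rng.multinomial(total - richness, fill_p)
    return CommunityTable(
        pd.DataFrame(null, index=table.sample_ids, columns=table.taxon_ids),
        allow_empty_samples=True,
    )


# ---------------------------------------------------------------------------
# pairwise dissimilarity helpers
# ---------------------------------------------------------------------------

def _condensed_dissimilarity(table: CommunityTable, index: str) -> np.ndarray:
    if index == "bray":
        rel = table.relative_abundance().to_numpy()
        return pdist(rel, metric="braycurtis")
    if index == "jaccard":
        inc = (table.counts > 0)
        return pdist(inc, metric="jaccard")
    raise ValueError(f"unknown index {index!r}")


def null_expected_dissimilarity(
    table: CommunityTable, index: str, config: NullModelConfig
) -> np.ndarray:
    """Mean condensed dissimilarity over ``n_null`` taxonomic-null tables."""
    rngs = config.spawn_rngs(config.n_null)
    acc = None
    for rng in rngs:
        d = _condensed_dissimilarity(generate_null_community(table, rng), index)
        acc = d if acc is None else acc + d
    return acc / config.n_null


# ---------------------------------------------------------------------------
# NST
# ---------------------------------------------------------------------------

def _pairwise_stochasticity(d_obs: np.ndarray, d_exp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (ST, NST) from observed and null-expected dissimilarity."""
    d_obs = np.clip(d_obs, 0.0, 1.0)
    tied = np.abs(d_obs - d_exp) <= 1e-9  # D = E(D): maximally stochastic pair
    d_exp = np.clip(d_exp, 1e-12, 1.0 - 1e-12)
    more_similar = d_obs < d_exp
    ss = np.where(
        more_similar,
        (d_exp - d_obs) / d_exp,
        (d_obs - d_exp) / (1.0 - d_exp),
    )
    ss[tied] = 0.0
    nst = 1.0 - ss
    with np.errstate(divide="ignore", invalid="ignore"):
        st = np.where(more_similar, d_obs / d_exp, d_exp / np.maximum(d_obs, 1e-12))
    st[tied] = 1.0
    st = np.clip(np.nan_to_num(st, nan=1.0), 0.0, 1.0)
    return st, np.clip(nst, 0.0, 1.0)


def compute_nst(
    table: CommunityTable,
    groups: pd.Series,
    index: str = "bray",
    config: NullModelConfig | None = None,
    n_boot: int = 1000,
) -> list[NSTResult]:
    """Group-wise NST with sample-resampling bootstrap.

    ``groups`` maps sample id -> group label (e.g. gut type); groups with
    fewer than 3 samples are skipped with a warning. The null model is run
    within each group, so E(D) reflects that group's own regional pool.
    """
    config = config or NullModelConfig()
    results = []
    boot_ss = np.random.SeedSequence((config.seed, 0xB007))
    for gi, (group, members) in enumerate(sorted(groups.groupby(groups).groups.items())):
        members = [m for m in members if m in table.sample_ids]
        if len(members) < 3:
            warnings.warn(f"group {group!r} has fewer than 3 samples; skipped", stacklevel=2)
            continue
        sub = table.subset(sample_ids=members).drop_empty_taxa()
        group_cfg = NullModelConfig(
            n_null=config.n_null,
            seed=int(np.random.SeedSequence((config.seed, gi)).generate_state(1)[0] % (2**31 - 1)),
        )
        d_obs = _condensed_dissimilarity(sub, index)
        d_exp = null_expected_dissimilarity(sub, index, group_cfg)
        st, nst = _pairwise_stochasticity(d_obs, d_exp)
        n = len(members)
        nst_sq = squareform(nst, checks=False)
        rng = np.random.default_rng(boot_ss.spawn(1)[0])
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            ii, jj = np.triu_indices(n, k=1)
            a, c = idx[ii], idx[jj]
            keep = a != c
            boot[b] = nst_sq[a[keep], c[keep]].mean() * 100.0 if keep.any() else np.nan
        results.append(
            NSTResult(
                group_id=str(group),
                index_used=index,
                sample_ids=members,
                st_pairwise=st,
                nst_pairwise=nst,
                nst_point=float(nst.mean() * 100.0),
                nst_bootstrap=boot,
            )
        )
        logger.info("NST[%s, %s] = %.1f%% (n=%d)", group, index, results[-1].nst_point, n)
    return results


# ---------------------------------------------------------------------------
# beta-NRI
# ---------------------------------------------------------------------------

def _beta_mpd(rel: np.ndarray, dmat: np.ndarray) -> np.ndarray:
    """Abundance-weighted between-sample mean pairwise distance, square form."""
    return rel @ dmat @ rel.T


def compute_bnri(
    table: CommunityTable,
    tree: TreeNode,
    config: NullModelConfig | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """βNRI per sample pair: z-score of βMPD against tip-label shuffles.

    The null keeps the abundance matrix fixed and permutes taxa across the
    tips of the phylogeny. Degenerate nulls (zero standard deviation, e.g. a
    star tree with equal branch lengths) yield βNRI = 0 with a warning.
    """
    config = config or NullModelConfig()
    tip_names = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tip_names]
    if missing:
        raise ValueError(f"taxa absent from the phylogeny: {missing}")
    dm = patristic_distances(tree)
    dmat = dm.filter(table.taxon_ids).data
    if weighted:
        prof = table.relative_abundance().to_numpy()
    else:
        inc = (table.counts > 0).astype(float)
        prof = inc / inc.sum(axis=1, keepdims=True)
    obs = _beta_mpd(prof, dmat)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xB281)))
    n_taxa = dmat.shape[0]
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for k in range(1, config.n_null + 1):
        perm = rng.permutation(n_taxa)
        null = _beta_mpd(prof[:, perm], dmat)
        delta = null - mean
        mean += delta / k
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / max(config.n_null - 1, 1))
    # a null that never moves (e.g. equal-branch star tree) is degenerate
    degenerate = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate |= ~np.isfinite(z)
    if degenerate[np.triu_indices_from(z, k=1)].any():
        warnings.warn("zero-variance βMPD null; βNRI set to 0 for affected pairs", stacklevel=2)
    z[degenerate] = 0.0
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def compute_rc_bray(
    table: CommunityTable, config: NullModelConfig | None = None
) -> pd.DataFrame:
    """RC_Bray per pair: 2 * [(#null < obs) + 0.5 * (#null = obs)] / n_null - 1."""
    config = config or NullModelConfig()
    d_obs = _condensed_dissimilarity(table, "bray")
    rngs = NullModelConfig(n_null=config.n_null, seed=config.seed).spawn_rngs(config.n_null)
    less = np.zeros_like(d_obs)
    equal = np.zeros_like(d_obs)
    for rng in rngs:
        d_null = _condensed_dissimilarity(generate_null_community(table, rng), "bray")
        less += d_null < d_obs - 1e-12
        equal += np.abs(d_null - d_obs) <= 1e-12
    rc = 2.0 * (less + 0.5 * equal) / config.n_null - 1.0
    sq = squareform(rc, checks=False)
    return pd.DataFrame(sq, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# five-way partition
# ---------------------------------------------------------------------------

def classify_pair(bnri: float, rc: float, bnri_cut: float = 2.0, rc_cut: float = 0.95) -> str:
    if bnri > bnri_cut:
        return "heterogeneous_selection"
    if bnri < -bnri_cut:
        return "homogeneous_selection"
    if rc > rc_cut:
        return "dispersal_limitation"
    if rc < -rc_cut:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(
    bnri: pd.DataFrame,
    rc: pd.DataFrame,
    bnri_cut: float = 2.0,
    rc_cut: float = 0.95,
) -> AssemblyPartition:
    """Classify every sample pair and report the five process fractions."""
    if list(bnri.index) != list(rc.index) or list(bnri.columns) != list(rc.columns):
        raise ValueError("βNRI and RC_Bray must cover the same sample pairs")
    ids = np.asarray(bnri.index)
    ii, jj = np.triu_indices(len(ids), k=1)
    b = bnri.to_numpy()[ii, jj]
    r = rc.to_numpy()[ii, jj]
    process = np.where(
        b > bnri_cut, "heterogeneous_selection",
        np.where(
            b < -bnri_cut, "homogeneous_selection",
            np.where(r > rc_cut, "dispersal_limitation",
                     np.where(r < -rc_cut, "homogenizing_dispersal", "drift")),
        ),
    )
    pairs = pd.DataFrame(
        {"sample_a": ids[ii], "sample_b": ids[jj], "bnri": b, "rc_bray": r,
         "process": process}
    )
    n = len(pairs)
    fractions = {p: float((pairs["process"] == p).sum()) / n for p in PROCESSES}
    logger.info("process fractions: %s", {k: round(v, 3) for k, v in fractions.items()})
    return AssemblyPartition(pairs=pairs, fractions=fractions)
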