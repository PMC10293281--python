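"""Marker-threshold calibration, OTU clustering and genus assignment.

Anaerobic gut fungi are delineated with divergence thresholds defined on the
full D1/D2 LSU marker (2% species, 3% genus). Amplicon surveys sequence only
the faster-evolving D2 sub-region, so the thresholds must be mapped through
the empirical regression of sub-region on full-marker pairwise divergence.
Genus assignment is two-tier: queries within the (mapped) genus threshold of
a reference genus inherit its name; the remainder are clustered among
themselves and become novel genera labelled NY1, NY2, ... in order of first
appearance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from skbio import DistanceMatrix

from .core import Alignment, CommunityTable

logger = logging.getLogger("mycasm")

_GAP_CHARS = frozenset(b"ACGT")


@dataclass
class ThresholdMap:
    """OLS map from full-marker divergence to sub-region divergence."""

    slope: float
    intercept: float
    r_squared: float
    species_threshold_full: float
    genus_threshold_full: float

    @property
    def mapped_species_threshold(self) -> float:
        return self.slope * self.species_threshold_full + self.intercept

    @property
    def mapped_genus_threshold(self) -> float:
        return self.slope * self.genus_threshold_full + self.intercept

    def map(self, threshold: float) -> float:
        return self.slope * threshold + self.intercept


@dataclass
class OTUAssignment:
    sequence_id: str
    genus_label: str
    is_novel: bool
    cluster_id: int
    tier: int


# ---------------------------------------------------------------------------

def _valid_mask(seqs: np.ndarray) -> np.ndarray:
    """True where a site is an unambiguous base (A/C/G/T)."""
    mask = np.zeros(seqs.shape, dtype=bool)
    for b in b"ACGT":
        mask |= seqs == bytes([b])
    return mask


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise divergence with pairwise deletion of gaps.

    For each sequence pair only columns where both sequences carry an
    unambiguous base are compared; a pair with no comparable columns is an
    error (divergence undefined).
    """
    seqs = aln.seqs
    valid = _valid_mask(seqs)
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1:]
        comparable = both.sum(axis=1)
        if (comparable == 0).any():
            j = i + 1 + int(np.argmax(comparable == 0))
            raise ValueError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        diffs = ((seqs[i] != seqs[i + 1:]) & both).sum(axis=1)
        d[i, i + 1:] = d[i + 1:, i] = diffs / comparable
    return DistanceMatrix(d, ids=aln.ids)


def fit_threshold_map(
    dist_full: DistanceMatrix,
    dist_sub: DistanceMatrix,
    species_thr_full: float = 0.02,
    genus_thr_full: float = 0.03,
) -> ThresholdMap:
    """OLS of sub-region on full-marker divergences over the upper triangle."""
    if list(dist_full.ids) != list(dist_sub.ids):
        raise ValueError("distance matrices must share identical id order")
    iu = np.triu_indices(dist_full.shape[0], k=1)
    x = dist_full.data[iu]
    y = dist_sub.data[iu]
    if x.size < 3:
        raise ValueError("need at least 3 sequence pairs to fit the map")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in full-marker divergences")
    fit = linregress(x, y)
    tm = ThresholdMap(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        species_threshold_full=species_thr_full,
        genus_threshold_full=genus_thr_full,
    )
    logger.info(
        "threshold map: slope=%.4f intercept=%.5f R2=%.4f; %s%%->%.2f%%, %s%%->%.2f%%",
        tm.slope, tm.intercept, tm.r_squared,
        100 * species_thr_full, 100 * tm.mapped_species_threshold,
        100 * genus_thr_full, 100 * tm.mapped_genus_threshold,
    )
    return tm


def cluster_otus(dist: DistanceMatrix, threshold: float, method: str = "average") -> np.ndarray:
    """Average-linkage clustering cut at ``threshold``; labels in input order.

    Cluster ids are renumbered consecutively from 1 in order of first
    appearance, so the output is deterministic given input ordering.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    n = dist.shape[0]
    if n == 1:
        return np.array([1])
    Z = linkage(squareform(dist.data, checks=False), method=method)
    raw = fcluster(Z, t=threshold, criterion="distance")
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return out


def _cross_p_distance(a: Alignment, b: Alignment) -> np.ndarray:
    """p-distances between every sequence of ``a`` and every sequence of ``b``."""
    if a.length != b.length:
        raise ValueError("queries and references must be co-aligned (equal lengths)")
    va, vb = _valid_mask(a.seqs), _valid_mask(b.seqs)
    out = np.zeros((len(a.ids), len(b.ids)))
    for i in range(len(a.ids)):
        both = va[i] & vb
        comparable = both.sum(axis=1)
        if (comparable == 0).any():
            j = int(np.argmax(comparable == 0))
            raise ValueError(f"no comparable sites between {a.ids[i]!r} and {b.ids[j]!r}")
        out[i] = ((a.seqs[i] != b.seqs) & both).sum(axis=1) / comparable
    return out


def assign_genera(
    queries: Alignment,
    references: Alignment,
    reference_genera: dict[str, str] | pd.Series,
    genus_threshold: float = 0.051,
) -> list[OTUAssignment]:
    """Two-tier genus assignment with novel-genus (NY) labelling.

    Tier 1: a query joins the reference genus with the smallest *mean*
    p-distance to that genus's references, provided the mean is within the
    genus threshold (ties broken lexicographically by genus name). Tier 2:
    unassigned queries are clustered among themselves (average linkage, same
    threshold); each cluster becomes a novel genus NY<k>, numbered by first
    appearance in query order.
    """
    ref_genus = pd.Series(reference_genera)
    missing = [r for r in references.ids if r not in ref_genus.index]
    if missing:
        raise ValueError(f"references without a genus label: {missing}")
    genera = sorted(ref_genus.loc[references.ids].unique())
    cross = _cross_p_distance(queries, references)
    labels_by_ref = ref_genus.loc[references.ids].to_numpy()
    mean_by_genus = np.column_stack(
        [cross[:, labels_by_ref == g].mean(axis=1) for g in genera]
    )

    assignments: dict[str, OTUAssignment] = {}
    unassigned: list[int] = []
    for qi, qid in enumerate(queries.ids):
        means = mean_by_genus[qi]
        best = float(means.min())
        if best <= genus_threshold:
            near = [g for g, v in zip(genera, means) if v <= best + 1e-9]
            if len(near) > 1:
                logger.info("tie for query %s between %s; keeping %s", qid, near, near[0])
            assignments[qid] = OTUAssignment(qid, near[0], False, 0, 1)
        else:
            unassigned.append(qi)

    if unassigned:
        sub = Alignment([queries.ids[i] for i in unassigned], queries.seqs[unassigned])
        if len(unassigned) == 1:
            clusters = np.array([1])
        else:
            clusters = cluster_otus(p_distance_matrix(sub), genus_threshold)
        ny_of_cluster: dict[int, str] = {}
        for qid, lab in zip(sub.ids, clusters):
            if lab not in ny_of_cluster:
                ny_of_cluster[lab] = f"NY{len(ny_of_cluster) + 1}"
            assignments[qid] = OTUAssignment(qid, ny_of_cluster[lab], True, int(lab), 2)

    # cluster ids for tier-1 assignments: one id per reference genus, after NY ids
    genus_cluster = {g: i + 1 for i, g in enumerate(genera)}
    out = []
    for qid in queries.ids:
        a = assignments[qid]
        if not a.is_novel:
            a = OTUAssignment(a.sequence_id, a.genus_label, False, -genus_cluster[a.genus_label], 1)
        out.append(a)
    return out


def ubiquity_abundance_summary(table: CommunityTable) -> tuple[pd.DataFrame, float]:
    """Per-taxon ubiquity and mean relative abundance, plus their correlation.

    Ubiquity is the number of samples in which a taxon occurs. The R^2 comes
    from an OLS of log10(mean relative abundance) on ubiquity over taxa with
    ubiquity > 0 (absent taxa are excluded; the log transform is this
    package's declared choice and is recorded in the output).
    """
    rel = table.relative_abundance()
    ubiquity = (table.data > 0).sum(axis=0)
    mean_rel = rel.mean(axis=0)
    df = pd.DataFrame(
        {"ubiquity": ubiquity.astype(int), "mean_relative_abundance": mean_rel}
    )
    present = df[df["ubiquity"] > 0]
    if len(present) >= 3 and present["ubiquity"].nunique() > 1:
        fit = linregress(present["ubiquity"], np.log10(present["mean_relative_abundance"]))
        r2 = float(fit.rvalue**2)
    else:
        r2 = float("nan")
    df.attrs["abundance_transform"] = "log10"
    df.attrs["r_squared"] = r2
    return df, r2
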