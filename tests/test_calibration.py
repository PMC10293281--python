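"""Divergence thresholds, OTU clustering and two-tier genus assignment."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from mycasm.calibration import (
    assign_genera,
    cluster_otus,
    fit_threshold_map,
    p_distance_matrix,
    ubiquity_abundance_summary,
)
from mycasm.core import Alignment


def _aln(pairs):
    ids, seqs = zip(*pairs)
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(ids), -1)
    return Alignment(list(ids), mat)


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "s1, s2, expected",
    [
        ("ACGT", "ACGA", 0.25),
        ("ACGT", "ACGT", 0.0),
        ("AC-T", "ACGT", 0.0),  # gap column dropped pairwise: 0 diffs / 3 sites
    ],
)
def test_p_distance_examples(s1, s2, expected):
    dm = p_distance_matrix(_aln([("a", s1), ("b", s2)]))
    assert dm["a", "b"] == pytest.approx(expected)


def test_p_distance_no_comparable_sites():
    with pytest.raises(ValueError, match="a.*b"):
        p_distance_matrix(_aln([("a", "AC--"), ("b", "--GT")]))


# ---------------------------------------------------------------------------
# threshold map
# ---------------------------------------------------------------------------

def _dm(values, ids):
    return DistanceMatrix(values, ids=ids)


def test_threshold_map_identity():
    ids = list("abcd")
    rng = np.random.default_rng(1)
    d = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    d[iu] = rng.uniform(0.01, 0.2, size=6)
    d += d.T
    tm = fit_threshold_map(_dm(d, ids), _dm(d, ids))
    assert tm.slope == pytest.approx(1.0)
    assert tm.intercept == pytest.approx(0.0, abs=1e-12)
    assert tm.r_squared == pytest.approx(1.0)
    assert tm.mapped_species_threshold == pytest.approx(0.02)


def test_threshold_map_scaled_recovers_published_ratio():
    """A sub-region evolving 1.7x faster maps 3% to 5.1% exactly."""
    ids = list("abcde")
    rng = np.random.default_rng(2)
    d = np.zeros((5, 5))
    iu = np.triu_indices(5, 1)
    d[iu] = rng.uniform(0.01, 0.15, size=10)
    d += d.T
    tm = fit_threshold_map(_dm(d, ids), _dm(1.7 * d, ids))
    assert tm.mapped_genus_threshold == pytest.approx(0.051)
    assert tm.r_squared == pytest.approx(1.0)


def test_threshold_map_input_validation():
    ids = list("ab")
    d = np.array([[0.0, 0.1], [0.1, 0.0]])
    with pytest.raises(ValueError, match="3"):
        fit_threshold_map(_dm(d, ids), _dm(d, ids))
    ids3 = list("abc")
    z = np.array([[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]], dtype=float)
    with pytest.raises(ValueError, match="variance"):
        fit_threshold_map(_dm(z, ids3), _dm(z, ids3))


# ---------------------------------------------------------------------------
# OTU clustering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dist, threshold, expected", [(0.10, 0.051, 2), (0.02, 0.051, 1)])
def test_cluster_pair(dist, threshold, expected):
    dm = _dm(np.array([[0, dist], [dist, 0.0]]), ["a", "b"])
    labels = cluster_otus(dm, threshold)
    assert len(set(labels)) == expected


def _brute_force_average_linkage(d, threshold):
    """Naive agglomeration oracle: merge the closest pair until the minimum
    average inter-cluster distance exceeds the threshold."""
    clusters = [[i] for i in range(d.shape[0])]
    while len(clusters) > 1:
        best, pair = None, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or avg < best:
                    best, pair = avg, (i, j)
        if best > threshold:
            break
        i, j = pair
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.zeros(d.shape[0], dtype=int)
    for k, members in enumerate(clusters):
        labels[members] = k
    return labels


def test_cluster_matches_brute_force_oracle(rng):
    n = 12
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    d[iu] = rng.uniform(0.0, 0.2, size=len(iu[0]))
    d += d.T
    dm = _dm(d, [f"q{i}" for i in range(n)])
    for threshold in (0.03, 0.051, 0.1):
        ours = cluster_otus(dm, threshold)
        oracle = _brute_force_average_linkage(d, threshold)
        # same partition up to label names
        pairs_ours = (ours[:, None] == ours[None, :])
        pairs_oracle = (oracle[:, None] == oracle[None, :])
        np.testing.assert_array_equal(pairs_ours, pairs_oracle)


def test_cluster_count_non_increasing_in_threshold(rng):
    n = 15
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    d[iu] = rng.uniform(0.0, 0.3, size=len(iu[0]))
    d += d.T
    dm = _dm(d, [f"q{i}" for i in range(n)])
    counts = [len(set(cluster_otus(dm, t))) for t in np.linspace(0.01, 0.29, 12)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# genus assignment
# ---------------------------------------------------------------------------

def _mutate(seq, k, rng):
    out = bytearray(seq.encode())
    pos = rng.choice(len(out), size=k, replace=False)
    for p in pos:
        out[p] = ord(rng.choice([b for b in "ACGT" if b != chr(out[p])]))
    return out.decode()


def _reference_panel(seed=5, length=200):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), size=length))
    genera = {}
    for gi, g in enumerate(["Alpha", "Beta", "Gamma"]):
        anchor = _mutate(base, 30 + 25 * gi, rng)  # genera >5.1% apart
        genera[g] = [(f"{g}_{k}", _mutate(anchor, 2, rng)) for k in range(3)]
    novel = {}
    for ni in range(2):
        anchor = _mutate(base, 70 + 30 * ni, rng)
        novel[f"clade{ni}"] = [(f"nov{ni}_{k}", _mutate(anchor, 2, rng)) for k in range(3)]
    return base, genera, novel, rng


def test_assign_close_query_inherits_reference_genus():
    base, genera, _, rng = _reference_panel()
    refs = _aln([s for g in genera.values() for s in g])
    labels = {sid: sid.split("_")[0] for sid in refs.ids}
    query = _aln([("q1", _mutate(dict(genera["Alpha"])["Alpha_0"], 2, rng))])
    (a,) = assign_genera(query, refs, labels)
    assert a.genus_label == "Alpha" and not a.is_novel and a.tier == 1


def test_assign_lone_distant_query_becomes_ny1():
    base, genera, _, rng = _reference_panel()
    refs = _aln([s for g in genera.values() for s in g])
    labels = {sid: sid.split("_")[0] for sid in refs.ids}
    query = _aln([("far", _mutate(base, 60, rng))])
    (a,) = assign_genera(query, refs, labels)
    assert a.genus_label == "NY1" and a.is_novel and a.tier == 2


def test_assign_recovers_two_planted_novel_clades():
    base, genera, novel, rng = _reference_panel(seed=5)
    refs = _aln([s for g in genera.values() for s in g])
    labels = {sid: sid.split("_")[0] for sid in refs.ids}
    queries = _aln(
        [("qA", _mutate(dict(genera["Beta"])["Beta_1"], 2, rng))]
        + [s for c in novel.values() for s in c]
    )
    assigns = {a.sequence_id: a for a in assign_genera(queries, refs, labels)}
    assert assigns["qA"].genus_label == "Beta"
    ny_labels = {a.genus_label for a in assigns.values() if a.is_novel}
    assert ny_labels == {"NY1", "NY2"}
    # each planted clade maps to exactly one NY label
    for members in novel.values():
        got = {assigns[sid].genus_label for sid, _ in members}
        assert len(got) == 1 and got.issubset(ny_labels)


def test_assignment_is_idempotent():
    """Using the assigned queries as references reproduces their own labels."""
    base, genera, novel, rng = _reference_panel(seed=5)
    refs = _aln([s for g in genera.values() for s in g])
    labels = {sid: sid.split("_")[0] for sid in refs.ids}
    queries = _aln([s for c in novel.values() for s in c])
    first = {a.sequence_id: a.genus_label for a in assign_genera(queries, refs, labels)}
    second = assign_genera(queries, queries, first)
    assert all(a.genus_label == first[a.sequence_id] and not a.is_novel for a in second)


# ---------------------------------------------------------------------------
# ubiquity / abundance
# ---------------------------------------------------------------------------

def test_ubiquity_counts(toy_table):
    df, _ = ubiquity_abundance_summary(toy_table)
    assert df.loc["t1", "ubiquity"] == 3
    assert df.loc["t4", "ubiquity"] == 2


def test_absent_taxon_excluded_from_regression():
    from mycasm.core import CommunityTable

    tab = CommunityTable(pd.DataFrame(
        [[5, 0, 3], [2, 0, 1]], index=["s1", "s2"], columns=["a", "zero", "c"]))
    df, r2 = ubiquity_abundance_summary(tab)
    assert df.loc["zero", "ubiquity"] == 0
    assert np.isnan(r2) or -1 <= r2 <= 1


def test_abundance_occupancy_relationship(neutral_fixture):
    """Log-series pools produce the classic positive abundance-occupancy link."""
    _, r2 = ubiquity_abundance_summary(neutral_fixture.table)
    assert r2 > 0.3
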