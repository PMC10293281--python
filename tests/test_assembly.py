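"""Null models, NST, betaNRI, RC_Bray and the five-way process partition."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from mycasm.assembly import (
    NullModelConfig,
    _pairwise_stochasticity,
    classify_pair,
    compute_bnri,
    compute_nst,
    compute_rc_bray,
    generate_null_community,
    partition_processes,
)
from mycasm.core import CommunityTable, parse_tree
from mycasm.synth import make_study_fixture, simulate_phylogeny


def _table(counts, prefix="s"):
    counts = np.asarray(counts)
    return CommunityTable(pd.DataFrame(
        counts,
        index=[f"{prefix}{i}" for i in range(counts.shape[0])],
        columns=[f"g{j}" for j in range(counts.shape[1])],
    ))


# ---------------------------------------------------------------------------
# null community generation
# ---------------------------------------------------------------------------

def test_single_taxon_null_equals_observed():
    tab = _table([[7], [3]])
    null = generate_null_community(tab, np.random.default_rng(0))
    np.testing.assert_array_equal(null.counts, tab.counts)


def test_null_preserves_richness_and_totals(rng):
    counts = rng.integers(0, 30, size=(20, 40))
    counts[counts.sum(axis=1) == 0, 0] = 1
    tab = _table(counts)
    null = generate_null_community(tab, rng)
    np.testing.assert_array_equal(null.counts.sum(axis=1), counts.sum(axis=1))
    np.testing.assert_array_equal((null.counts > 0).sum(axis=1), (counts > 0).sum(axis=1))


def test_null_requires_integer_counts():
    tab = _table([[1.5, 2.0]])
    with pytest.raises(ValueError, match="integer"):
        generate_null_community(tab, np.random.default_rng(0))


def _sequential_inclusion_probs(weights, k):
    """Enumerate inclusion probabilities of weighted sequential sampling
    without replacement (the draw scheme behind the taxonomic null)."""
    w = np.asarray(weights, float)
    n = len(w)
    probs = np.zeros(n)
    for order in permutations(range(n), k):
        p, rem = 1.0, w.copy()
        for i in order:
            p *= rem[i] / rem.sum()
            rem = rem.copy()
            rem[i] = 0.0
        for i in order:
            probs[i] += p
    return probs


def test_null_taxon_inclusion_matches_analytic_probabilities():
    # 3-sample toy: occupancies 3, 1, 1; the first null sample draws 2 of 3 taxa
    tab = _table([[5, 4, 0], [3, 0, 2], [6, 0, 0]])
    occupancy = (tab.counts > 0).sum(axis=0).astype(float)
    expected = _sequential_inclusion_probs(occupancy / occupancy.sum(), 2)
    n_reps = 2000
    included = np.zeros(3)
    rng = np.random.default_rng(42)
    for _ in range(n_reps):
        null = generate_null_community(tab, rng)
        included += null.counts[0] > 0  # first sample has richness 2
    freq = included / n_reps
    se = np.sqrt(expected * (1 - expected) / n_reps)
    assert (np.abs(freq - expected) < 4 * se + 1e-9).all()


# ---------------------------------------------------------------------------
# NST
# ---------------------------------------------------------------------------

def test_pair_at_null_expectation_is_fully_stochastic():
    st, nst = _pairwise_stochasticity(np.array([0.4]), np.array([0.4]))
    assert st[0] == pytest.approx(1.0)
    assert nst[0] == pytest.approx(1.0)


def test_nst_extremes():
    # far more similar than expected -> deterministic (toward similarity)
    _, nst_sim = _pairwise_stochasticity(np.array([0.0]), np.array([0.8]))
    # far more dissimilar than expected -> deterministic (toward dissimilarity)
    _, nst_dis = _pairwise_stochasticity(np.array([1.0]), np.array([0.2]))
    assert nst_sim[0] == pytest.approx(0.0)
    assert nst_dis[0] == pytest.approx(0.0)


def test_small_group_skipped(neutral_fixture):
    groups = pd.Series("big", index=neutral_fixture.table.sample_ids)
    groups.iloc[:2] = "tiny"
    with pytest.warns(UserWarning, match="tiny"):
        res = compute_nst(neutral_fixture.table, groups,
                          config=NullModelConfig(n_null=99, seed=0), n_boot=50)
    assert [r.group_id for r in res] == ["big"]


def test_nst_monotone_in_selection_strength():
    """Median bootstrap NST never increases along a selection-strength grid."""
    medians = []
    for sigma in (0.0, 0.5, 2.0, 8.0):
        f = make_study_fixture("small", seed=3, selection_strength=sigma,
                               phylosymbiosis_strength=1.0, dispersal_rate=0.0)
        groups = pd.Series("all", index=f.table.sample_ids)
        res = compute_nst(f.table, groups, index="bray",
                          config=NullModelConfig(n_null=99, seed=7), n_boot=200)[0]
        medians.append(np.median(res.nst_bootstrap))
    assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))


# ---------------------------------------------------------------------------
# betaNRI
# ---------------------------------------------------------------------------

def test_star_tree_degenerate_bnri_is_zero():
    tree = parse_tree("(g0:1,g1:1,g2:1,g3:1);")
    tab = _table([[5, 1, 0, 0], [0, 1, 3, 2]])
    with pytest.warns(UserWarning, match="zero-variance"):
        b = compute_bnri(tab, tree, NullModelConfig(n_null=99, seed=0))
    assert (b.to_numpy() == 0).all()


def test_identical_one_taxon_samples_are_degenerate():
    """Two samples carrying only the same tip give betaMPD = 0 under every
    tip shuffle, so the null collapses and the degenerate rule applies."""
    tree = simulate_phylogeny(8, seed=5, tip_prefix="g")
    counts = np.zeros((2, 8), dtype=int)
    counts[:, 0] = 10
    tab = CommunityTable(pd.DataFrame(
        counts, index=["a", "b"], columns=[t.name for t in tree.tips()]))
    with pytest.warns(UserWarning, match="zero-variance"):
        b = compute_bnri(tab, tree, NullModelConfig(n_null=299, seed=1))
    assert b.loc["a", "b"] == 0.0


def test_sister_taxa_concentration_strongly_negative():
    """Samples concentrated on one tight cherry sit far below the shuffle null."""
    tree = parse_tree(
        "((g0:0.1,g1:0.1):1.9,((g2:1,g3:1):1,(g4:1,(g5:1,g6:1):0.5):1):0.2);"
    )
    names = [t.name for t in tree.tips()]
    counts = np.zeros((2, len(names)), dtype=int)
    counts[0, names.index("g0")], counts[0, names.index("g1")] = 10, 8
    counts[1, names.index("g0")], counts[1, names.index("g1")] = 7, 12
    tab = CommunityTable(pd.DataFrame(counts, index=["a", "b"], columns=names))
    b = compute_bnri(tab, tree, NullModelConfig(n_null=299, seed=1))
    assert b.loc["a", "b"] < -2


def test_bnri_invariant_to_branch_scaling():
    f = make_study_fixture("small", seed=2, selection_strength=4.0)
    cfg = NullModelConfig(n_null=99, seed=3)
    b1 = compute_bnri(f.table, f.symbiont_tree, cfg)
    scaled = f.symbiont_tree.copy()
    for node in scaled.traverse(include_self=False):
        node.length = (node.length or 0.0) * 10.0
    b2 = compute_bnri(f.table, scaled, cfg)
    np.testing.assert_allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-8)


def test_bnri_missing_taxa_rejected():
    tree = parse_tree("((g0:1,g1:1):1,g2:2);")
    tab = _table([[1, 2, 3, 4], [4, 3, 2, 1]])
    with pytest.raises(ValueError, match="g3"):
        compute_bnri(tab, tree, NullModelConfig(n_null=99, seed=0))


# ---------------------------------------------------------------------------
# RC_Bray
# ---------------------------------------------------------------------------

def test_identical_samples_rc_minus_one():
    rng = np.random.default_rng(9)
    row = rng.integers(1, 20, size=12)
    counts = np.vstack([row, row, rng.integers(0, 20, size=12)])
    counts[2, counts[2].sum() == 0] = 1
    tab = _table(counts)
    rc = compute_rc_bray(tab, NullModelConfig(n_null=199, seed=9))
    assert rc.loc["s0", "s1"] <= -0.95


def test_disjoint_samples_rc_near_plus_one():
    rng = np.random.default_rng(9)
    n_taxa = 30
    counts = np.zeros((3, n_taxa), dtype=int)
    counts[0, :10] = rng.integers(5, 20, size=10)
    counts[1, 10:20] = rng.integers(5, 20, size=10)
    counts[2, :] = rng.integers(1, 10, size=n_taxa)  # heterogeneous pool donor
    tab = _table(counts)
    rc = compute_rc_bray(tab, NullModelConfig(n_null=199, seed=9))
    assert rc.loc["s0", "s1"] >= 0.9


def test_rc_bounded(neutral_fixture):
    rc = compute_rc_bray(neutral_fixture.table, NullModelConfig(n_null=99, seed=2))
    vals = rc.to_numpy()
    assert (vals >= -1 - 1e-12).all() and (vals <= 1 + 1e-12).all()


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "bnri, rc, expected",
    [
        (-3.0, 0.99, "homogeneous_selection"),
        (3.0, -0.99, "heterogeneous_selection"),
        (0.0, 0.0, "drift"),
        (1.5, 0.99, "dispersal_limitation"),
        (-1.5, -0.99, "homogenizing_dispersal"),
    ],
)
def test_classification_rules(bnri, rc, expected):
    assert classify_pair(bnri, rc) == expected


def test_fractions_sum_to_one(neutral_fixture):
    cfg = NullModelConfig(n_null=99, seed=5)
    part = partition_processes(
        compute_bnri(neutral_fixture.table, neutral_fixture.symbiont_tree, cfg),
        compute_rc_bray(neutral_fixture.table, cfg),
    )
    assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert len(part.pairs) == 30 * 29 // 2


def test_partition_mismatched_ids_rejected():
    a = pd.DataFrame(np.zeros((2, 2)), index=["x", "y"], columns=["x", "y"])
    b = pd.DataFrame(np.zeros((2, 2)), index=["x", "z"], columns=["x", "z"])
    with pytest.raises(ValueError, match="same sample pairs"):
        partition_processes(a, b)
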