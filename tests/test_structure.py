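"""Diversity metrics, ordination, PERMANOVA and matrix regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from mycasm.core import CommunityTable, parse_tree
from mycasm.structure import (
    alpha_diversity,
    beta_diversity,
    factor_dissimilarity,
    group_rank_sum,
    mantel_test,
    mrm_fit,
    pcoa,
    permanova,
    permuted_mrm,
    procrustes_protest,
)


def _table(counts, taxa=None):
    counts = np.asarray(counts)
    return CommunityTable(pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(counts.shape[0])],
        columns=taxa or [f"g{j}" for j in range(counts.shape[1])],
    ))


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def test_alpha_uniform_four_taxa():
    out = alpha_diversity(_table([[5, 5, 5, 5]]))
    assert out.loc["s0", "shannon"] == pytest.approx(np.log(4))
    assert out.loc["s0", "observed"] == 4
    assert out.loc["s0", "simpson"] == pytest.approx(0.75)
    assert out.loc["s0", "invsimpson"] == pytest.approx(4.0)


def test_alpha_single_taxon():
    out = alpha_diversity(_table([[9, 0]]))
    assert out.loc["s0", "shannon"] == pytest.approx(0.0)
    assert out.loc["s0", "simpson"] == pytest.approx(0.0)
    assert out.loc["s0", "observed"] == 1


def test_alpha_matches_direct_formulas(rng):
    counts = rng.integers(1, 40, size=(8, 15))
    out = alpha_diversity(_table(counts))
    for i, row in enumerate(counts):
        p = row / row.sum()
        p = p[p > 0]
        assert out.iloc[i]["shannon"] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
        assert out.iloc[i]["simpson"] == pytest.approx(1 - (p**2).sum(), abs=1e-12)
        assert out.iloc[i]["invsimpson"] == pytest.approx(1 / (p**2).sum(), abs=1e-12)
        assert out.iloc[i]["observed"] == (row > 0).sum()


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("metric", ["bray", "jaccard", "unifrac_unweighted", "unifrac_weighted"])
def test_identical_samples_distance_zero(metric):
    tree = parse_tree("((g0:1,g1:1):1,(g2:1,g3:1):1);")
    tab = _table([[3, 1, 0, 2], [3, 1, 0, 2]])
    d = beta_diversity(tab, metric, tree=tree)
    assert d["s0", "s1"] == pytest.approx(0.0, abs=1e-12)


def test_unweighted_unifrac_disjoint_star_halves():
    # rooted star: two zero-length cherries, all pendant branches equal
    tree = parse_tree("((g0:1,g1:1):0,(g2:1,g3:1):0);")
    tab = _table([[1, 1, 0, 0], [0, 0, 1, 1]])
    d = beta_diversity(tab, "unifrac_unweighted", tree=tree)
    assert d["s0", "s1"] == pytest.approx(1.0)


def test_unweighted_unifrac_hand_tree_single_tips():
    tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
    tab = _table([[1, 0, 0, 0], [0, 0, 1, 0]], taxa=list("ABCD"))
    d = beta_diversity(tab, "unifrac_unweighted", tree=tree)
    # paths root->A and root->C share no branch: (1+1+1+1)/(1+1+1+1) = 1
    assert d["s0", "s1"] == pytest.approx(1.0)


def _branch_union_unifrac(tree, pres_a, pres_b):
    """Brute-force branch enumeration oracle for unweighted UniFrac."""
    shared = unshared = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        in_a = bool(tips & pres_a)
        in_b = bool(tips & pres_b)
        if in_a and in_b:
            shared += node.length
        elif in_a or in_b:
            unshared += node.length
    return unshared / (shared + unshared)


def test_unweighted_unifrac_matches_branch_union_oracle():
    tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
    tab = _table([[1, 1, 0, 0], [1, 0, 1, 0]], taxa=list("ABCD"))
    d = beta_diversity(tab, "unifrac_unweighted", tree=tree)
    oracle = _branch_union_unifrac(tree, {"A", "B"}, {"A", "C"})
    assert d["s0", "s1"] == pytest.approx(oracle)


def test_unifrac_missing_taxon_listed():
    tree = parse_tree("((g0:1,g1:1):1,g2:2);")
    tab = _table([[1, 2, 3, 1], [2, 1, 0, 1]])
    with pytest.raises(ValueError, match="g3"):
        beta_diversity(tab, "unifrac_weighted", tree=tree)


def test_beta_permutation_equivariance(rng):
    counts = rng.integers(1, 20, size=(6, 10))
    tab = _table(counts)
    d = beta_diversity(tab, "bray")
    order = list(rng.permutation(tab.sample_ids))
    tab2 = tab.subset(sample_ids=order)
    d2 = beta_diversity(tab2, "bray")
    np.testing.assert_allclose(d2.filter(tab.sample_ids).data, d.data, atol=1e-12)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_three_equidistant_points():
    d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
                       ids=list("abc"))
    res = pcoa(d)
    assert len(res.eigenvalues) == 2
    assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])


def test_pcoa_recovers_euclidean_configuration(rng):
    pts = rng.normal(size=(12, 2))
    d = DistanceMatrix(squareform(pdist(pts), checks=False),
                       ids=[f"s{i}" for i in range(12)])
    res = pcoa(d)
    fit = procrustes_protest(res.coordinates.to_numpy()[:, :2], pts, n_perm=9, seed=0)
    assert fit.coefficient < 1e-9
    # reconstruction: pairwise distances of the full embedding match the input
    np.testing.assert_allclose(pdist(res.coordinates.to_numpy()), pdist(pts), atol=1e-9)


def test_pcoa_zero_matrix():
    d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
    res = pcoa(d)
    assert len(res.eigenvalues) == 0 or np.allclose(res.eigenvalues, 0)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _clustered_distance(seed=2, n=20, shift=4.0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts[n // 2:, 0] += shift
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({"grp": ["a"] * (n // 2) + ["b"] * (n // 2)}, index=ids)
    return DistanceMatrix(squareform(pdist(pts), checks=False), ids=ids), meta


def test_permanova_separated_clusters():
    d, meta = _clustered_distance(seed=2)
    res = permanova(d, meta, ["grp"], n_perm=199, seed=2)
    assert res.loc["grp", "r_squared"] > 0.5
    assert res.loc["grp", "p_value"] <= 0.01


def test_permanova_duplicate_factor_gets_zero_ss():
    d, meta = _clustered_distance(seed=3)
    meta["grp2"] = meta["grp"]
    res = permanova(d, meta, ["grp", "grp2"], n_perm=49, seed=3)
    assert abs(res.loc["grp2", "ss"]) < 1e-8
    assert res.loc["grp2", "df"] == 0


def test_permanova_single_level_factor_rejected():
    d, meta = _clustered_distance(seed=4)
    meta["const"] = "x"
    with pytest.raises(ValueError, match="const"):
        permanova(d, meta, ["const"], n_perm=49, seed=4)


def test_permanova_r_squared_partition_sums_to_one():
    d, meta = _clustered_distance(seed=5)
    res = permanova(d, meta, ["grp"], n_perm=49, seed=5)
    assert res["r_squared"].sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Mantel / MRM / PROTEST
# ---------------------------------------------------------------------------

def _random_dm(rng, n=12):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts), checks=False),
                          ids=[f"s{i}" for i in range(n)])


def test_mantel_self_and_scale_invariance(rng):
    d = _random_dm(rng)
    r1 = mantel_test(d, d, n_perm=99, seed=0)
    d2 = DistanceMatrix(2.0 * d.data, ids=list(d.ids))
    r2 = mantel_test(d, d2, n_perm=99, seed=0)
    assert r1.coefficient == pytest.approx(1.0)
    assert r2.coefficient == pytest.approx(1.0)
    assert r1.p_value <= 0.05


def test_mantel_zero_variance_rejected():
    d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), ids=list("abc"))
    with pytest.raises(ValueError, match="variance"):
        mantel_test(d, d, n_perm=99, seed=0)


def test_mrm_perfect_predictor(rng):
    d = _random_dm(rng)
    res = mrm_fit(d, {"self": d}, n_perm=99, seed=1)
    assert res.coefficient == pytest.approx(1.0)
    assert res.p_value <= 0.05
    assert res.details.loc["self", "coefficient"] == pytest.approx(1.0)


def test_mrm_collinear_predictors_rejected(rng):
    d = _random_dm(rng)
    d2 = DistanceMatrix(2.0 * d.data, ids=list(d.ids))
    with pytest.raises(ValueError, match="collinear"):
        mrm_fit(d, {"a": d, "b": d2}, n_perm=9, seed=1)


def test_protest_invariances(rng):
    pts = rng.normal(size=(10, 2))
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    assert procrustes_protest(pts, 3.0 * pts @ rot + 5.0, n_perm=9, seed=0).coefficient < 1e-12
    mirror = pts.copy()
    mirror[:, 0] *= -1
    assert procrustes_protest(pts, mirror, n_perm=9, seed=0).coefficient < 1e-12


def test_protest_random_configuration_not_significant(rng):
    a = rng.normal(size=(12, 2))
    b = rng.normal(size=(12, 2))
    res = procrustes_protest(a, b, n_perm=199, seed=3)
    assert res.coefficient > 0.5


# ---------------------------------------------------------------------------
# permuted MRM and rank-sum utility
# ---------------------------------------------------------------------------

def test_permuted_mrm_bookkeeping(phylosym_fixture):
    from mycasm.core import patristic_distances

    v = permuted_mrm(
        phylosym_fixture.table, phylosym_fixture.metadata,
        metrics=("bray",), factors=("species", "gut_type"),
        host_tree_distance=patristic_distances(phylosym_fixture.host_tree),
        n_perm_outer=10, n_perm_inner=49, min_significant=8, seed=2,
    )
    for verdict in v.values():
        assert len(verdict.p_values) == 10
        assert verdict.significant_overall == (verdict.n_significant >= 8)


def test_factor_dissimilarity_encoding():
    meta = pd.DataFrame({"f": ["x", "x", "y"]}, index=["a", "b", "c"])
    d = factor_dissimilarity(meta, "f")
    assert d["a", "b"] == 0.0 and d["a", "c"] == 1.0


def test_group_rank_sum_bh_adjusts():
    values = pd.Series(np.r_[np.zeros(10), np.ones(10), np.full(10, 5.0)])
    groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    out = group_rank_sum(values, groups)
    assert len(out) == 3
    assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()
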