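"""Profiles, Pearson dual-threshold partner sets, clustering, set algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coexkit.containers import ExpressionMatrix, GeneSet
from coexkit.coexpression import (
    CoexpressionError,
    TissueProfiles,
    correlation_matrix,
    correlation_pvalue,
    exclusive_intersections,
    filter_expressed,
    hierarchical_order,
    partner_set,
    pearson_r,
    set_contrast,
    tissue_dendrogram,
    tissue_mean_profiles,
)


def make_profiles(values: np.ndarray, genes=None) -> TissueProfiles:
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tissues = [f"t{j}" for j in range(values.shape[1])]
    return TissueProfiles(values=pd.DataFrame(values, index=genes, columns=tissues))


# ------------------------------------------------------------------ profiles

def test_tissue_mean_is_arithmetic_mean():
    samples = ["a1", "a2", "b1", "b2", "b3"]
    expr = ExpressionMatrix(
        values=pd.DataFrame([[2.0, 4.0, 1.0, 2.0, 6.0]], index=["g"], columns=samples),
        unit="RPKM",
    )
    sm = pd.DataFrame({"tissue": ["A", "A", "B", "B", "B"]}, index=samples)
    prof = tissue_mean_profiles(expr, sm)
    assert prof.values.loc["g", "A"] == 3.0
    assert prof.values.loc["g", "B"] == 3.0


def test_single_replicate_identity():
    expr = ExpressionMatrix(values=pd.DataFrame([[7.5]], index=["g"], columns=["s"]), unit="RPKM")
    sm = pd.DataFrame({"tissue": ["A"]}, index=["s"])
    assert tissue_mean_profiles(expr, sm).values.loc["g", "A"] == 7.5


def test_profiles_require_rpkm():
    expr = ExpressionMatrix(values=pd.DataFrame([[1.0]], index=["g"], columns=["s"]), unit="CPM")
    with pytest.raises(CoexpressionError):
        tissue_mean_profiles(expr, pd.DataFrame({"tissue": ["A"]}, index=["s"]))


def test_expression_floor_is_strict_max_over_tissues():
    prof = make_profiles(np.array([[0.0, 0.0], [6.0, 0.0], [5.0, 5.0]]))
    kept = filter_expressed(prof, min_rpkm=5.0)
    assert list(kept.genes) == ["g1"]  # 5.0 exactly fails the strict bound
    assert list(filter_expressed(prof, min_rpkm=0.0).genes) == ["g1", "g2"]


def test_lowering_floor_never_removes_genes():
    rng = np.random.default_rng(0)
    prof = make_profiles(rng.gamma(2.0, 5.0, size=(50, 6)))
    high = set(filter_expressed(prof, 10.0).genes)
    low = set(filter_expressed(prof, 2.0).genes)
    assert high <= low


# --------------------------------------------------------------- correlation

def test_pearson_hand_values():
    assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)


def test_pearson_zero_variance_errors():
    with pytest.raises(CoexpressionError, match="variance"):
        pearson_r([1, 1, 1], [1, 2, 3])


def test_correlation_pvalue_against_t_tail():
    assert correlation_pvalue(0.0, 11) == pytest.approx(1.0)
    # the study design: n = 11 tissues makes p < 0.001 stricter than r > 0.8
    p85 = correlation_pvalue(0.85, 11)
    p82 = correlation_pvalue(0.82, 11)
    assert p85 == pytest.approx(9.2e-4, rel=0.05)
    assert p85 < 0.001 < p82
    assert p82 == pytest.approx(2e-3, rel=0.2)
    # direct oracle: two-sided Student t tail
    for r, n in [(0.3, 8), (0.6, 11), (-0.9, 5)]:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        assert correlation_pvalue(r, n) == pytest.approx(2 * stats.t.sf(abs(t), n - 2))
    assert correlation_pvalue(1.0, 11) == 0.0
    with pytest.raises(CoexpressionError):
        correlation_pvalue(0.5, 2)


def test_correlation_matrix_matches_pairwise_oracle():
    rng = np.random.default_rng(1)
    prof = make_profiles(rng.gamma(2.0, 10.0, size=(10, 7)))
    mat = correlation_matrix(prof)
    pd.testing.assert_frame_equal(mat.r, mat.r.T)
    np.testing.assert_allclose(np.diag(mat.r), 1.0)
    for a, b in itertools.combinations(range(10), 2):
        expected = pearson_r(prof.values.iloc[a], prof.values.iloc[b])
        assert mat.r.iloc[a, b] == pytest.approx(expected, abs=1e-12)


def test_correlation_matrix_excludes_zero_variance():
    values = np.vstack([np.full(5, 3.0), np.arange(5.0), np.arange(5.0)[::-1]])
    mat = correlation_matrix(make_profiles(values))
    assert mat.zero_variance_genes == ["g0"]
    assert "g0" not in mat.r.index


# --------------------------------------------------------------- partner sets

def test_partner_set_empty_mean_none():
    rng = np.random.default_rng(2)
    prof = make_profiles(rng.permuted(np.tile(np.arange(11.0) + 1, (5, 1)), axis=1))
    group = partner_set(prof, "g0", r_min=0.999, p_max=1e-9)
    assert len(group.partners) == 0 and group.mean_coefficient is None


def test_partner_set_missing_seed_errors():
    prof = make_profiles(np.random.default_rng(0).gamma(2, 5, (4, 11)))
    with pytest.raises(CoexpressionError, match="absent"):
        partner_set(prof, "nope")


def test_partner_relation_symmetric():
    rng = np.random.default_rng(3)
    prof = make_profiles(rng.gamma(2.0, 10.0, size=(30, 11)))
    for a in ["g0", "g5", "g12"]:
        partners_a = partner_set(prof, a, r_min=0.5, p_max=0.05).members
        for b in partners_a:
            assert a in partner_set(prof, b, r_min=0.5, p_max=0.05).members


def test_partner_set_dual_threshold_conjunctive():
    """A pair with r ~ 0.82 (p > 0.001 at n=11) must be excluded even
    though r > 0.8; r ~ 0.86 passes both bounds."""
    rng = np.random.default_rng(8)
    x = rng.normal(10, 3, 11)

    def vector_with_r(target):
        noise = rng.normal(0, 1, 11)
        noise -= np.polyval(np.polyfit(x, noise, 1), x)  # orthogonalize
        xc = (x - x.mean()) / x.std()
        return target * (x - x.mean()) / x.std() + np.sqrt(1 - target**2) * noise / noise.std()

    y_low = vector_with_r(0.82)
    y_high = vector_with_r(0.86)
    base = 50.0
    prof = make_profiles(np.vstack([x, y_low, y_high]) + base)
    r_low = pearson_r(prof.values.loc["g0"], prof.values.loc["g1"])
    r_high = pearson_r(prof.values.loc["g0"], prof.values.loc["g2"])
    assert r_low == pytest.approx(0.82, abs=1e-9)
    assert r_high == pytest.approx(0.86, abs=1e-9)
    members = partner_set(prof, "g0").members
    assert "g1" not in members and "g2" in members


def test_planted_module_partner_recovery(module_sim):
    from coexkit.dge import compute_rpkm

    cfg, cm, truth = module_sim
    prof = filter_expressed(tissue_mean_profiles(compute_rpkm(cm), cm.sample_map), 5.0)
    for m in range(cfg.n_modules):
        members = [g for g in truth.module_genes(m) if g in prof.genes]
        seed = members[0]
        hits = partner_set(prof, seed).members
        tp = len(hits & set(members[1:]))
        assert tp / max(len(hits), 1) >= 0.8  # precision
        assert tp / len(members[1:]) >= 0.8  # recall


# ---------------------------------------------------------------- clustering

def brute_force_average_linkage(points: np.ndarray):
    """Recompute all pairwise average-linkage distances at every step."""
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a] for j in clusters[b]
            ])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_identical_rows_merge_first_at_zero():
    mat = pd.DataFrame([[1.0, 2.0], [5.0, 1.0], [1.0, 2.0]], index=["a", "b", "c"])
    tree = hierarchical_order(mat)
    first = tree.linkage[0]
    assert first[2] == 0.0
    assert {int(first[0]), int(first[1])} == {0, 2}


def test_average_linkage_matches_brute_force_oracle():
    rng = np.random.default_rng(4)
    points = rng.normal(size=(6, 3))
    tree = hierarchical_order(pd.DataFrame(points))
    expected = brute_force_average_linkage(points)
    got = [(row[0], row[1], row[2]) for row in tree.linkage]
    for (ga, gb, gd), (ea, eb, ed) in zip(got, expected):
        assert {int(ga), int(gb)} == {ea, eb}
        assert gd == pytest.approx(ed)


def test_leaf_order_is_permutation():
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(rng.normal(size=(8, 4)), index=[f"x{i}" for i in range(8)])
    tree = hierarchical_order(mat)
    assert sorted(tree.leaf_order) == sorted(mat.index)


def test_tissue_dendrogram_newick():
    rng = np.random.default_rng(6)
    prof = make_profiles(rng.gamma(2, 10, (20, 5)))
    tree = tissue_dendrogram(prof)
    newick = tree.to_newick()
    assert newick.endswith(";")
    for t in prof.tissues:
        assert t in newick
    assert sorted(tree.leaf_order) == sorted(prof.tissues)


# ---------------------------------------------------------------- set algebra

def test_exclusive_intersections_example():
    s1 = GeneSet("S1", {"a", "b", "c"})
    s2 = GeneSet("S2", {"b", "c", "d"})
    counts = exclusive_intersections([s1, s2])
    assert counts == {("S1",): 1, ("S2",): 1, ("S1", "S2"): 2}


def test_single_set_single_signature():
    counts = exclusive_intersections([GeneSet("S", {"x", "y"})])
    assert counts == {("S",): 2}


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.sets(st.integers(0, 30)), min_size=1, max_size=5))
def test_intersections_partition_union(member_lists):
    sets = [GeneSet(f"S{i}", {str(x) for x in m}) for i, m in enumerate(member_lists)]
    counts = exclusive_intersections(sets)
    union = set().union(*(s.members for s in sets))
    assert sum(counts.values()) == len(union)
    # brute-force membership scan
    for signature, count in counts.items():
        sig = set(signature)
        expected = sum(
            1 for g in union
            if {s.name for s in sets if g in s.members} == sig
        )
        assert count == expected


def test_set_contrast():
    a = GeneSet("A", {"1", "2", "3"})
    b = GeneSet("B", {"2", "3", "4"})
    shared, a_only, b_only = set_contrast(a, b)
    assert shared == {"2", "3"} and a_only == {"1"} and b_only == {"4"}
    shared, a_only, _ = set_contrast(GeneSet("A", {"1"}), GeneSet("B", {"1", "2"}))
    assert a_only == frozenset()
    shared, *_ = set_contrast(GeneSet("A", {"1"}), GeneSet("B", {"2"}))
    assert shared == frozenset()
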