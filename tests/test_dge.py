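"""Normalization identities, NB test behavior, and selection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexkit.containers import CountMatrix
from coexkit.dge import (
    DGEError,
    DGEResult,
    bh_adjust,
    compute_cpm,
    compute_rpkm,
    enrichment_score,
    estimate_common_dispersion,
    nb_pairwise_test,
    nb_test_table,
    run_dge,
    select_enriched,
    tmm_factors,
)
from coexkit.simulate import nb_counts


def make_cm(counts: np.ndarray, lengths=None) -> CountMatrix:
    counts = np.atleast_2d(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    sm = pd.DataFrame(
        {"tissue": "T", "genotype": "wt", "replicate": range(1, counts.shape[1] + 1)},
        index=pd.Index(samples, name="sample"),
    )
    gl = pd.Series(lengths, index=genes) if lengths is not None else None
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), sm, gl)


# ------------------------------------------------------------------ CPM/RPKM

def test_cpm_definition():
    cm = make_cm(np.array([[1], [1]]))
    assert compute_cpm(cm).values.iloc[:, 0].tolist() == [500000.0, 500000.0]
    cm = make_cm(np.array([[3], [7]]))
    assert compute_cpm(cm).values.iloc[:, 0].tolist() == [300000.0, 700000.0]
    cm = make_cm(np.array([[0], [10]]))
    assert compute_cpm(cm).values.iloc[0, 0] == 0.0


def test_cpm_columns_sum_to_million(tiny_counts):
    cpm = compute_cpm(tiny_counts)
    np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6)


def test_cpm_all_zero_column_errors():
    cm = make_cm(np.array([[0, 1], [0, 1]]))
    with pytest.raises(DGEError, match="s0"):
        compute_cpm(cm)


def test_rpkm_unit_definition():
    cm = make_cm(np.array([[10], [0]]) * np.array([[1], [1]]), lengths=[1000, 500])
    # pad library to 1e6 with a filler gene
    counts = np.array([[10], [0], [1_000_000 - 10]])
    cm = make_cm(counts, lengths=[1000, 500, 1000])
    rpkm = compute_rpkm(cm)
    assert rpkm.values.iloc[0, 0] == pytest.approx(10.0)
    assert rpkm.values.iloc[1, 0] == 0.0
    # count 20, length 500 bp, library 2e6 -> RPKM 20
    counts = np.array([[20], [2_000_000 - 20]])
    cm = make_cm(counts, lengths=[500, 1000])
    assert compute_rpkm(cm).values.iloc[0, 0] == pytest.approx(20.0)


def test_rpkm_requires_lengths():
    cm = make_cm(np.array([[1], [2]]))
    with pytest.raises(DGEError, match="lengths"):
        compute_rpkm(cm)


# ----------------------------------------------------------------------- TMM

def test_tmm_identical_columns_unity():
    rng = np.random.default_rng(0)
    col = rng.poisson(50, size=200)
    cm = make_cm(np.column_stack([col, col, col]))
    np.testing.assert_allclose(tmm_factors(cm).to_numpy(), 1.0)


def test_tmm_proportional_columns_unity():
    rng = np.random.default_rng(1)
    col = rng.poisson(100, size=300) + 1
    cm = make_cm(np.column_stack([col, 2 * col]))
    np.testing.assert_allclose(tmm_factors(cm).to_numpy(), 1.0, atol=1e-12)


def test_tmm_geometric_mean_is_one():
    rng = np.random.default_rng(2)
    counts = rng.negative_binomial(5, 0.05, size=(500, 6))
    cm = make_cm(counts)
    f = tmm_factors(cm).to_numpy()
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------- dispersion

def test_single_gene_identical_replicates_phi_zero():
    cm = make_cm(np.array([[40, 40, 40]]))
    assert estimate_common_dispersion(cm, groups={"s0": "A", "s1": "A", "s2": "A"}) == 0.0


def test_dispersion_requires_replication():
    cm = make_cm(np.array([[3, 5]]))
    with pytest.raises(DGEError, match="phi"):
        estimate_common_dispersion(cm, groups={"s0": "A", "s1": "B"})


def test_poisson_data_yields_near_zero_dispersion():
    rng = np.random.default_rng(3)
    mu = rng.lognormal(np.log(100), 1.0, 2000)
    counts = rng.poisson(mu[:, None] * np.ones(6))
    cm = make_cm(counts)
    phi = estimate_common_dispersion(cm, groups={f"s{j}": ("A" if j < 3 else "B") for j in range(6)})
    assert phi < 0.01


# ------------------------------------------------------------------- NB test

def test_identical_groups_equal_libraries_logfc_zero():
    logfc, logcpm, p = nb_pairwise_test(
        [30, 30, 30, 30], [0, 1], [2, 3], np.full(4, 1e6), phi=0.1
    )
    assert logfc == pytest.approx(0.0)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_all_zero_gene_flagged():
    logfc, logcpm, p = nb_pairwise_test([0, 0, 0, 0], [0, 1], [2, 3], np.full(4, 1e6), phi=0.1)
    assert p == 1.0 and logfc == 0.0


def test_nb_test_detects_planted_shift():
    """>= 80% of genes with a planted 4-fold shift reach p < 0.01 (phi=0.1, 3v3)."""
    rng = np.random.default_rng(4)
    mu = rng.lognormal(np.log(200), 0.5, 500)
    mu_b = mu * 4.0
    counts = np.column_stack([
        nb_counts(rng, np.tile(mu, (3, 1)).T, 0.1),
        nb_counts(rng, np.tile(mu_b, (3, 1)).T, 0.1),
    ])
    eff = np.full(6, counts.sum() / 6)
    tab = nb_test_table(counts, np.arange(3), np.arange(3, 6), eff, 0.1)
    assert (tab.pvalue < 0.01).mean() >= 0.80
    assert (tab.logFC > 0).mean() > 0.95


def test_nb_test_empty_group_rejected():
    with pytest.raises(DGEError):
        nb_pairwise_test([1, 2], [], [0, 1], np.ones(2), 0.1)


# ------------------------------------------------------------------- run_dge

def test_run_dge_internal(tiny_counts):
    res = run_dge(tiny_counts, contrast=("A", "B"), phi=0.05, use_tmm=False)
    assert set(res.table.columns) >= {"logFC", "logCPM", "pvalue", "padj"}
    # g1 quadruples A->B, g4 drops: signs must reflect the contrast orientation
    assert res.table.loc["g1", "logFC"] > 0
    assert res.table.loc["g4", "logFC"] < 0
    assert (res.table["padj"] >= res.table["pvalue"] - 1e-12).all()


def test_run_dge_external_round_trip():
    table = pd.DataFrame(
        {"gene": ["a", "b"], "logFC": [1.5, -2.0], "logCPM": [3.0, 4.0], "pvalue": [0.001, 0.5]}
    )
    res = run_dge(None, contrast=("wt", "mut"), method="external_table", table=table)
    assert res.table.loc["a", "logFC"] == 1.5
    assert res.table.loc["b", "pvalue"] == 0.5
    np.testing.assert_allclose(res.table["padj"], bh_adjust([0.001, 0.5]))


def test_run_dge_external_deseq2_style_columns():
    table = pd.DataFrame(
        {"gene": ["a"], "log2FoldChange": [2.0], "baseMean": [8.0], "pvalue": [0.01]}
    )
    res = run_dge(None, contrast=("wt", "mut"), method="external_table", table=table)
    assert res.table.loc["a", "logFC"] == 2.0
    assert res.table.loc["a", "logCPM"] == pytest.approx(3.0)  # log2(8)


def test_run_dge_external_missing_columns():
    with pytest.raises(DGEError, match="missing"):
        run_dge(None, contrast=("wt", "mut"), method="external_table",
                table=pd.DataFrame({"gene": ["a"], "logFC": [1.0]}))


# ----------------------------------------------------------------- selection

def test_enrichment_score_product():
    assert enrichment_score(8.0, 5.9) == pytest.approx(47.2)
    assert enrichment_score(0.0, 3.0) == 0.0
    # strictly increasing in logFC at fixed positive logCPM
    scores = enrichment_score(np.array([1.0, 2.0, 3.0]), 2.5)
    assert np.all(np.diff(scores) > 0)


def make_result(rows: dict) -> DGEResult:
    tab = pd.DataFrame(rows, index=["logFC", "logCPM", "pvalue"]).T
    tab["padj"] = bh_adjust(tab["pvalue"].to_numpy())
    return DGEResult(table=tab, contrast=("ref", "test"))


def test_select_enriched_filter():
    res = make_result({"g1": (1, 2, 0.001), "g2": (1, 2, 0.02), "g3": (-1, 2, 0.001)})
    assert select_enriched(res).members == {"g1"}
    assert select_enriched(res, direction="down").members == {"g3"}


def test_select_enriched_strict_inequalities():
    res = make_result({"g1": (0.0, 2, 0.001), "g2": (1, 0.0, 0.001), "g3": (1, 2, 0.01)})
    assert select_enriched(res, p_max=0.01).members == set()


@settings(derandomize=True, max_examples=30)
@given(
    p1=st.floats(0.001, 0.5),
    p2=st.floats(0.001, 0.5),
)
def test_select_enriched_monotone_in_p_threshold(p1, p2):
    res = make_result({f"g{i}": (1.0, 1.0, p) for i, p in enumerate([0.0005, 0.005, 0.05, 0.3])})
    lo, hi = sorted([p1, p2])
    assert select_enriched(res, p_max=lo).members <= select_enriched(res, p_max=hi).members


# ------------------------------------------------------------------------ BH

def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up definition computed directly."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_bh_matches_step_up_definition(pvals):
    p = np.array(pvals)
    np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_bh_monotone_in_p_rank():
    p = np.array([0.04, 0.001, 0.2, 0.01])
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
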