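"""Normalization and simplified negative-binomial differential expression.

The per-gene test is a likelihood-ratio test of equal NB means between two
sample groups, with a single common dispersion phi shared by all genes and
log effective library sizes as offsets (variance mu + phi*mu^2, the usual
count-model convention).  It reports the same three statistics the
surrounding selection rules operate on -- logFC, logCPM and a chi-square
P-value -- without reproducing any particular tool's internals; externally
computed result tables are accepted as a drop-in alternative source.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

PRIOR_COUNT = 0.5


class DGEError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_cpm(
    counts: CountMatrix,
    effective_library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """Counts per million: count / column_total * 1e6.

    With *effective_library_sizes* (e.g. TMM-adjusted) those totals are used
    instead of the raw column sums, and the result is tagged TMM-normalized.
    """
    if effective_library_sizes is None:
        totals = counts.library_sizes
        norm = "none"
    else:
        totals = effective_library_sizes.reindex(counts.samples)
        norm = "TMM"
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise DGEError(f"all-zero library for sample(s): {zero}")
    values = counts.counts / totals * 1e6
    return ExpressionMatrix(values=values, unit="CPM", normalization=norm)


def compute_rpkm(
    counts: CountMatrix,
    effective_library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase per million: count / (length_kb * total_millions)."""
    if counts.gene_lengths is None:
        raise DGEError("RPKM requires gene lengths")
    lengths = counts.gene_lengths.reindex(counts.genes)
    missing = lengths.index[lengths.isna()].tolist()
    if missing:
        raise DGEError(f"genes missing lengths: {missing[:10]}")
    cpm = compute_cpm(counts, effective_library_sizes)
    values = cpm.values.div(lengths / 1e3, axis=0)
    return ExpressionMatrix(values=values, unit="RPKM", normalization=cpm.normalization)


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (Robinson-Oshlack).

    The reference sample is the column whose 75th count-fraction percentile
    is closest to the mean across samples.  For each sample, log2 ratios (M)
    against the reference are doubly trimmed -- `logratio_trim` on each M
    tail, `abs_trim` on each average-abundance tail -- and averaged with
    precision weights.  Factors are rescaled to geometric mean 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    if np.any(libs <= 0):
        raise DGEError("TMM undefined with an all-zero sample")
    frac = mat / libs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f75 = np.array([np.quantile(frac[:, j][mat[:, j] > 0], 0.75) if (mat[:, j] > 0).any() else 0.0
                        for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        keep = (mat[:, j] > 0) & (mat[:, ref] > 0)
        if not keep.any():
            warnings.warn(f"no genes usable for TMM in sample {counts.samples[j]!r}; factor set to 1")
            continue
        y, r = mat[keep, j], mat[keep, ref]
        nj, nr = libs[j], libs[ref]
        m = np.log2((y / nj) / (r / nr))
        a = 0.5 * np.log2((y / nj) * (r / nr))
        w = (nj - y) / (nj * y) + (nr - r) / (nr * r)
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        if m.size == 0:
            warnings.warn(f"sample {counts.samples[j]!r}: nothing survives TMM trimming; factor 1")
            continue
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_trim, 1 - abs_trim])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            warnings.warn(f"sample {counts.samples[j]!r}: nothing survives TMM trimming; factor 1")
            continue
        wsel = w[sel]
        with np.errstate(divide="ignore", invalid="ignore"):
            weights = np.where(wsel > 0, 1.0 / wsel, 0.0)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        factors[j] = 2 ** (np.sum(weights * m[sel]) / np.sum(weights))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


def effective_library_sizes(counts: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(counts)
    return counts.library_sizes * factors.reindex(counts.samples)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# NB likelihood machinery
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Row sums of the NB log-likelihood; Poisson limit at phi == 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    if phi <= 0:
        ll = y * np.log(mu) - mu - special.gammaln(y + 1)
    else:
        r = 1.0 / phi
        ll = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + y * np.log(mu / (mu + r))
            + r * np.log(r / (r + mu))
        )
    return ll.sum(axis=-1)


def _fit_group_means(y: np.ndarray, sizes: np.ndarray, phi: float, n_iter: int = 25) -> np.ndarray:
    """Per-row MLE of the common rate m (mu_i = m * s_i) for NB(phi).

    Solves sum_i (y_i - m s_i) / (1 + phi m s_i) = 0 by damped Newton on
    log m, vectorized across rows.  phi = 0 reduces to sum(y)/sum(s).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    s = np.asarray(sizes, dtype=float)
    m = y.sum(axis=1) / s.sum()
    if phi <= 0:
        return m
    pos = m > 0
    logm = np.where(pos, np.log(np.maximum(m, 1e-300)), 0.0)
    for _ in range(n_iter):
        mu = np.exp(logm)[:, None] * s
        denom = 1.0 + phi * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(mu * (1.0 + phi * y) / denom**2).sum(axis=1)
        step = np.where(fp != 0, f / fp, 0.0)
        step = np.clip(step, -5.0, 5.0)
        logm = np.where(pos, logm - step, logm)
        if np.max(np.abs(step[pos])) < 1e-12 if pos.any() else True:
            break
    return np.where(pos, np.exp(logm), 0.0)


def estimate_common_dispersion(
    counts: CountMatrix,
    groups: pd.Series | dict | None = None,
    by: str = "tissue",
    phi_max: float = 5.0,
) -> float:
    """Common NB dispersion maximizing the Cox-Reid adjusted profile likelihood.

    Group means are profiled out at their MLE for each candidate phi; the
    adjustment term 0.5*log(sum_i mu_i/(1+phi*mu_i)) per gene and group
    counters the downward bias of the plain profile MLE.  Result clipped
    at 0.  Raises unless at least one group has >= 2 replicates.
    """
    if groups is None:
        meta = counts.sample_map.loc[counts.samples, by]
        groups = {s: meta[s] for s in counts.samples}
    elif not isinstance(groups, dict):
        groups = dict(pd.Series(groups))
    labels: dict[str, list[str]] = {}
    for s, g in groups.items():
        labels.setdefault(g, []).append(s)
    if not any(len(v) >= 2 for v in labels.values()):
        raise DGEError(
            "common-dispersion estimation needs a group with >= 2 replicates; "
            "supply phi explicitly instead"
        )
    libs = counts.library_sizes
    blocks = []
    for members in labels.values():
        if len(members) < 2:
            continue
        y = counts.counts[members].to_numpy(dtype=float)
        s = libs[members].to_numpy(dtype=float)
        s = s / s.mean()
        keep = y.sum(axis=1) > 0
        if keep.any():
            blocks.append((y[keep], s))
    if not blocks:
        return 0.0

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        total = 0.0
        for y, s in blocks:
            m = _fit_group_means(y, s, phi)
            mu = m[:, None] * s
            ll = _nb_loglik(y, mu, phi)
            info = (mu / (1.0 + phi * mu)).sum(axis=1)
            total += float(np.sum(ll - 0.5 * np.log(np.maximum(info, 1e-300))))
        return -total

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log(1e-6), np.log(phi_max)), method="bounded",
        options={"xatol": 1e-4},
    )
    phi_hat = float(np.exp(res.x))
    # boundary check: if the likelihood keeps improving toward phi -> 0,
    # report 0 (Poisson)
    if phi_hat <= 2e-6 or neg_apl(np.log(1e-6)) <= res.fun:
        return 0.0
    return phi_hat


def _augmented_cpm(y: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Per-sample CPM with a library-size-proportional prior count added."""
    sizes = np.asarray(sizes, dtype=float)
    prior = PRIOR_COUNT * sizes / sizes.mean()
    return (np.atleast_2d(y) + prior) / sizes * 1e6


def nb_test_table(
    counts: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    effective_sizes: np.ndarray,
    phi: float,
) -> pd.DataFrame:
    """Vectorized NB LRT over all genes for one A-vs-B contrast.

    Returns columns logFC (log2 B/A on prior-augmented CPM), logCPM,
    pvalue, flagged (all-zero genes: p = 1, logFC = 0).
    """
    y = np.asarray(counts, dtype=float)
    s = np.asarray(effective_sizes, dtype=float)
    ya, yb = y[:, idx_a], y[:, idx_b]
    sa, sb = s[idx_a], s[idx_b]
    yab = np.concatenate([ya, yb], axis=1)
    sab = np.concatenate([sa, sb])

    m0 = _fit_group_means(yab, sab, phi)
    ma = _fit_group_means(ya, sa, phi)
    mb = _fit_group_means(yb, sb, phi)
    ll0 = _nb_loglik(yab, m0[:, None] * sab, phi)
    ll1 = _nb_loglik(ya, ma[:, None] * sa, phi) + _nb_loglik(yb, mb[:, None] * sb, phi)
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    pvalue = stats.chi2.sf(lrt, df=1)

    cpm_a = _augmented_cpm(ya, sa).mean(axis=1)
    cpm_b = _augmented_cpm(yb, sb).mean(axis=1)
    logfc = np.log2(cpm_b / cpm_a)
    logcpm = np.log2(_augmented_cpm(yab, sab).mean(axis=1))

    flagged = yab.sum(axis=1) == 0
    pvalue = np.where(flagged, 1.0, pvalue)
    logfc = np.where(flagged, 0.0, logfc)
    return pd.DataFrame(
        {"logFC": logfc, "logCPM": logcpm, "pvalue": pvalue, "flagged": flagged}
    )


def nb_pairwise_test(
    counts_gene,
    group_a,
    group_b,
    effective_library_sizes,
    phi: float,
) -> tuple[float, float, float]:
    """Single-gene NB likelihood-ratio test.

    *counts_gene* holds the gene's counts ordered as group A then group B
    sample positions given by *group_a* / *group_b* index lists into
    *effective_library_sizes*.  Returns (logFC, logCPM, pvalue); logFC > 0
    means higher in group B.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise DGEError("both groups must be non-empty")
    if phi < 0:
        raise DGEError("phi must be >= 0")
    y = np.asarray(counts_gene, dtype=float)[None, :]
    tab = nb_test_table(
        y,
        np.asarray(group_a, dtype=int),
        np.asarray(group_b, dtype=int),
        np.asarray(effective_library_sizes, dtype=float),
        phi,
    )
    row = tab.iloc[0]
    return float(row.logFC), float(row.logCPM), float(row.pvalue)


# ---------------------------------------------------------------------------
# contrast driver
# ---------------------------------------------------------------------------

@dataclass
class DGEResult:
    """Per-gene statistics for one pairwise contrast (reference, test).

    logFC is log2(test/reference); padj is Benjamini-Hochberg across all
    tested genes of the contrast.
    """

    table: pd.DataFrame  # index gene; logFC, logCPM, pvalue, padj
    contrast: tuple[str, str]
    method: str = "internal_nb"
    dispersion: float | None = None

    def __post_init__(self) -> None:
        required = {"logFC", "logCPM", "pvalue", "padj"}
        missing = required - set(self.table.columns)
        if missing:
            raise DGEError(f"DGE table missing columns: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index


EXTERNAL_COLUMN_ALIASES = {
    "logfc": "logFC",
    "log2foldchange": "logFC",
    "logcpm": "logCPM",
    "pvalue": "pvalue",
    "p.value": "pvalue",
    "padj": "padj",
    "fdr": "padj",
    "gene": "gene",
}


def normalize_external_table(table: pd.DataFrame) -> pd.DataFrame:
    """Map edgeR-style / DESeq2-style column names onto the internal schema.

    `baseMean` (DESeq2) is converted to a logCPM-like abundance via log2.
    """
    renames = {}
    for col in table.columns:
        key = col.strip().lower()
        if key in EXTERNAL_COLUMN_ALIASES:
            renames[col] = EXTERNAL_COLUMN_ALIASES[key]
    out = table.rename(columns=renames).copy()
    if "logCPM" not in out.columns and "baseMean" in out.columns:
        with np.errstate(divide="ignore"):
            out["logCPM"] = np.log2(out["baseMean"].astype(float))
    required = {"gene", "logFC", "logCPM", "pvalue"}
    missing = required - set(out.columns)
    if missing:
        raise DGEError(f"external DGE table missing columns: {sorted(missing)}")
    return out.set_index("gene")[[c for c in ("logFC", "logCPM", "pvalue", "padj") if c in out.columns]]


def run_dge(
    counts: CountMatrix | None,
    contrast: tuple[str, str],
    method: str = "internal_nb",
    by: str = "tissue",
    phi: float | None = None,
    use_tmm: bool = True,
    table: pd.DataFrame | None = None,
    recompute_padj: bool = False,
) -> DGEResult:
    """Produce a complete DGEResult for one (reference, test) contrast.

    method="internal_nb" runs the NB LRT on *counts*; method="external_table"
    ingests an externally computed table (values preserved; padj recomputed
    only on request or when absent).
    """
    reference, test = contrast
    if method == "external_table":
        if table is None:
            raise DGEError("external_table method requires a table")
        tab = normalize_external_table(table.reset_index() if "gene" not in table.columns and table.index.name == "gene" else table)
        if "padj" not in tab.columns or recompute_padj:
            tab = tab.copy()
            tab["padj"] = bh_adjust(tab["pvalue"].to_numpy())
        return DGEResult(table=tab, contrast=contrast, method="external_table")

    if method != "internal_nb":
        raise DGEError(f"unknown method {method!r}")
    if counts is None:
        raise DGEError("internal_nb requires counts")
    samples_a = counts.samples_in_group(reference, by=by)
    samples_b = counts.samples_in_group(test, by=by)
    if not samples_a or not samples_b:
        raise DGEError(f"contrast groups empty: {reference!r} n={len(samples_a)}, {test!r} n={len(samples_b)}")
    if use_tmm:
        eff = effective_library_sizes(counts)
    else:
        eff = counts.library_sizes.astype(float)
    if phi is None:
        sub = {s: ("A" if s in samples_a else "B") for s in samples_a + samples_b}
        phi = estimate_common_dispersion(counts, groups=sub)
    pos = {s: i for i, s in enumerate(counts.samples)}
    idx_a = np.array([pos[s] for s in samples_a])
    idx_b = np.array([pos[s] for s in samples_b])
    tab = nb_test_table(counts.counts.to_numpy(), idx_a, idx_b, eff.to_numpy(dtype=float), phi)
    tab.index = counts.genes
    tab["padj"] = bh_adjust(tab["pvalue"].to_numpy())
    return DGEResult(table=tab, contrast=contrast, method="internal_nb", dispersion=phi)


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def enrichment_score(logfc, logcpm):
    """Tissue-enrichment ranking score: the product logFC * logCPM.

    Meaningful for ranking only among genes with logFC > 0 and logCPM > 0
    (both factors positive), where it rewards jointly large fold change and
    abundance.
    """
    return np.asarray(logfc, dtype=float) * np.asarray(logcpm, dtype=float)


def select_enriched(
    dge: DGEResult,
    p_max: float = 0.01,
    min_logfc: float = 0.0,
    min_logcpm: float = 0.0,
    direction: str = "up",
    use_padj: bool = False,
    name: str | None = None,
) -> GeneSet:
    """Genes passing the strict-threshold selection rule.

    Membership requires p < p_max AND logCPM > min_logcpm AND
    logFC > min_logfc (direction="up") or logFC < -min_logfc ("down").
    All inequalities strict.
    """
    tab = dge.table
    p = tab["padj"] if use_padj else tab["pvalue"]
    mask = (p < p_max) & (tab["logCPM"] > min_logcpm)
    if direction == "up":
        mask &= tab["logFC"] > min_logfc
    elif direction == "down":
        mask &= tab["logFC"] < -min_logfc
    else:
        raise DGEError(f"direction must be 'up' or 'down', got {direction!r}")
    label = name or f"{dge.contrast[1]}_{direction}"
    return GeneSet(
        name=label,
        members=frozenset(tab.index[mask]),
        provenance=(
            f"contrast={dge.contrast[0]}->{dge.contrast[1]} direction={direction} "
            f"p<{p_max} logFC>{min_logfc} logCPM>{min_logcpm} "
            f"{'padj' if use_padj else 'raw p'}"
        ),
    )
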