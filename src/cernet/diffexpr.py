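"""Normalization and two-group differential expression for count data.

The A-ED vs NC comparison is run per RNA class with:

* FPKM (for descriptive expression levels, given feature lengths);
* TMM (trimmed mean of M-values) scaling factors for between-sample
  normalization;
* a negative-binomial exact conditional test with a common dispersion
  estimated by method of moments.  Group sums are modelled NB (a sum of n
  i.i.d. NB(mu, phi) variables is NB(n*mu, phi/n)); conditioning on the total
  gives a one-dimensional discrete distribution that is enumerated exactly,
  and the two-sided p-value doubles the smaller tail (observed point
  included), capped at 1.  This is a self-contained, calibration-tested
  replacement for an edgeR-style analysis; numerical agreement with edgeR is
  not a goal.

Feature-selection filters follow the study design: differential expression at
|log2FC| > 2 and p < 0.05 for miRNA/mRNA (strict inequalities), and a
qPCR-friendly lncRNA candidate window of mean raw count strictly between
1 and 120 with fold change > 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .seqio import GROUP_CASE, GROUP_CONTROL, ExpressionMatrix, ValidationError

DE_COLUMNS = [
    "feature_id",
    "rna_class",
    "mean_nc",
    "mean_aed",
    "mean_count",
    "log2fc",
    "p",
    "fdr",
    "direction",
    "passes_de",
    "passes_candidate_window",
]


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors and effective library sizes."""

    factors: pd.Series
    lib_sizes: pd.Series
    method: str = "TMM"

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.factors * self.lib_sizes


def fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    FPKM_gs = counts_gs * 1e9 / (length_g * library_s) with library_s the
    column sum of raw counts.
    """
    if matrix.lengths is None or matrix.lengths.isna().any():
        missing = (
            matrix.features
            if matrix.lengths is None
            else list(matrix.lengths.index[matrix.lengths.isna()])
        )
        raise ValidationError(f"feature lengths required for FPKM; missing: {missing[:5]}")
    if (matrix.lengths <= 0).any():
        bad = list(matrix.lengths.index[matrix.lengths <= 0])
        raise ValidationError(f"non-positive feature lengths: {bad[:5]}")
    lib = matrix.counts.sum(axis=0).astype(float)
    return (
        matrix.counts.astype(float)
        .div(matrix.lengths, axis=0)
        .div(lib, axis=1)
        * 1e9
    )


def normalization_factors(
    matrix: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """TMM scaling factors, renormalized to geometric mean 1.

    The reference is the sample whose 75th CPM percentile is closest to the
    mean of those percentiles.  Per sample, M-values (log2 depth-adjusted
    ratios vs the reference) are trimmed by ``trim_m`` on each tail and
    A-values (average log intensity) by ``trim_a``; the factor is the
    precision-weighted mean of surviving M-values (delta-method binomial
    weights, as in standard TMM).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValidationError("need at least 2 samples for normalization")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [matrix.samples[i] for i in np.nonzero(lib == 0)[0]]
        raise ValidationError(f"all-zero samples: {bad}")
    cpm = counts / lib * 1e6
    q75 = np.quantile(cpm, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    log2_factors = np.zeros(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        y_s, y_r = counts[:, s], counts[:, ref]
        ok = (y_s > 0) & (y_r > 0)
        if not ok.any():
            continue
        p_s, p_r = y_s[ok] / lib[s], y_r[ok] / lib[ref]
        m = np.log2(p_s / p_r)
        a = 0.5 * np.log2(p_s * p_r)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            continue
        var = (lib[s] - y_s[ok]) / (lib[s] * y_s[ok]) + (lib[ref] - y_r[ok]) / (
            lib[ref] * y_r[ok]
        )
        w = np.where(var > 0, 1.0 / np.maximum(var, 1e-12), 0.0)[keep]
        if w.sum() == 0:
            continue
        log2_factors[s] = np.average(m[keep], weights=w)
    log2_factors = log2_factors - log2_factors.mean()  # geometric mean 1
    return NormalizationFactors(
        factors=pd.Series(2.0 ** log2_factors, index=matrix.samples),
        lib_sizes=pd.Series(lib, index=matrix.samples),
    )


def normalized_counts(
    matrix: ExpressionMatrix, factors: NormalizationFactors
) -> pd.DataFrame:
    """Counts rescaled to a common effective library size (its geometric mean)."""
    eff = factors.effective_lib_sizes.reindex(matrix.samples).to_numpy()
    scale = np.exp(np.mean(np.log(eff)))
    return matrix.counts * (scale / eff)


def log_expression(
    matrix: ExpressionMatrix, factors: NormalizationFactors | None = None
) -> pd.DataFrame:
    """log2(normalized count + 0.5): the expression scale used for
    co-expression screening (tames NB skew and removes depth differences)."""
    if factors is None:
        factors = normalization_factors(matrix)
    return np.log2(normalized_counts(matrix, factors) + 0.5)


def estimate_common_dispersion(
    norm: pd.DataFrame, groups: pd.Series, floor: float = 1e-8
) -> float:
    """Method-of-moments common NB dispersion pooled over features and groups.

    With var = mu + phi*mu^2, per feature/group the excess of the sample
    variance over the sample mean estimates phi*mu^2; summing numerators and
    (bias-corrected) denominators over all features gives a pooled ratio
    estimator, floored at ``floor``.
    """
    num = 0.0
    den = 0.0
    for g in (GROUP_CASE, GROUP_CONTROL):
        cols = groups.index[groups == g]
        x = norm[cols].to_numpy(dtype=float)
        n = x.shape[1]
        if n < 2:
            continue
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2 - v / n))
    if den <= 0:
        return floor
    return max(num / den, floor)


def _nb_logpmf(y: np.ndarray, r: float, mu: float) -> np.ndarray:
    log_p = np.log(r / (r + mu))
    log_q = np.log(mu / (r + mu)) if mu > 0 else -np.inf
    return gammaln(y + r) - gammaln(r) - gammaln(y + 1) + r * log_p + y * log_q


def _exact_p(y_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided NB exact conditional p for group-A sum given the total."""
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    y = np.arange(total + 1)
    logf = _nb_logpmf(y, n_a / phi, n_a * mu) + _nb_logpmf(
        y[::-1], n_b / phi, n_b * mu
    )
    logf -= logsumexp(logf)
    f = np.exp(logf)
    lower = float(f[: y_a + 1].sum())
    upper = float(f[y_a:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def exact_test(
    matrix: ExpressionMatrix,
    factors: NormalizationFactors | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-feature NB exact conditional test of equal group means.

    Returns a DataFrame with one row per feature: normalized group means,
    log2 fold change (A-ED over NC, pseudocount 0.5), two-sided p, BH FDR
    (within this matrix's RNA class) and direction.  With a single sample in
    either group p is set to 1.  ``passes_de`` / ``passes_candidate_window``
    start False and are set by the filter operations.
    """
    if factors is None:
        factors = normalization_factors(matrix)
    norm = normalized_counts(matrix, factors)
    a_cols = matrix.samples_in_group(GROUP_CASE)
    b_cols = matrix.samples_in_group(GROUP_CONTROL)
    n_a, n_b = len(a_cols), len(b_cols)
    degenerate = n_a < 2 or n_b < 2
    if dispersion is None:
        phi = estimate_common_dispersion(norm, matrix.groups)
    else:
        if dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        phi = dispersion

    sum_a = norm[a_cols].sum(axis=1).to_numpy()
    sum_b = norm[b_cols].sum(axis=1).to_numpy()
    y_a = np.round(sum_a).astype(np.int64)
    y_b = np.round(sum_b).astype(np.int64)
    mean_a = sum_a / max(n_a, 1)
    mean_b = sum_b / max(n_b, 1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    if degenerate:
        p = np.ones(len(y_a))
    else:
        p = np.array(
            [_exact_p(int(ya), int(ya + yb), n_a, n_b, phi) for ya, yb in zip(y_a, y_b)]
        )
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature_id": matrix.features,
            "rna_class": matrix.rna_class,
            "mean_nc": mean_b,
            "mean_aed": mean_a,
            "mean_count": matrix.counts.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc < 0, "down", "up"),
            "passes_de": False,
            "passes_candidate_window": False,
        },
        columns=DE_COLUMNS,
    )


def apply_de_filter(
    results: pd.DataFrame, lfc_threshold: float = 2.0, p_threshold: float = 0.05,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Flag differentially expressed features: |log2FC| > lfc AND p < alpha.

    Both inequalities are strict (a feature at p = 0.05 exactly is excluded).
    ``use_fdr`` switches the p column to the BH-adjusted one.
    """
    pcol = "fdr" if use_fdr else "p"
    out = results.copy()
    out["passes_de"] = (out["log2fc"].abs() > lfc_threshold) & (out[pcol] < p_threshold)
    return out


def select_candidate_lncrnas(
    results: pd.DataFrame,
    count_low: float = 1.0,
    count_high: float = 120.0,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """qPCR candidate window for lncRNAs.

    Keeps features with mean raw count strictly between ``count_low`` and
    ``count_high``, fold change > 2 (|log2FC| > 1) and p < 0.05 — a
    lowly-to-moderately-expressed window where validation is practical.
    """
    out = results.copy()
    out["passes_candidate_window"] = (
        (out["mean_count"] > count_low)
        & (out["mean_count"] < count_high)
        & (out["log2fc"].abs() > lfc_threshold)
        & (out["p"] < p_threshold)
    )
    return out
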