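"""Phenotype and validation arithmetic.

* Erectile evaluation: the ratio of maximal intracavernous pressure (ICP) to
  mean arterial pressure (MAP) is the erectile-function readout; animals are
  assigned to the age-related ED group below 0.35 and to the control group
  above it, both with strict inequalities (an animal exactly at the threshold
  is flagged unassigned).
* qPCR relative quantification by the 2^-ddCt method: per sample,
  dCt = Ct_gene - Ct_reference (replicates averaged on the Ct scale first);
  ddCt subtracts the calibrator group's mean dCt; fold change = 2^-ddCt,
  normalized here against beta-actin by default.
* Two-group comparisons: Welch t-test for parametric data, Mann-Whitney for
  nonparametric; "auto" screens each group with Shapiro-Wilk at alpha=0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import GROUP_CASE, GROUP_CONTROL, ValidationError
from .simdata import QPCRPlate

UNASSIGNED = "unassigned"


def assign_groups(table: pd.DataFrame, threshold: float = 0.35) -> pd.DataFrame:
    """Group animals by the ICP/MAP ratio.

    Adds ``ratio`` and ``group`` columns: ratio < threshold -> A-ED,
    ratio > threshold -> NC, ratio == threshold -> "unassigned" (the grouping
    rule defines both groups with strict inequalities and leaves the boundary
    undefined).
    """
    need = [c for c in ("animal", "ICP", "MAP") if c not in table.columns]
    if need:
        raise ValidationError(f"phenotype table missing columns: {need}")
    if (table["MAP"] <= 0).any():
        bad = table.loc[table["MAP"] <= 0, "animal"].tolist()
        raise ValidationError(f"non-positive MAP for animals: {bad}")
    out = table.copy()
    out["ratio"] = out["ICP"] / out["MAP"]
    out["group"] = np.select(
        [out["ratio"] < threshold, out["ratio"] > threshold],
        [GROUP_CASE, GROUP_CONTROL],
        default=UNASSIGNED,
    )
    return out


def ddct_fold_change(
    plate: QPCRPlate,
    gene: str,
    test_group: str = GROUP_CASE,
    calibrator_group: str | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """2^-ddCt fold change of ``gene`` relative to the calibrator group.

    Returns (per-sample table with dCt, ddCt and fold change, summary dict
    with the geometric-mean fold change and mean ddCt per group).
    """
    calibrator = calibrator_group or plate.calibrator_group
    ct = plate.ct
    if gene not in set(ct["gene"]):
        raise ValidationError(f"gene {gene!r} not on the plate")
    mean_ct = ct.groupby(["gene", "sample"])["ct"].mean()
    try:
        ref = mean_ct.loc[plate.reference_gene]
    except KeyError:
        raise ValidationError(f"reference gene {plate.reference_gene!r} missing")
    tgt = mean_ct.loc[gene]
    samples = tgt.index
    dct = tgt - ref.reindex(samples)
    if dct.isna().any():
        missing = list(samples[dct.isna()])
        raise ValidationError(f"reference Ct missing for samples: {missing}")
    groups = plate.groups.reindex(samples)
    cal_samples = groups.index[groups == calibrator]
    if len(cal_samples) == 0:
        raise ValidationError(f"no samples in calibrator group {calibrator!r}")
    ddct = dct - dct[cal_samples].mean()
    fold = 2.0 ** (-ddct)
    table = pd.DataFrame(
        {"sample": samples, "group": groups.values, "dct": dct.values,
         "ddct": ddct.values, "fold_change": fold.values}
    )
    test = table[table["group"] == test_group]
    summary = {
        "gene": gene,
        "mean_ddct": float(test["ddct"].mean()),
        "fold_change": float(2.0 ** (-test["ddct"].mean())),
    }
    return table, summary


def compare_groups(
    values_a, values_b, mode: str = "auto", shapiro_alpha: float = 0.05
) -> tuple[float, float, str]:
    """Two-sided two-group comparison: Welch t or Mann-Whitney.

    ``mode="auto"`` uses the t-test iff Shapiro-Wilk fails to reject
    normality in both groups; the Mann-Whitney test is exact for a combined
    n <= 20 without ties, otherwise the tie-corrected normal approximation.
    Returns (statistic, p, test used).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 observations per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        # all observations identical: no evidence of any difference
        return 0.0, 1.0, "degenerate"
    if mode == "auto":
        if len(a) < 3 or len(b) < 3:
            raise ValidationError("auto mode needs >= 3 observations per group")
        normal = all(
            np.ptp(g) > 0 and stats.shapiro(g).pvalue > shapiro_alpha for g in (a, b)
        )
        mode = "t" if normal else "mann-whitney"
    if mode == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue), "t"
    if mode == "mann-whitney":
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue), "mann-whitney"
    raise ValidationError(f"unknown mode {mode!r}")
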