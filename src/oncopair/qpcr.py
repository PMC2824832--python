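"""qPCR-side validation statistics: dCT/ddCT arithmetic, genotype calls
from genomic DNA, the pooled-variance copy-number significance test, and
validation-rate bookkeeping.

Cycle-threshold (CT) conventions: a lower CT means more template.  dCT
contrasts a target against a control (or allele 1 against allele 2);
ddCT contrasts the tumor dCT against the normal dCT; the fold change is
``2 ** (-ddCT)``, so a ddCT of -1 is a 2-fold gain in the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

# Variance of the median of n i.i.d. normals, relative to the element
# variance (order-statistic constants; the even-n median is the mean of
# the two central order statistics).
MEDIAN4_VAR = 0.2983
MEDIAN6_VAR = 0.2146
# ddCT = median(4 tumor dCTs) - median(6 per-normal medians of 4 dCTs):
# Var(ddCT) = MEDIAN4_VAR * (1 + MEDIAN6_VAR) * per-replicate dCT variance
DDCT_VAR_FACTOR = MEDIAN4_VAR * (1.0 + MEDIAN6_VAR)


def dct(target_cts: Sequence[float], control_cts: Sequence[float]) -> float:
    """Mean CT difference: target minus control.

    For allele-specific assays the "target" is allele 1 and the "control"
    is allele 2; for expression assays the control is an abundantly
    expressed reference gene.
    """
    t = np.asarray(target_cts, dtype=float)
    c = np.asarray(control_cts, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("dCT needs at least one replicate on each side")
    return float(t.mean() - c.mean())


def ddct(tumor_dct: float, normal_dct: float) -> Tuple[float, float]:
    """ddCT (tumor dCT minus normal dCT) and the implied fold change.

    Fold change is ``2 ** (-ddCT)``: lower CT in the tumor relative to its
    control means more template, so a negative ddCT is a gain.
    """
    d = tumor_dct - normal_dct
    return float(d), float(2.0 ** (-d))


def genotype_from_gdna(gdna_dct: float, cutoff: float = 4.0) -> str:
    """Genotype call from an allele-contrast dCT on genomic DNA.

    With |dCT| > ``cutoff`` only one allele amplified appreciably: the
    sample is homozygous for the allele with the *lower* CT (dCT =
    CT(allele1) - CT(allele2), so a large positive dCT means allele 2 is
    the one present).  Otherwise heterozygous.
    """
    if abs(gdna_dct) > cutoff:
        return "homozygous-allele2" if gdna_dct > 0 else "homozygous-allele1"
    return "heterozygous"


@dataclass
class CNTestResult:
    """Outcome of the copy-number qPCR significance test for one assay."""

    ddct: float
    fold_change: float
    t: float
    df: int
    p: float
    significant: bool


def cn_significance_one_assay(
    tumor_dcts: Sequence[float],
    normal_dcts: np.ndarray,
    alpha: float = 0.05,
) -> CNTestResult:
    """Test a copy-number fold-change against a panel of normal samples.

    ``normal_dcts`` is (n_normals, n_replicates) — canonically 6 x 4.
    The point estimate is ddCT = median(tumor dCTs) minus the median of
    the per-normal median dCTs.  Replicate noise is estimated by pooling
    the normal-panel dCT values (within-sample deviations, df =
    n_values - n_normals), and the null "fold-change is 1" is tested with
    a t statistic whose scale accounts for the median-based estimator
    (``DDCT_VAR_FACTOR``).  A degenerate zero-variance panel falls back to
    an exact comparison: significant iff ddCT != 0.
    """
    tumor = np.asarray(tumor_dcts, dtype=float)
    panel = np.asarray(normal_dcts, dtype=float)
    if panel.ndim != 2 or panel.shape[0] < 2:
        raise ValueError("normal panel needs >= 2 samples with replicates")
    per_normal_medians = np.median(panel, axis=1)
    d = float(np.median(tumor) - np.median(per_normal_medians))
    resid = panel - panel.mean(axis=1, keepdims=True)
    df = panel.size - panel.shape[0]
    s2 = float((resid**2).sum() / df)
    if s2 == 0.0:
        return CNTestResult(d, 2.0 ** (-d), np.inf if d else 0.0, df,
                            0.0 if d else 1.0, bool(d != 0))
    t = d / np.sqrt(s2 * DDCT_VAR_FACTOR)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CNTestResult(d, 2.0 ** (-d), float(t), df, p, bool(p < alpha))


def cn_significance(
    tumor_dcts_by_assay: Mapping[str, Sequence[float]],
    normal_dcts_by_assay: Mapping[str, np.ndarray],
    alpha: float = 0.05,
) -> Dict:
    """Combine the per-control-locus tests: significant only in unison.

    A gene's copy-number change is deemed significant only when the test
    rejects at ``alpha`` in *both* control-locus assays (e.g. one using
    RNaseP and one using TERT as the reference), which guards against a
    single misbehaving control.
    """
    per_assay = {
        assay: cn_significance_one_assay(
            tumor_dcts_by_assay[assay], normal_dcts_by_assay[assay], alpha
        )
        for assay in tumor_dcts_by_assay
    }
    if len(per_assay) < 2:
        raise ValueError("the both-assays rule needs two control assays")
    return {
        "per_assay": per_assay,
        "significant": all(r.significant for r in per_assay.values()),
    }


def validation_rates(outcomes: pd.DataFrame) -> Dict:
    """False-positive / false-negative accounting for assayed predictions.

    ``outcomes`` has one row per assayed predicted-positive with boolean
    columns ``validated`` (the qPCR assay confirmed the sequencing call),
    optionally ``genotype_error`` (the failure traces to a false
    heterozygous genotype) and ``filtered_out`` (a revised filter chain
    removes the site retrospectively).

    Returns percentages rounded to whole percent:

    * ``fp_rate`` — failed validations / assayed;
    * ``genotype_attribution`` — genotype-attributable failures / failures;
    * ``post_filter_fp_rate`` — failures surviving the revised filters /
      predictions surviving the revised filters (when ``filtered_out``
      present);
    * ``fn_rate`` — validated positives removed by the revised filters /
      assayed (when ``filtered_out`` present).
    """
    n = len(outcomes)
    if n == 0:
        raise ValueError("no assayed outcomes")
    failed = ~outcomes["validated"]
    report: Dict = {
        "n_assayed": n,
        "n_validated": int(outcomes["validated"].sum()),
        "fp_rate": round(100 * failed.sum() / n),
    }
    if "genotype_error" in outcomes.columns and failed.sum() > 0:
        report["genotype_attribution"] = round(
            100 * (failed & outcomes["genotype_error"]).sum() / failed.sum()
        )
    if "filtered_out" in outcomes.columns:
        kept = ~outcomes["filtered_out"]
        if kept.sum() > 0:
            report["post_filter_fp_rate"] = round(
                100 * (failed & kept).sum() / kept.sum()
            )
        report["fn_rate"] = round(
            100 * (outcomes["validated"] & outcomes["filtered_out"]).sum() / n
        )
    return report
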