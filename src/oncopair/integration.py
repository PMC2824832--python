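"""Linking copy-number change to expression change and allelic imbalance.

Three statistics connect the segmentation output to the transcriptome:

* the Pearson correlation between per-segment log2 copy-number change
  (CNC) and log2 expression ratio, optionally restricted to segments with
  a CNC above a fold-change floor;
* a shift test: heterozygous sites are binned by the |log2 CNC| of their
  overlapping segment (low < 1.2, moderate 1.2-1.8, large > 1.8) and the
  moderate/large |AI| distributions are compared against the low bin with
  a one-sided Mann-Whitney rank-sum test (alternative: shifted higher);
* hypergeometric gene-set overlap arithmetic (expected overlap and upper
  tail probability), used for AI-vs-DE and cross-study comparisons.

Heterozygous sites are selected from the normal sample alone: a
catalogued position where both the reference and the first alternate
nucleotide are supported by at least four reads in the normal tissue is
very likely heterozygous in the patient.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from oncopair.allelic_imbalance import KnownVariant
from oncopair.tally import NUCLEOTIDES

#: |log2 CNC| bin edges; boundary values belong to the higher bin
CNC_BIN_EDGES = {"low": (0.0, 1.2), "moderate": (1.2, 1.8), "large": (1.8, np.inf)}


def cnc_bin(abs_log2_cnc: float) -> str:
    """Bin label for an absolute log2 copy-number change.

    Bins are half-open on the left: [0, 1.2) low, [1.2, 1.8) moderate,
    [1.8, inf) large — a boundary value goes to the higher bin.
    """
    if abs_log2_cnc < 0:
        raise ValueError("|log2 CNC| cannot be negative")
    if abs_log2_cnc < 1.2:
        return "low"
    if abs_log2_cnc < 1.8:
        return "moderate"
    return "large"


def cnc_expression_correlation(
    segments: pd.DataFrame,
    min_fold_change: Optional[float] = None,
) -> float:
    """Pearson correlation of per-segment log2 CNC vs log2 expression ratio.

    ``segments`` needs ``log2_cnc`` and ``log2_expression_ratio`` columns.
    With ``min_fold_change`` (e.g. 1.4), only segments whose copy-number
    change exceeds that fold in either direction — ``|log2_cnc| >
    log2(min_fold_change)`` — are retained.  Returns NaN when either
    retained vector has zero variance.
    """
    df = segments
    if min_fold_change is not None:
        if min_fold_change <= 0:
            raise ValueError("min_fold_change must be positive")
        df = df[np.abs(df["log2_cnc"]) > np.log2(min_fold_change)]
    if len(df) < 3:
        raise ValueError("correlation needs at least 3 segments after filtering")
    x = df["log2_cnc"].to_numpy(dtype=float)
    y = df["log2_expression_ratio"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def select_het_sites(
    normal_tallies: pd.DataFrame,
    variants: Iterable[KnownVariant],
    min_reads_each: int = 4,
) -> pd.DataFrame:
    """Likely-heterozygous catalogued sites from the normal sample.

    A site qualifies when (1) it appears in the known-variant catalog and
    (2) both the reference and the first alternate nucleotide are
    supported by at least ``min_reads_each`` reads in the normal tissue.
    Returns one row per selected site with the two allele counts.
    """
    catalog = {(v.chrom, v.pos): v for v in variants}
    rows = []
    for row in normal_tallies.itertuples(index=False):
        v = catalog.get((row.chrom, row.pos))
        if v is None:
            continue
        ref_c = getattr(row, f"count_{v.ref}")
        alt_c = getattr(row, f"count_{v.alt}")
        if ref_c >= min_reads_each and alt_c >= min_reads_each:
            rows.append((row.chrom, row.pos, v.ref, v.alt, int(ref_c), int(alt_c)))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
    )


def assign_sites_to_segments(
    sites: pd.DataFrame, segments: pd.DataFrame
) -> pd.DataFrame:
    """Attach each het site to the copy-number segment covering it.

    Segments tile the genome, so an uncovered site (masked region) is
    treated as copy-neutral: ``log2_cnc = 0`` and no segment id.  Adds
    ``segment_index``, ``log2_cnc`` and ``cnc_bin`` columns.
    """
    out = sites.copy()
    seg_idx = np.full(len(out), -1, dtype=int)
    log2_cnc = np.zeros(len(out))
    for chrom, grp in segments.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = grp.index.to_numpy()
        sel = out["chrom"] == chrom
        pos0 = out.loc[sel, "pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        rows = np.where(sel)[0]
        seg_idx[rows[ok]] = idx[j[ok]]
        log2_cnc[rows[ok]] = grp["log2_cnc"].to_numpy()[j[ok]]
    out["segment_index"] = seg_idx
    out["log2_cnc"] = log2_cnc
    out["cnc_bin"] = [cnc_bin(abs(v)) for v in log2_cnc]
    return out


def cnc_ai_shift_test(
    sites: pd.DataFrame,
    ai_column: str = "abs_ai",
) -> Dict[str, Dict]:
    """Mann-Whitney shift tests of |AI| in moderate/large CNC bins vs low.

    ``sites`` needs a ``cnc_bin`` column (see
    :func:`assign_sites_to_segments`) and an |AI| column.  For each of the
    moderate and large bins, tests one-sided (alternative: the bin's |AI|
    distribution is stochastically greater than the low bin's).  Exact
    enumeration is used for small samples (both sides < 20, no ties),
    otherwise the tie-corrected normal approximation.  A bin with fewer
    than 2 sites is skipped with a notice.
    """
    groups = {
        label: sites.loc[sites["cnc_bin"] == label, ai_column].to_numpy(dtype=float)
        for label in ("low", "moderate", "large")
    }
    results: Dict[str, Dict] = {}
    low = groups["low"]
    for label in ("moderate", "large"):
        x = groups[label]
        if len(x) < 2 or len(low) < 2:
            results[label] = {"skipped": True, "n": len(x), "n_low": len(low)}
            continue
        exact = len(x) < 20 and len(low) < 20
        method = "exact" if exact else "asymptotic"
        try:
            stat, p = stats.mannwhitneyu(
                x, low, alternative="greater", method=method
            )
        except ValueError:  # ties with exact method
            stat, p = stats.mannwhitneyu(
                x, low, alternative="greater", method="asymptotic"
            )
        results[label] = {
            "skipped": False,
            "U": float(stat),
            "p": float(p),
            "n": len(x),
            "n_low": len(low),
            "median": float(np.median(x)),
            "median_low": float(np.median(low)),
        }
    return results


def attach_segment_expression(
    segments: pd.DataFrame,
    genes: Sequence,
    gene_counts: pd.DataFrame,
    totals: Mapping[str, float],
) -> pd.DataFrame:
    """Per-segment tumor/normal expression ratio from gene counts.

    Each gene is assigned to the segment containing its midpoint; the
    segment's expression ratio is the ratio of summed tumor to summed
    normal raw counts (one pseudo-count each side), normalized by the
    library-total ratio.  Adds ``log2_expression_ratio`` and
    ``n_genes`` columns.
    """
    t_sum = np.zeros(len(segments))
    n_sum = np.zeros(len(segments))
    n_genes = np.zeros(len(segments), dtype=int)
    seg_by_chrom = {
        chrom: grp for chrom, grp in segments.reset_index().groupby("chrom")
    }
    for g in genes:
        grp = seg_by_chrom.get(g.chrom)
        if grp is None or g.gene_id not in gene_counts.index:
            continue
        mid = (g.start + g.end) // 2
        hit = grp[(grp["start"] <= mid) & (mid < grp["end"])]
        if len(hit) == 0:
            continue
        i = int(hit["index"].iloc[0])
        t_sum[i] += gene_counts.loc[g.gene_id, "tumor"]
        n_sum[i] += gene_counts.loc[g.gene_id, "normal"]
        n_genes[i] += 1
    lib_ratio = totals["tumor"] / totals["normal"]
    out = segments.copy()
    out["n_genes"] = n_genes
    out["log2_expression_ratio"] = np.log2(
        ((t_sum + 1) / (n_sum + 1)) / lib_ratio
    )
    return out


def hypergeometric_overlap(
    universe_size: int, set1_size: int, draw_size: int, observed_overlap: int
) -> Tuple[float, float]:
    """Expected overlap and upper-tail probability of a gene-set overlap.

    Drawing ``draw_size`` genes without replacement from a universe of
    ``universe_size`` containing ``set1_size`` marked genes, returns
    ``(expected, P(X >= observed_overlap))`` where expected =
    draw_size * set1_size / universe_size.  The tail is computed by the
    hypergeometric survival function (log-space internally), exact to
    floating-point precision.
    """
    N, K, n, k = universe_size, set1_size, draw_size, observed_overlap
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError("inconsistent hypergeometric parameters")
    expected = n * K / N
    tail = float(stats.hypergeom.sf(k - 1, N, K, n))
    return expected, tail


def ai_de_overlap_report(
    ai_genes: Iterable[str],
    de_genes: Iterable[str],
    universe_size: Optional[int] = None,
) -> Dict:
    """Overlap of the AI gene set with the differentially expressed set.

    Reports the intersection size, the percentage of AI genes that are
    also DE (rounded to a whole percent), and — when a gene universe size
    is given — the expected percentage and hypergeometric upper-tail
    probability of the observed overlap.
    """
    ai = set(ai_genes)
    de = set(de_genes)
    inter = ai & de
    report: Dict = {
        "n_ai": len(ai),
        "n_de": len(de),
        "n_overlap": len(inter),
        "overlap_genes": sorted(inter),
        "observed_percent": round(100 * len(inter) / len(ai)) if ai else 0,
    }
    if universe_size is not None and ai:
        expected, tail = hypergeometric_overlap(
            universe_size, len(de), len(ai), len(inter)
        )
        report["expected_percent"] = round(100 * expected / len(ai))
        report["p_value"] = tail
    return report
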