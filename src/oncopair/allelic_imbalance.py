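"""Relative allelic imbalance between paired tumor/normal samples.

Allelic imbalance (AI) here means a difference in per-nucleotide
observation frequencies at a genomic position between the tumor and the
matched normal RNA sample.  Significance is assessed with a Pearson
chi-square test of independence on the 2 x 4 (sample x nucleotide)
contingency table of read counts; nucleotide columns with a zero marginal
total are dropped first, so the degrees of freedom equal (number of
observed nucleotides - 1).

A site is called AI-positive when it passes all four filters:

1. coverage >= ``min_cov`` in *both* samples (post-trim, post-uniqueness);
2. chi-square p-value < ``max_p``;
3. the absolute frequency of at least one nucleotide changes by strictly
   more than ``min_delta`` between the samples;
4. in each sample, no nucleotide with nonzero count has more than
   ``max_dupstart_frac`` of its supporting observations sharing a single
   alignment start+strand (the duplicate-start artifact filter: an
   over-amplified reverse-transcription error produces many copies of one
   fragment, all landing at the same start).

Presence in the known-variant catalog is annotated but not required, so
imbalance caused by de novo point mutation remains detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from oncopair.tally import (
    NUCLEOTIDES,
    counts_matrix,
    max_same_start_matrix,
    pair_tallies,
)


@dataclass(frozen=True)
class KnownVariant:
    """A catalogued variant: reference and first alternate nucleotide."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(
                f"variant at {self.chrom}:{self.pos} has ref == alt ({self.ref})"
            )


@dataclass(frozen=True)
class AIThresholds:
    """Filter chain parameters for relative-AI detection."""

    min_cov: int = 15
    max_p: float = 1e-3
    min_delta: float = 0.10
    max_dupstart_frac: float = 0.90
    #: the duplicate-start filter needs repeated observations to show
    #: over-sampling; nucleotides with fewer supporting reads than this
    #: (e.g. sequencing-error singletons, which trivially share their own
    #: start) are not grounds for discarding a site
    min_dupstart_count: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_delta <= 1.0):
            raise ValueError("min_delta must be in [0, 1]")
        if not (0.0 <= self.max_dupstart_frac <= 1.0):
            raise ValueError("max_dupstart_frac must be in [0, 1]")
        if not (0.0 < self.max_p <= 1.0):
            raise ValueError("max_p must be in (0, 1]")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")


def chi2_independence(
    normal_counts: Sequence[int], tumor_counts: Sequence[int]
) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence on the 2 x k count table.

    Nucleotide columns whose marginal total is zero are dropped before the
    test (they contribute no information and would give 0/0 expected
    counts); the remaining table has k columns and k-1 degrees of freedom.
    With a single shared nucleotide the test is degenerate: chi2 = 0,
    p = 1.  No continuity correction is applied.

    Returns ``(chi2, df, p)``.  Raises ``ValueError`` if either sample has
    zero total coverage (not a testable site).
    """
    n = np.asarray(normal_counts, dtype=np.int64)
    t = np.asarray(tumor_counts, dtype=np.int64)
    if n.sum() == 0 or t.sum() == 0:
        raise ValueError("chi2_independence requires coverage >= 1 in both samples")
    keep = (n + t) > 0
    table = np.stack([n[keep], t[keep]])
    k = table.shape[1]
    if k == 1:
        return 0.0, 0, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def ai_magnitude(
    normal_counts: Sequence[int], tumor_counts: Sequence[int]
) -> Tuple[np.ndarray, float]:
    """Per-nucleotide frequency change and its largest absolute value.

    ``delta_freq[i] = tumor_freq[i] - normal_freq[i]`` for nucleotide i in
    A,C,G,T order; the scalar AI magnitude used downstream is
    ``max(|delta_freq|)``.
    """
    n = np.asarray(normal_counts, dtype=float)
    t = np.asarray(tumor_counts, dtype=float)
    if n.sum() == 0 or t.sum() == 0:
        raise ValueError("ai_magnitude requires coverage > 0 in both samples")
    delta = t / t.sum() - n / n.sum()
    return delta, float(np.max(np.abs(delta)))


def _dupstart_ok(
    counts: np.ndarray, mss: np.ndarray, max_frac: float, min_count: int = 2
) -> np.ndarray:
    """Row-wise duplicate-start filter for one sample.

    A row passes when every nucleotide with at least ``min_count``
    supporting reads has ``max_same_start / count <= max_frac``.
    Nucleotides below ``min_count`` carry no over-sampling evidence (a
    lone read always coincides with its own start) and are ignored.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts >= min_count, mss / np.maximum(counts, 1), 0.0)
    return np.all(frac <= max_frac, axis=1)


def detect_relative_ai(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    thresholds: AIThresholds = AIThresholds(),
    variants: Optional[Iterable[KnownVariant]] = None,
) -> pd.DataFrame:
    """Evaluate the full AI filter chain at every shared tallied position.

    Parameters
    ----------
    normal, tumor
        Site tally tables (see ``oncopair.tally``), already trimmed and
        uniqueness-filtered.
    thresholds
        Filter chain parameters.
    variants
        Optional known-variant catalog; membership is annotated in the
        ``in_variant_catalog`` column but is not a filter.

    Returns one row per shared position, sorted by (chrom, pos), with the
    chi-square statistic, per-nucleotide frequency deltas, the four filter
    flags and the combined ``ai_positive`` call.
    """
    paired = pair_tallies(normal, tumor)
    ncols = [f"count_{x}_normal" for x in NUCLEOTIDES]
    tcols = [f"count_{x}_tumor" for x in NUCLEOTIDES]
    ncnt = paired[ncols].to_numpy(dtype=np.int64)
    tcnt = paired[tcols].to_numpy(dtype=np.int64)
    nmss = paired[[f"max_same_start_{x}_normal" for x in NUCLEOTIDES]].to_numpy(
        dtype=np.int64
    )
    tmss = paired[[f"max_same_start_{x}_tumor" for x in NUCLEOTIDES]].to_numpy(
        dtype=np.int64
    )
    ncov = ncnt.sum(axis=1)
    tcov = tcnt.sum(axis=1)

    m = len(paired)
    chi2 = np.zeros(m)
    df_out = np.zeros(m, dtype=np.int64)
    pval = np.ones(m)
    # vectorized Pearson chi-square per site over the 2 x k table after
    # zero-column drop; the per-site loop form is kept in
    # chi2_independence for single-site use and as the tested reference
    tot = ncnt + tcnt
    grand = (ncov + tcov).astype(float)
    testable = (ncov > 0) & (tcov > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_n = ncov[:, None] * tot / grand[:, None]
        e_t = tcov[:, None] * tot / grand[:, None]
        terms = np.where(tot > 0, (ncnt - e_n) ** 2 / np.where(e_n > 0, e_n, 1), 0.0)
        terms += np.where(tot > 0, (tcnt - e_t) ** 2 / np.where(e_t > 0, e_t, 1), 0.0)
    chi2[testable] = terms[testable].sum(axis=1)
    df_out[testable] = (tot[testable] > 0).sum(axis=1) - 1
    pos_df = testable & (df_out > 0)
    pval[pos_df] = stats.chi2.sf(chi2[pos_df], df_out[pos_df])
    chi2[~testable] = np.nan
    pval[~testable] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(
            testable[:, None],
            tcnt / np.maximum(tcov, 1)[:, None] - ncnt / np.maximum(ncov, 1)[:, None],
            np.nan,
        )
    max_abs_delta = np.nanmax(np.abs(delta), axis=1) if m else np.zeros(0)

    coverage_ok = (ncov >= thresholds.min_cov) & (tcov >= thresholds.min_cov)
    p_ok = testable & (pval < thresholds.max_p)
    delta_ok = testable & (max_abs_delta > thresholds.min_delta)
    dupstart_ok = _dupstart_ok(
        ncnt, nmss, thresholds.max_dupstart_frac, thresholds.min_dupstart_count
    ) & _dupstart_ok(
        tcnt, tmss, thresholds.max_dupstart_frac, thresholds.min_dupstart_count
    )

    out = paired[["chrom", "pos"]].copy()
    out["coverage_normal"] = ncov
    out["coverage_tumor"] = tcov
    out["chi2"] = chi2
    out["df"] = df_out
    out["p"] = pval
    for i, x in enumerate(NUCLEOTIDES):
        out[f"delta_{x}"] = delta[:, i] if m else []
    out["max_abs_delta"] = max_abs_delta
    out["coverage_ok"] = coverage_ok
    out["p_ok"] = p_ok
    out["delta_ok"] = delta_ok
    out["dupstart_ok"] = dupstart_ok
    out["ai_positive"] = coverage_ok & p_ok & delta_ok & dupstart_ok

    catalog: Set[Tuple[str, int]] = set()
    if variants is not None:
        catalog = {(v.chrom, v.pos) for v in variants}
    out["in_variant_catalog"] = [
        (c, p) in catalog for c, p in zip(out["chrom"], out["pos"])
    ]
    return out


def classify_genotypes(
    ratios: pd.DataFrame,
    boundaries: Tuple[float, float] = (-2.0, 2.0),
) -> pd.DataFrame:
    """Classify genotypes from log2 allelic ratios.

    The allelic-ratio distribution over catalogued sites is trimodal: a
    high-ratio peak (homozygous reference), a balanced peak (heterozygous)
    and a low-ratio peak (homozygous alternate).  ``ratios`` needs columns
    ``ref_count``, ``alt_count`` and ``allelic_ratio`` (NaN where
    undefined).  Sites where exactly one allele was observed at adequate
    coverage are classified homozygous for that allele even though the
    log-ratio is undefined; sites with no defined ratio and both alleles
    observed remain ``unclassified``.

    Boundaries are inclusive on the homozygous side: a ratio of exactly
    ``high`` is homozygous-reference.
    """
    low, high = boundaries
    if not low < high:
        raise ValueError("boundaries must satisfy low < high")
    out = ratios.copy()
    ratio = out["allelic_ratio"].to_numpy(dtype=float)
    ref = out["ref_count"].to_numpy()
    alt = out["alt_count"].to_numpy()
    cls = np.full(len(out), "unclassified", dtype=object)
    defined = ~np.isnan(ratio)
    cls[defined & (ratio >= high)] = "hom-ref"
    cls[defined & (ratio <= low)] = "hom-alt"
    cls[defined & (ratio > low) & (ratio < high)] = "het"
    single_ref = ~defined & (ref > 0) & (alt == 0)
    single_alt = ~defined & (alt > 0) & (ref == 0)
    cls[single_ref] = "hom-ref"
    cls[single_alt] = "hom-alt"
    out["genotype"] = cls
    return out


# ---------------------------------------------------------------------------
# gene-level aggregation


@dataclass
class GeneModel:
    """A gene with exon structure on one strand.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    ``utr3`` optionally marks annotated 3'-UTR intervals (same convention).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    utr3: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene model {self.gene_id} has zero exons")
        self.exons = sorted(self.exons)
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def classify_site_region(
    gene: GeneModel, pos0: int, near_splice_bp: int = 10
) -> str:
    """Region class of a 0-based position inside a gene's span.

    Classes: ``3utr`` (annotated 3' UTR), ``exonic``, ``near-splice-site``
    (intronic, within ``near_splice_bp`` of an exon boundary), or
    ``intronic``.
    """
    for s, e in gene.utr3:
        if s <= pos0 < e:
            return "3utr"
    for s, e in gene.exons:
        if s <= pos0 < e:
            return "exonic"
    # intronic: distance (in bases) to the nearest splice site; the first
    # intronic base on either side of an exon is at distance 1
    dist = min(
        (s - pos0) if pos0 < s else (pos0 - e + 1) for s, e in gene.exons
    )
    return "near-splice-site" if dist <= near_splice_bp else "intronic"


def aggregate_ai_to_genes(
    calls: pd.DataFrame,
    genes: Sequence[GeneModel],
    near_splice_bp: int = 10,
) -> pd.DataFrame:
    """Roll AI calls up to genes.

    Every tested site is assigned to all genes whose span overlaps it
    (both strands — an imbalanced site in an antisense overlap is evidence
    for both annotations); AI-positive sites additionally get a region
    class.  Returns one row per gene with ``n_sites_tested``,
    ``n_ai_positive``, the positive positions and their region classes.
    """
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    summary: Dict[str, dict] = {
        g.gene_id: {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "n_sites_tested": 0,
            "n_ai_positive": 0,
            "positions": [],
            "region_classes": [],
        }
        for g in genes
    }
    for row in calls.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        pos0 = row.pos - 1
        for iv in tree.at(pos0):
            g: GeneModel = iv.data
            rec = summary[g.gene_id]
            rec["n_sites_tested"] += 1
            if getattr(row, "ai_positive", False):
                rec["n_ai_positive"] += 1
                rec["positions"].append(int(row.pos))
                rec["region_classes"].append(
                    classify_site_region(g, pos0, near_splice_bp)
                )
    df = pd.DataFrame(list(summary.values()))
    return df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def recurrent_ai_genes(
    per_patient: Mapping[str, Iterable[str]]
) -> Tuple[pd.Series, Dict[Tuple[str, str], int]]:
    """Recurrence of AI genes across patients.

    Returns (gene -> number of patients with at least one AI-positive site
    in that gene, sorted by descending recurrence then gene id) and the
    pairwise intersection sizes between patients.
    """
    if len(per_patient) < 2:
        raise ValueError("recurrence requires at least two patients")
    sets = {p: set(gs) for p, gs in per_patient.items()}
    all_genes = sorted(set().union(*sets.values()))
    rec = pd.Series(
        {g: sum(g in s for s in sets.values()) for g in all_genes}, dtype=int
    )
    rec = rec.sort_values(ascending=False, kind="mergesort")
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(sorted(sets), 2)
    }
    return rec, pairwise
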