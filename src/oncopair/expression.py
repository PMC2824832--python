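"""Transcript quantification and cross-patient rank-order differential
expression.

Per sample, a gene's raw count is the number of uniquely aligned reads
whose alignment start falls inside one of its exons (strand-aware by
default, since the library protocol is strand-specific).  Normalized
counts are ``(raw + 1) / total uniquely aligned reads``: the single
pseudo-count keeps tumor/normal ratios finite for silent genes.  No
transcript-length normalization is applied — all downstream analyses are
fold-changes between two conditions of the same gene.

The cross-patient differentially expressed sets are defined by rank
aggregation: within each patient genes are ranked by log2 tumor/normal
ratio (ascending, average rank on ties), the per-gene median rank across
patients is taken, and the ``set_size`` lowest / highest median ranks
become the commonly down- / up-regulated sets.  A shuffled-pairing null
(each patient's ratio vector independently permuted over genes) estimates
how often median ranks this extreme arise with no shared signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from oncopair.allelic_imbalance import GeneModel

__all__ = [
    "GeneModel",
    "count_transcript_reads",
    "normalize_counts",
    "min_count_filter",
    "rank_order_de",
    "shuffled_rank_null",
    "profile_correlation",
    "cluster_samples",
    "DEResult",
]


def count_transcript_reads(
    read_starts: pd.DataFrame,
    genes: Sequence[GeneModel],
    stranded: bool = True,
) -> pd.Series:
    """Sum uniquely aligned reads over each gene's exons.

    ``read_starts`` needs columns ``chrom``, ``start`` (0-based alignment
    start) and, when ``stranded``, ``strand``.  A read is assigned to a
    gene when its start lies inside an exon; with ``stranded=True`` the
    read strand must match the gene's annotated strand (antisense reads
    contribute nothing).  Reads spanning an exon boundary are counted by
    where they start, which makes the assignment unambiguous.
    """
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        t = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            t.addi(s, e, g)
    counts = {g.gene_id: 0 for g in genes}
    has_strand = "strand" in read_starts.columns
    if stranded and not has_strand:
        raise ValueError("stranded counting requires a 'strand' column")
    for row in read_starts.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.at(int(row.start)):
            g: GeneModel = iv.data
            if stranded and row.strand != g.strand:
                continue
            counts[g.gene_id] += 1
    return pd.Series(counts, name="raw").sort_index()


def normalize_counts(raw: pd.DataFrame, totals: Mapping[str, float]) -> pd.DataFrame:
    """Pseudo-counted, library-size-normalized expression.

    ``raw`` is genes x samples; ``totals`` maps sample -> total uniquely
    aligned reads.  Returns ``(raw + 1) / total`` per column.
    """
    out = {}
    for col in raw.columns:
        total = totals[col]
        if total <= 0:
            raise ValueError(f"sample {col!r} has non-positive read total")
        out[col] = (raw[col] + 1) / total
    return pd.DataFrame(out, index=raw.index)


def min_count_filter(
    raw_by_patient: Mapping[str, pd.DataFrame], min_raw: int = 50
) -> pd.Index:
    """Genes adequately measured in every patient.

    ``raw_by_patient`` maps patient -> DataFrame with columns ``normal``
    and ``tumor`` of raw counts over a shared gene index.  A gene is
    retained iff in *every* patient at least one of the two tissues has
    ``raw >= min_raw``.
    """
    patients = list(raw_by_patient)
    if not patients:
        raise ValueError("no patients supplied")
    index = raw_by_patient[patients[0]].index
    keep = pd.Series(True, index=index)
    for p in patients:
        df = raw_by_patient[p]
        if not df.index.equals(index):
            df = df.reindex(index)
        keep &= df[["normal", "tumor"]].max(axis=1) >= min_raw
    return index[keep]


@dataclass
class DEResult:
    """Rank-aggregated differential expression across patients."""

    ranks: pd.DataFrame  # genes x patients, per-patient rank of log2 ratio
    median_rank: pd.Series  # per gene
    up: List[str]  # commonly up-regulated (highest median ranks)
    down: List[str]  # commonly down-regulated (lowest median ranks)
    set_size: int


def _lower_median(values: np.ndarray) -> np.ndarray:
    """Row-wise lower median (the smaller central order statistic when the
    count is even); identical to the ordinary median for odd counts."""
    s = np.sort(values, axis=1)
    return s[:, (values.shape[1] - 1) // 2]


def rank_order_de(log2_ratios: pd.DataFrame, set_size: int = 300) -> DEResult:
    """Median-rank aggregation of per-patient tumor/normal fold-changes.

    ``log2_ratios`` is genes x patients.  Ranks ascend with the ratio
    (rank 1 = most down-regulated) with average ranks on ties, so the
    ``set_size`` smallest median ranks form the down set and the largest
    form the up set.  Ties on the median rank are broken by gene id so the
    sets are deterministic.
    """
    if log2_ratios.shape[1] < 1:
        raise ValueError("need at least one patient")
    if not np.isfinite(log2_ratios.to_numpy(dtype=float)).all():
        raise ValueError("log2 ratios must be finite (use pseudo-counted counts)")
    ranks = log2_ratios.apply(lambda col: stats.rankdata(col, method="average"))
    ranks = pd.DataFrame(ranks, index=log2_ratios.index, columns=log2_ratios.columns)
    median = pd.Series(
        _lower_median(ranks.to_numpy(dtype=float)), index=ranks.index, name="median_rank"
    )
    n = len(median)
    k = min(set_size, n)
    if set_size > n:
        import warnings

        warnings.warn(
            f"set_size {set_size} exceeds the {n}-gene universe; sets truncated"
        )
    order = median.reset_index()
    order.columns = ["gene", "median_rank"]
    asc = order.sort_values(["median_rank", "gene"], kind="mergesort")
    desc = order.sort_values(
        ["median_rank", "gene"], ascending=[False, True], kind="mergesort"
    )
    down = asc["gene"].head(k).tolist()
    up = desc["gene"].head(k).tolist()
    return DEResult(ranks=ranks, median_rank=median, up=up, down=down, set_size=k)


def shuffled_rank_null(
    log2_ratios: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Shuffled-pairing null for median-rank extremity.

    In each shuffle every patient's ratio vector is independently permuted
    over genes, destroying any shared tumor/normal signal while preserving
    each patient's marginal ratio distribution.  For each gene the
    exceedance fraction is the fraction of (shuffle, gene) median ranks at
    least as extreme as the observed one, measured toward the tail the
    observed rank leans to (lower tail for median rank below the center,
    upper tail above; a dead-center rank gets exceedance 1).

    Returns a DataFrame with ``median_rank`` and ``exceedance`` per gene.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    values = log2_ratios.to_numpy(dtype=float)
    n_genes, n_pat = values.shape
    observed = _lower_median(
        np.column_stack(
            [stats.rankdata(values[:, j], method="average") for j in range(n_pat)]
        )
    )
    null_medians = np.empty((n_shuffles, n_genes))
    base_ranks = np.column_stack(
        [stats.rankdata(values[:, j], method="average") for j in range(n_pat)]
    )
    for i in range(n_shuffles):
        shuffled = np.column_stack(
            [rng.permutation(base_ranks[:, j]) for j in range(n_pat)]
        )
        null_medians[i] = _lower_median(shuffled)
    flat = np.sort(null_medians.ravel())
    total = flat.size
    center = (n_genes + 1) / 2.0
    exceed = np.ones(n_genes)
    below = observed < center
    above = observed > center
    # P(null median <= observed) via searchsorted on the pooled null
    exceed[below] = np.searchsorted(flat, observed[below], side="right") / total
    exceed[above] = (total - np.searchsorted(flat, observed[above], side="left")) / total
    return pd.DataFrame(
        {"median_rank": observed, "exceedance": exceed}, index=log2_ratios.index
    )


def profile_correlation(
    ratios_a: pd.Series,
    ratios_b: pd.Series,
    cap: Optional[float] = None,
) -> float:
    """Pearson correlation between two patients' log2 ratio profiles.

    With ``cap`` set, only genes with ``|log2 ratio| < cap`` in *both*
    patients enter the correlation (the capped variant down-weights the
    most extreme fold-changes).  Requires at least three shared genes;
    returns NaN when either restricted vector has zero variance.
    """
    shared = ratios_a.index.intersection(ratios_b.index)
    a = ratios_a.loc[shared].to_numpy(dtype=float)
    b = ratios_b.loc[shared].to_numpy(dtype=float)
    if cap is not None:
        keep = (np.abs(a) < cap) & (np.abs(b) < cap)
        a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("profile correlation needs at least 3 shared genes")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def cluster_samples(
    normalized: pd.DataFrame, log_transform: bool = True
) -> Tuple[np.ndarray, List[str]]:
    """Average-linkage hierarchical clustering of samples.

    Distance is 1 - Pearson correlation of (log2) normalized expression
    profiles.  Returns the scipy linkage matrix and the leaf order as
    sample labels.  Deterministic given column order.
    """
    if normalized.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    x = normalized.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x)
    corr = np.corrcoef(x.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    labels = [normalized.columns[i] for i in order]
    return link, labels
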