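"""Paired tumor/normal copy-number segmentation from read-start tracks.

The tumor:normal ratio of uniquely aligned read counts over a genomic
window estimates the copy-number change (CNC) of that window.  The
segmentation follows the windowed read-ratio change-point idea:

1. chromosome windows are delimited so that each contains exactly ``W``
   normal-sample read starts (the last window of a chromosome may hold
   fewer), making the normal coverage per window constant by construction;
2. candidate breakpoints are found by recursive binary splitting: within
   a stretch of windows, the cut maximizing the chi-square two-proportion
   statistic of the flanking tumor-vs-normal read sums becomes a
   candidate when its p-value is below ``p_init``, and both sides are
   split further;
3. adjacent candidate segments are then merged greedily, most-similar
   pair first, while the same test on the segment totals gives
   p > ``p_merge``.

Segments tile each chromosome.  The per-segment CNC is the tumor:normal
read-count ratio normalized by the library-size ratio, with one
pseudo-count on each segment sum so that homozygous deletions stay
finite; it is analyzed on the log2 scale.  An optional alignability mask
(e.g. 100 kb alignable windows) restricts the reads considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

SEGMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_windows",
    "normal_reads",
    "tumor_reads",
    "cnc",
    "log2_cnc",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning of the windowed read-ratio segmentation.

    ``W`` — normal read starts per local window.  ``alignable_window`` —
    granularity (bp) of the optional alignability mask.  ``p_init`` /
    ``p_merge`` — chi-square p-value cutoffs for proposing and for keeping
    breakpoints; together they control the genome-wide false-segment rate
    (defaults give on the order of one spurious segment over a few
    thousand null windows).
    """

    W: int = 400
    alignable_window: int = 100_000
    p_init: float = 1e-4
    p_merge: float = 1e-5

    def __post_init__(self) -> None:
        if self.W < 10:
            raise ValueError("W must be >= 10")
        if not (0.0 < self.p_merge <= self.p_init < 1.0):
            raise ValueError("need 0 < p_merge <= p_init < 1")


def apply_alignability_mask(
    starts: np.ndarray, mask: Sequence[Tuple[int, int]]
) -> np.ndarray:
    """Keep read starts falling inside any of the 0-based half-open
    alignable intervals."""
    starts = np.asarray(starts)
    keep = np.zeros(len(starts), dtype=bool)
    for s, e in mask:
        keep |= (starts >= s) & (starts < e)
    return starts[keep]


def build_local_windows(
    normal_starts: np.ndarray,
    tumor_starts: np.ndarray,
    chrom_length: int,
    params: SegmentationParams = SegmentationParams(),
) -> pd.DataFrame:
    """Delimit windows holding exactly ``W`` normal read starts each.

    Returns a DataFrame with 0-based half-open ``start``/``end`` and the
    normal and tumor read-start counts per window.  Window boundaries sit
    at the first read of the next block, so windows tile
    ``[0, chrom_length)`` exactly.  A chromosome with fewer than ``W``
    normal reads yields a single window.
    """
    normal = np.sort(np.asarray(normal_starts, dtype=np.int64))
    tumor = np.sort(np.asarray(tumor_starts, dtype=np.int64))
    n = len(normal)
    if n == 0:
        raise ValueError("no normal reads on chromosome; cannot window")
    W = params.W
    boundaries = [0]
    for i in range(W, n, W):
        boundaries.append(int(normal[i]))
    boundaries.append(int(chrom_length))
    starts = np.array(boundaries[:-1], dtype=np.int64)
    ends = np.array(boundaries[1:], dtype=np.int64)
    n_counts = np.searchsorted(normal, ends) - np.searchsorted(normal, starts)
    t_counts = np.searchsorted(tumor, ends) - np.searchsorted(tumor, starts)
    return pd.DataFrame(
        {"start": starts, "end": ends, "normal": n_counts, "tumor": t_counts}
    )


def _two_proportion_p(t1: int, n1: int, t2: int, n2: int) -> float:
    """Chi-square test (no continuity correction) that the tumor:normal
    read-count proportion is the same in two regions."""
    table = np.array([[t1, n1], [t2, n2]], dtype=float)
    if table.sum() == 0:
        return 1.0
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    if (col == 0).any() or (row == 0).any():
        return 1.0
    expected = np.outer(row, col) / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, 1))


def segment_read_ratios(
    windows: pd.DataFrame,
    params: SegmentationParams,
    normal_total: int,
    tumor_total: int,
    chrom: str = "chr",
) -> pd.DataFrame:
    """Segment one chromosome's window table into constant-ratio segments.

    Candidate breakpoints come from recursive binary splitting (the cut
    maximizing the two-proportion chi-square of the flanking read sums,
    accepted at ``p_init``); merging then removes the weakest breakpoints
    (highest between-segment p) while they exceed ``p_merge``.  Returns a
    segment table (``SEGMENT_COLUMNS``) tiling the chromosome, with
    ``cnc = ((tumor+1)/(normal+1)) / (tumor_total/normal_total)``.
    """
    if len(windows) == 0:
        raise ValueError("empty window table")
    nw = windows["normal"].to_numpy(dtype=np.int64)
    tw = windows["tumor"].to_numpy(dtype=np.int64)
    # cumulative sums for O(1) flank totals during splitting
    ncum = np.concatenate([[0], np.cumsum(nw)])
    tcum = np.concatenate([[0], np.cumsum(tw)])

    def best_split(lo: int, hi: int) -> Tuple[float, int]:
        """Maximally selected two-proportion chi-square over internal
        cuts of windows [lo, hi); returns (p at the best cut, cut)."""
        best_chi2, best_j = -1.0, -1
        for j in range(lo + 1, hi):
            t1, n1 = tcum[j] - tcum[lo], ncum[j] - ncum[lo]
            t2, n2 = tcum[hi] - tcum[j], ncum[hi] - ncum[j]
            table = np.array([[t1, n1], [t2, n2]], dtype=float)
            if table.sum() == 0:
                continue
            row = table.sum(axis=1)
            col = table.sum(axis=0)
            if (row == 0).any() or (col == 0).any():
                continue
            expected = np.outer(row, col) / table.sum()
            chi2 = ((table - expected) ** 2 / expected).sum()
            if chi2 > best_chi2:
                best_chi2, best_j = chi2, j
        if best_j < 0:
            return 1.0, -1
        return float(stats.chi2.sf(best_chi2, 1)), best_j

    cuts = [0, len(windows)]

    def split_recursive(lo: int, hi: int) -> None:
        if hi - lo < 2:
            return
        p, j = best_split(lo, hi)
        if j >= 0 and p < params.p_init:
            cuts.append(j)
            split_recursive(lo, j)
            split_recursive(j, hi)

    split_recursive(0, len(windows))
    cuts = sorted(set(cuts))

    # greedy merge: repeatedly drop the internal breakpoint whose
    # between-segment test is least significant, while p > p_merge
    def seg_sums(lo: int, hi: int) -> Tuple[int, int]:
        return int(tw[lo:hi].sum()), int(nw[lo:hi].sum())

    while len(cuts) > 2:
        best_p, best_j = -1.0, -1
        for j in range(1, len(cuts) - 1):
            t1, n1 = seg_sums(cuts[j - 1], cuts[j])
            t2, n2 = seg_sums(cuts[j], cuts[j + 1])
            p = _two_proportion_p(t1, n1, t2, n2)
            if p > best_p:
                best_p, best_j = p, j
        if best_p > params.p_merge:
            del cuts[best_j]
        else:
            break

    lib_ratio = tumor_total / normal_total
    rows = []
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        t_sum, n_sum = seg_sums(lo, hi)
        cnc = ((t_sum + 1) / (n_sum + 1)) / lib_ratio
        rows.append(
            (
                chrom,
                int(starts[lo]),
                int(ends[hi - 1]),
                hi - lo,
                n_sum,
                t_sum,
                cnc,
                float(np.log2(cnc)),
            )
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def segment_genome(
    normal_starts: Mapping[str, np.ndarray],
    tumor_starts: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    params: SegmentationParams = SegmentationParams(),
    alignability: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> pd.DataFrame:
    """Window and segment every chromosome; returns one segment table.

    Library totals are the genome-wide read counts after alignability
    masking, so the genome-wide CNC centers at 1.
    """
    masked_n: Dict[str, np.ndarray] = {}
    masked_t: Dict[str, np.ndarray] = {}
    for chrom in chrom_lengths:
        n = np.asarray(normal_starts.get(chrom, np.array([], dtype=np.int64)))
        t = np.asarray(tumor_starts.get(chrom, np.array([], dtype=np.int64)))
        if alignability is not None and chrom in alignability:
            n = apply_alignability_mask(n, alignability[chrom])
            t = apply_alignability_mask(t, alignability[chrom])
        masked_n[chrom] = n
        masked_t[chrom] = t
    n_total = int(sum(len(v) for v in masked_n.values()))
    t_total = int(sum(len(v) for v in masked_t.values()))
    if n_total == 0 or t_total == 0:
        raise ValueError("need reads in both samples")
    pieces = []
    for chrom, length in chrom_lengths.items():
        windows = build_local_windows(masked_n[chrom], masked_t[chrom], length, params)
        pieces.append(
            segment_read_ratios(windows, params, n_total, t_total, chrom=chrom)
        )
    return pd.concat(pieces, ignore_index=True)


def segment_expression_ratio(
    segment: Mapping,
    normal_tx_starts: np.ndarray,
    tumor_tx_starts: np.ndarray,
    normal_total: int,
    tumor_total: int,
) -> float:
    """Library-size-normalized tumor/normal expression ratio of a segment.

    Counts transcriptome read starts inside the segment interval in each
    sample (plus one pseudo-count each) and divides the in-segment ratio
    by the library-total ratio.
    """
    s, e = int(segment["start"]), int(segment["end"])
    n = np.asarray(normal_tx_starts)
    t = np.asarray(tumor_tx_starts)
    n_in = int(((n >= s) & (n < e)).sum()) + 1
    t_in = int(((t >= s) & (t < e)).sum()) + 1
    return (t_in / n_in) / (tumor_total / normal_total)


def split_and_rerun(
    normal_starts: Mapping[str, np.ndarray],
    tumor_starts: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    n_subsets: int = 2,
    seed: int = 0,
    params: SegmentationParams = SegmentationParams(),
) -> Dict:
    """Concordance check: random read subsets should segment alike.

    Reads of each sample are randomly partitioned into ``n_subsets``
    equal-probability subsets; segmentation runs independently on each.
    Returns the per-subset segment tables plus, for each subset pair, the
    breakpoint distances (bp, each breakpoint of one subset matched to the
    nearest of the other) and the correlation of window-level log2 CNC.
    """
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    rng = np.random.default_rng(seed)

    def partition(starts: np.ndarray) -> List[np.ndarray]:
        labels = rng.integers(0, n_subsets, size=len(starts))
        return [np.asarray(starts)[labels == k] for k in range(n_subsets)]

    subsets = []
    for k in range(n_subsets):
        subsets.append(({}, {}))
    for chrom in chrom_lengths:
        for k, part in enumerate(partition(normal_starts[chrom])):
            subsets[k][0][chrom] = part
        for k, part in enumerate(partition(tumor_starts[chrom])):
            subsets[k][1][chrom] = part
    tables = [
        segment_genome(n, t, chrom_lengths, params) for n, t in subsets
    ]

    def internal_breakpoints(table: pd.DataFrame) -> Dict[str, np.ndarray]:
        out = {}
        for chrom, grp in table.groupby("chrom"):
            out[chrom] = grp["start"].to_numpy()[1:]
        return out

    pair_reports = {}
    for a in range(n_subsets):
        for b in range(a + 1, n_subsets):
            dists: List[int] = []
            bk_a = internal_breakpoints(tables[a])
            bk_b = internal_breakpoints(tables[b])
            for chrom in chrom_lengths:
                pa, pb = bk_a.get(chrom, []), bk_b.get(chrom, [])
                for x in pa:
                    if len(pb):
                        dists.append(int(np.min(np.abs(np.asarray(pb) - x))))
            pair_reports[(a, b)] = {
                "breakpoint_distances": dists,
                "n_segments": (len(tables[a]), len(tables[b])),
            }
    return {"segments": tables, "pairs": pair_reports}
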