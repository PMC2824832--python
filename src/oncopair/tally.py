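"""Per-site nucleotide tallies from uniquely aligned reads.

Alignments are consumed in base space: each aligned position carries one
observation in {A, C, G, T} or ``N`` (invalid — an observation that failed
the upstream encoding-validity check and is excluded from all tallies).

Conventions
-----------
* Coordinates are 0-based half-open internally; tally tables report a
  1-based ``pos`` column.  BED inputs/outputs are 0-based half-open.
* Trimming operates in read orientation: the last ``n_trim`` positions of
  the alignment *as sequenced* are masked, because reverse-transcription
  and sequencing errors accumulate at the read's 3' end.  On the minus
  strand these are the lowest genomic coordinates.
* Coverage used by downstream thresholds is counted after trimming and
  after the unique-alignment filter.
* ``max_same_start`` records, per nucleotide, the largest number of its
  supporting observations that share one (alignment start, strand) pair.
  A fragment duplicated by over-amplification of an RT error lands at a
  single start on a single strand, so this statistic is the handle the
  duplicate-start artifact filter needs.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
INVALID = "N"

#: column order of the site tally table (one row per position x sample)
TALLY_COLUMNS = (
    ["chrom", "pos", "sample"]
    + [f"count_{n}" for n in NUCLEOTIDES]
    + [f"max_same_start_{n}" for n in NUCLEOTIDES]
    + ["coverage"]
)


@dataclass
class AlignmentRecord:
    """One gapless alignment of a read to the genome.

    ``observed`` holds the per-position observations in genomic orientation
    (index 0 = genomic coordinate ``start``); its length equals the aligned
    length.  ``margin`` is the score margin to the next-best alignment of
    the same read, or ``None`` when the read aligned to a single place.
    """

    read_id: str
    chrom: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    observed: str  # over {A,C,G,T,N}, genomic orientation
    score: int
    margin: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.observed) < 1:
            raise ValueError("alignment must cover at least one position")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def filter_unique_alignments(
    records: Iterable[AlignmentRecord],
    min_score: int = 24,
    min_margin: int = 4,
) -> Iterator[AlignmentRecord]:
    """Keep uniquely aligned reads.

    A read is uniquely aligned when its best alignment scores at least
    ``min_score`` and beats the next-best placement by at least
    ``min_margin``.  A read with a single placement has no competitor
    (``margin is None``) and passes the margin condition by definition.
    Input order is preserved.
    """
    if min_score < 0 or min_margin < 0:
        raise ValueError("min_score and min_margin must be non-negative")
    for rec in records:
        if rec.score < min_score:
            continue
        if rec.margin is not None and rec.margin < min_margin:
            continue
        yield rec


def trim_alignment_tail(record: AlignmentRecord, n_trim: int = 5) -> AlignmentRecord:
    """Mask the last ``n_trim`` aligned positions of the read as sequenced.

    The masked positions become ``N`` and therefore contribute nothing to
    tallies; the record length and coordinates are unchanged.  For a
    minus-strand alignment the read's 3' end sits at the *lowest* genomic
    coordinates, so the mask is applied at the front of ``observed``.
    """
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim == 0:
        return record
    k = min(n_trim, len(record.observed))
    if record.strand == "+":
        masked = record.observed[: len(record.observed) - k] + INVALID * k
    else:
        masked = INVALID * k + record.observed[k:]
    return replace(record, observed=masked)


def build_site_tallies(
    records: Iterable[AlignmentRecord], sample: str
) -> pd.DataFrame:
    """Tally valid per-position observations into a site table.

    Records are expected to be trimmed and uniqueness-filtered already.
    Per position each nucleotide's observation count is accumulated,
    together with ``max_same_start``: the largest number of observations of
    that nucleotide sharing one (alignment start, strand).  ``N``
    observations are dropped.  Returns a DataFrame with ``TALLY_COLUMNS``
    (``pos`` 1-based), sorted by (chrom, pos).
    """
    counts: dict = defaultdict(lambda: np.zeros(4, dtype=np.int64))
    by_start: dict = defaultdict(lambda: defaultdict(int))
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for rec in records:
        for offset, obs in enumerate(rec.observed):
            if obs == INVALID:
                continue
            try:
                j = nuc_index[obs]
            except KeyError:
                raise ValueError(f"invalid observation {obs!r} in read {rec.read_id}")
            key = (rec.chrom, rec.start + offset)
            counts[key][j] += 1
            by_start[key][(j, rec.start, rec.strand)] += 1

    rows = []
    for (chrom, pos), cnt in counts.items():
        mss = np.zeros(4, dtype=np.int64)
        for (j, _, _), c in by_start[(chrom, pos)].items():
            if c > mss[j]:
                mss[j] = c
        rows.append((chrom, pos + 1, sample, *cnt, *mss, int(cnt.sum())))
    df = pd.DataFrame(rows, columns=TALLY_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def make_tally_frame(
    chrom,
    pos,
    sample: str,
    counts: np.ndarray,
    max_same_start: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assemble a tally table from arrays (n_sites x 4 counts).

    ``max_same_start`` defaults to ``min(counts, 1)`` — every observation
    at a distinct start — which is the artifact-free limit.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be an (n_sites, 4) array")
    if max_same_start is None:
        max_same_start = np.minimum(counts, 1)
    max_same_start = np.asarray(max_same_start, dtype=np.int64)
    if np.any(max_same_start > counts):
        raise ValueError("max_same_start cannot exceed counts")
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "sample": sample})
    for i, n in enumerate(NUCLEOTIDES):
        df[f"count_{n}"] = counts[:, i]
    for i, n in enumerate(NUCLEOTIDES):
        df[f"max_same_start_{n}"] = max_same_start[:, i]
    df["coverage"] = counts.sum(axis=1)
    return df[list(TALLY_COLUMNS)]


class AllelicRatio(NamedTuple):
    """log2(ref/alt) read ratio, or the reason it is undefined."""

    value: Optional[float]
    reason: Optional[str]


def allelic_ratio(
    ref_count: int, alt_count: int, coverage: int, min_coverage: int = 15
) -> AllelicRatio:
    """log2 of (reads supporting the reference) / (reads supporting the
    first catalogued alternate), defined only at adequately covered sites
    where both alleles were observed.

    ``coverage`` is the site's total filtered coverage (all four
    nucleotides), which is what the coverage floor applies to.
    """
    if coverage < min_coverage:
        return AllelicRatio(None, f"below {min_coverage}x")
    if ref_count <= 0 and alt_count <= 0:
        return AllelicRatio(None, "neither allele observed")
    if alt_count <= 0:
        return AllelicRatio(None, "alt allele not observed")
    if ref_count <= 0:
        return AllelicRatio(None, "ref allele not observed")
    return AllelicRatio(math.log2(ref_count / alt_count), None)


def counts_matrix(tallies: pd.DataFrame) -> np.ndarray:
    """(n_sites, 4) int array of A/C/G/T counts from a tally table."""
    return tallies[[f"count_{n}" for n in NUCLEOTIDES]].to_numpy(dtype=np.int64)


def max_same_start_matrix(tallies: pd.DataFrame) -> np.ndarray:
    """(n_sites, 4) int array of max_same_start values from a tally table."""
    return tallies[[f"max_same_start_{n}" for n in NUCLEOTIDES]].to_numpy(
        dtype=np.int64
    )


def pair_tallies(normal: pd.DataFrame, tumor: pd.DataFrame) -> pd.DataFrame:
    """Inner-join normal and tumor tally tables on (chrom, pos).

    Returns one row per shared position with ``_normal``/``_tumor``
    suffixed count, max_same_start and coverage columns, sorted by
    position.  Only positions present in both samples are testable for
    relative imbalance, so the join is inner.
    """
    value_cols = [c for c in TALLY_COLUMNS if c not in ("chrom", "pos", "sample")]
    n = normal[["chrom", "pos"] + value_cols]
    t = tumor[["chrom", "pos"] + value_cols]
    paired = n.merge(t, on=["chrom", "pos"], suffixes=("_normal", "_tumor"))
    return paired.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_tally_tsv(path) -> pd.DataFrame:
    """Read a site tally TSV written by :func:`write_tally_tsv`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(TALLY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tally table missing columns: {sorted(missing)}")
    return df


def write_tally_tsv(df: pd.DataFrame, path) -> None:
    """Write a site tally TSV (1-based ``pos``, header comment with the
    coordinate convention)."""
    with open(path, "w") as fh:
        fh.write("# site tally table; pos is 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_alignments_sam(path, min_mapq: int = 0) -> Iterator[AlignmentRecord]:
    """Yield :class:`AlignmentRecord` from a SAM/BAM file via pysam.

    The observed sequence is taken from the aligned portion of the read;
    soft-clipped bases are excluded.  The alignment score is read from the
    ``AS`` tag and the margin from ``AS - XS`` when an ``XS``
    (next-best-score) tag is present.  Reads without ``AS`` get a score of
    0 and are typically removed by the uniqueness filter.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.mapping_quality < min_mapq:
                continue
            pairs = aln.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            seq = aln.query_sequence or ""
            start = pairs[0][1]
            # build a genomic-orientation observation string; positions
            # skipped by indels become N over the gap
            end = pairs[-1][1]
            obs = [INVALID] * (end - start + 1)
            for qpos, rpos in pairs:
                if qpos is not None and rpos is not None and qpos < len(seq):
                    base = seq[qpos].upper()
                    obs[rpos - start] = base if base in NUCLEOTIDES else INVALID
            score = aln.get_tag("AS") if aln.has_tag("AS") else 0
            margin = None
            if aln.has_tag("XS"):
                margin = int(score) - int(aln.get_tag("XS"))
            yield AlignmentRecord(
                read_id=aln.query_name or "",
                chrom=aln.reference_name or "",
                start=int(start),
                strand="-" if aln.is_reverse else "+",
                observed="".join(obs),
                score=int(score),
                margin=margin,
            )
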