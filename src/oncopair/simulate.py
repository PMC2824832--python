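"""Synthetic paired tumor/normal cohorts with known ground truth.

The generator emulates the data structure of a paired tumor/normal
RNA-seq study of a small patient cohort: per-site nucleotide tallies at
catalogued variant positions, per-gene read counts, genomic (DNA)
read-start tracks, and qPCR cycle-threshold tables — all with planted
effects recorded in truth tables so that every downstream detector can be
scored against what was actually simulated.

Signal and noise model
----------------------
* Genotypes at catalogued sites are heterozygous with probability
  ``het_fraction``, otherwise homozygous (mostly reference).
* Site coverage is Poisson around ``mean_site_coverage``; in the tumor it
  is additionally scaled by the total copy ratio of any overlapping
  copy-number segment.
* Observations at a site are multinomial over the four nucleotides; a
  per-observation sequencing error of rate ``sequencing_error_rate``
  redirects an observation uniformly over the three other nucleotides.
* An allele-specific copy-number segment with tumor:normal ratio ``r`` on
  one haplotype distorts the heterozygous allele proportion to
  ``r / (r + 1)`` for the affected allele (copy-proportional expression).
* A fraction ``rt_artifact_rate`` of sites receives a duplicate-start
  artifact: ``k >= coverage/2`` observations of an erroneous nucleotide,
  all sharing a single alignment start, in one sample only — the
  signature of a reverse-transcription error amplified and over-sampled
  during library preparation.  This is exactly the failure mode the
  duplicate-start filter must catch.
* Gene counts are Poisson around a log-normal baseline; planted
  differentially expressed genes multiply the tumor mean by
  ``2 ** effect`` with effects drawn from ``de_log2_effect``; overlapping
  copy-number segments multiply it by the total copy ratio.
* Genomic read starts are sampled per 1 kb bin with Poisson-multinomial
  rates proportional to local copy number.

Alignment starts for tally observations are drawn uniformly over the
50 bp upstream window on either strand, which reproduces the benign level
of start-sharing expected from random fragmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from oncopair.allelic_imbalance import GeneModel, KnownVariant
from oncopair.tally import NUCLEOTIDES, TALLY_COLUMNS, make_tally_frame

READ_LENGTH = 50  # span of possible alignment starts covering a site
_GENOTYPES = ("hom-ref", "het", "hom-alt")


@dataclass(frozen=True)
class CNSegmentSpec:
    """A planted copy-number segment.

    ``ratio`` is the tumor:normal copy ratio of the *affected* haplotype
    relative to its normal single copy when ``haplotype`` is "A" or "B"
    (allele-specific event), or of both haplotypes when ``haplotype`` is
    "both".  The total tumor:normal copy ratio of the segment is
    ``(ratio + 1) / 2`` for allele-specific events and ``ratio`` for
    balanced ones.
    """

    chrom: str
    start: int
    end: int
    ratio: float
    haplotype: str = "A"  # "A", "B", or "both"

    def total_ratio(self) -> float:
        if self.haplotype == "both":
            return self.ratio
        return (self.ratio + 1.0) / 2.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults mirror a small paired
    tumor/normal study analyzed at adequate pileup depth."""

    seed: int = 0
    n_patients: int = 3
    genome: Sequence[Tuple[str, int]] = (("chr1", 10_000_000),)
    n_genes: int = 200
    n_variant_sites: int = 2_000
    het_fraction: float = 1.0 / 3.0
    mean_site_coverage: float = 50.0
    sequencing_error_rate: float = 0.005
    rt_artifact_rate: float = 0.0
    de_gene_fraction: float = 0.1
    de_log2_effect: Tuple[float, float] = (0.0, 2.5)  # (mean, sd)
    cn_segments: Sequence[CNSegmentSpec] = ()
    genomic_reads_per_sample: int = 200_000
    qpcr_noise_sd: float = 0.15
    qpcr_replicates: int = 4
    qpcr_n_normals: int = 6

    def __post_init__(self) -> None:
        for name in ("het_fraction", "sequencing_error_rate", "rt_artifact_rate",
                     "de_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_site_coverage <= 0:
            raise ValueError("mean_site_coverage must be positive")
        for name in ("n_patients", "n_genes", "n_variant_sites",
                     "genomic_reads_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lengths = {c: l for c, l in self.genome}
        by_chrom: Dict[str, List[CNSegmentSpec]] = {}
        for seg in self.cn_segments:
            if seg.chrom not in lengths:
                raise ValueError(f"cn_segments: unknown chromosome {seg.chrom}")
            if not (0 <= seg.start < seg.end <= lengths[seg.chrom]):
                raise ValueError(f"cn_segments: bad interval {seg}")
            if seg.ratio <= 0:
                raise ValueError("cn_segments: ratio must be positive")
            if seg.haplotype not in ("A", "B", "both"):
                raise ValueError("cn_segments: haplotype must be A, B or both")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"cn_segments: overlapping segments on {chrom}"
                    )


@dataclass
class TruthTables:
    """Ground truth of one simulated cohort."""

    # per patient: chrom, pos (1-based), ref, alt, genotype
    genotypes: Dict[str, pd.DataFrame]
    # per patient: het sites with a true allele-frequency shift
    planted_ai_sites: Dict[str, pd.DataFrame]
    # per patient: duplicate-start artifact sites (chrom, pos, sample, nucleotide)
    planted_artifact_sites: Dict[str, pd.DataFrame]
    planted_de_genes: pd.Series  # gene -> true log2 tumor/normal effect
    planted_breakpoints: Dict[str, List[int]]  # chrom -> internal breakpoints
    planted_segment_ratios: pd.DataFrame  # chrom, start, end, ratio, haplotype, total_ratio


@dataclass
class PatientData:
    patient: str
    tallies: Dict[str, pd.DataFrame]  # sample -> tally table
    gene_counts: pd.DataFrame  # index gene_id, columns normal/tumor raw counts
    totals: Dict[str, int]  # sample -> total uniquely aligned transcriptome reads
    genomic_reads: Dict[str, Dict[str, np.ndarray]]  # sample -> chrom -> starts


@dataclass
class Cohort:
    config: SimulationConfig
    genes: List[GeneModel]
    variants: List[KnownVariant]
    patients: List[PatientData]
    truth: TruthTables


def _segment_lookup(
    cn_segments: Sequence[CNSegmentSpec],
) -> Dict[str, List[CNSegmentSpec]]:
    out: Dict[str, List[CNSegmentSpec]] = {}
    for seg in cn_segments:
        out.setdefault(seg.chrom, []).append(seg)
    for segs in out.values():
        segs.sort(key=lambda s: s.start)
    return out


def _segment_at(
    lookup: Mapping[str, List[CNSegmentSpec]], chrom: str, pos0: int
) -> Optional[CNSegmentSpec]:
    for seg in lookup.get(chrom, []):
        if seg.start <= pos0 < seg.end:
            return seg
    return None


def _place_genes(rng: np.random.Generator, config: SimulationConfig) -> List[GeneModel]:
    """Non-overlapping two-exon genes spread evenly over the genome."""
    total_len = sum(l for _, l in config.genome)
    genes: List[GeneModel] = []
    per_chrom = [
        max(1, round(config.n_genes * l / total_len)) for _, l in config.genome
    ]
    # adjust to hit n_genes exactly
    while sum(per_chrom) > config.n_genes:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < config.n_genes:
        per_chrom[int(np.argmin(per_chrom))] += 1
    gid = 0
    for (chrom, length), k in zip(config.genome, per_chrom):
        if k <= 0:
            continue
        pitch = length // k
        span = min(2500, max(30, pitch // 2))
        exon = max(10, span // 3)
        for i in range(k):
            start = i * pitch + pitch // 10
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [(start, start + exon), (start + 2 * exon, start + 3 * exon)]
            genes.append(
                GeneModel(gene_id=f"G{gid:05d}", chrom=chrom, strand=strand,
                          exons=exons)
            )
            gid += 1
    return genes


def _place_variants(
    rng: np.random.Generator, config: SimulationConfig
) -> List[KnownVariant]:
    nucs = np.array(NUCLEOTIDES)
    variants: List[KnownVariant] = []
    total_len = sum(l for _, l in config.genome)
    for chrom, length in config.genome:
        k = max(1, round(config.n_variant_sites * length / total_len))
        pos = np.sort(
            rng.choice(length, size=min(k, length), replace=False)
        )
        for p in pos:
            i, j = rng.choice(4, size=2, replace=False)
            variants.append(
                KnownVariant(chrom=chrom, pos=int(p) + 1, ref=str(nucs[i]),
                             alt=str(nucs[j]))
            )
    return variants


def _max_same_start(rng: np.random.Generator, count: int) -> int:
    """Largest clump when ``count`` observations pick alignment starts
    uniformly over READ_LENGTH positions on two strands."""
    if count <= 1:
        return count
    starts = rng.integers(0, READ_LENGTH * 2, size=count)
    return int(np.bincount(starts).max())


def _simulate_patient_tallies(
    rng: np.random.Generator,
    config: SimulationConfig,
    variants: Sequence[KnownVariant],
    seg_lookup: Mapping[str, List[CNSegmentSpec]],
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    geno = rng.choice(
        3,
        size=len(variants),
        p=[
            (1 - config.het_fraction) * 0.8,
            config.het_fraction,
            (1 - config.het_fraction) * 0.2,
        ],
    )
    e = config.sequencing_error_rate

    tally_rows: Dict[str, list] = {"normal": [], "tumor": []}
    geno_rows = []
    ai_rows = []
    artifact_rows = []
    for v, g in zip(variants, geno):
        genotype = _GENOTYPES[g]
        geno_rows.append((v.chrom, v.pos, v.ref, v.alt, genotype))
        ref_i, alt_i = nuc_index[v.ref], nuc_index[v.alt]
        seg = _segment_at(seg_lookup, v.chrom, v.pos - 1)

        # true allele proportions per sample (ref, alt shares)
        props = {}
        if genotype == "het":
            props["normal"] = (0.5, 0.5)
            if seg is not None and seg.haplotype in ("A", "B"):
                # the affected haplotype carries one of the two alleles;
                # phase is random per site
                affected_is_ref = rng.random() < 0.5
                p_aff = seg.ratio / (seg.ratio + 1.0)
                props["tumor"] = (
                    (p_aff, 1 - p_aff) if affected_is_ref else (1 - p_aff, p_aff)
                )
                shift = abs(p_aff - 0.5)
                ai_rows.append((v.chrom, v.pos, shift))
            else:
                props["tumor"] = (0.5, 0.5)
        elif genotype == "hom-ref":
            props["normal"] = props["tumor"] = (1.0, 0.0)
        else:
            props["normal"] = props["tumor"] = (0.0, 1.0)

        cov_scale = {"normal": 1.0, "tumor": seg.total_ratio() if seg else 1.0}
        has_artifact = rng.random() < config.rt_artifact_rate
        artifact_sample = ("normal", "tumor")[rng.integers(0, 2)] if has_artifact else None

        for sample in ("normal", "tumor"):
            cov = rng.poisson(config.mean_site_coverage * cov_scale[sample])
            p_ref, p_alt = props[sample]
            probs = np.full(4, 0.0)
            probs[ref_i] = p_ref
            probs[alt_i] = p_alt
            probs = probs * (1 - e) + e * (1 - probs) / 3.0
            probs /= probs.sum()
            counts = rng.multinomial(cov, probs) if cov > 0 else np.zeros(4, int)
            mss = np.array([_max_same_start(rng, int(c)) for c in counts])
            if sample == artifact_sample and cov > 0:
                # an RT error burst: k >= cov/2 copies of a non-allele
                # nucleotide, all sharing one alignment start
                others = [i for i in range(4) if i not in (ref_i, alt_i)]
                err_i = others[rng.integers(0, len(others))]
                k = math.ceil(cov * 0.5) + int(rng.integers(0, max(1, cov // 4)))
                counts[err_i] += k
                mss[err_i] = max(mss[err_i], k)
                artifact_rows.append(
                    (v.chrom, v.pos, sample, NUCLEOTIDES[err_i], k)
                )
            tally_rows[sample].append((v.chrom, v.pos, counts, mss))

    tallies = {}
    for sample, rows in tally_rows.items():
        chroms = [r[0] for r in rows]
        pos = [r[1] for r in rows]
        counts = np.array([r[2] for r in rows])
        mss = np.array([r[3] for r in rows])
        tallies[sample] = make_tally_frame(chroms, pos, sample, counts, mss)
    genotypes = pd.DataFrame(
        geno_rows, columns=["chrom", "pos", "ref", "alt", "genotype"]
    )
    ai_sites = pd.DataFrame(ai_rows, columns=["chrom", "pos", "expected_shift"])
    artifacts = pd.DataFrame(
        artifact_rows, columns=["chrom", "pos", "sample", "nucleotide", "n_copies"]
    )
    return tallies, genotypes, ai_sites, artifacts


def _simulate_gene_counts(
    rng: np.random.Generator,
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    de_effects: pd.Series,
    seg_lookup: Mapping[str, List[CNSegmentSpec]],
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    base = rng.lognormal(mean=math.log(200.0), sigma=1.0, size=len(genes))
    raw = {}
    for sample in ("normal", "tumor"):
        means = base.copy()
        if sample == "tumor":
            for i, g in enumerate(genes):
                mid = (g.start + g.end) // 2
                seg = _segment_at(seg_lookup, g.chrom, mid)
                scale = seg.total_ratio() if seg else 1.0
                means[i] *= scale * 2.0 ** de_effects.get(g.gene_id, 0.0)
        raw[sample] = rng.poisson(means)
    df = pd.DataFrame(
        {"normal": raw["normal"], "tumor": raw["tumor"]},
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    # library totals: genic reads plus ~10% intergenic background
    totals = {
        s: int(df[s].sum() + rng.poisson(0.1 * max(df[s].sum(), 1)))
        for s in ("normal", "tumor")
    }
    return df, totals


def _simulate_genomic_reads(
    rng: np.random.Generator,
    config: SimulationConfig,
    seg_lookup: Mapping[str, List[CNSegmentSpec]],
) -> Dict[str, Dict[str, np.ndarray]]:
    """Poisson-multinomial read starts per 1 kb bin, tumor rate scaled by
    local total copy ratio."""
    bin_size = 1000
    out: Dict[str, Dict[str, np.ndarray]] = {"normal": {}, "tumor": {}}
    # weights per chromosome per sample
    weights: Dict[str, Dict[str, np.ndarray]] = {"normal": {}, "tumor": {}}
    for chrom, length in config.genome:
        n_bins = math.ceil(length / bin_size)
        w_norm = np.ones(n_bins)
        w_tum = np.ones(n_bins)
        for seg in seg_lookup.get(chrom, []):
            lo, hi = seg.start // bin_size, math.ceil(seg.end / bin_size)
            w_tum[lo:hi] = seg.total_ratio()
        weights["normal"][chrom] = w_norm
        weights["tumor"][chrom] = w_tum
    for sample in ("normal", "tumor"):
        total_w = sum(w.sum() for w in weights[sample].values())
        for chrom, length in config.genome:
            w = weights[sample][chrom]
            n_reads = rng.poisson(config.genomic_reads_per_sample * w.sum() / total_w)
            per_bin = rng.multinomial(n_reads, w / w.sum())
            starts = []
            for b, c in enumerate(per_bin):
                if c:
                    lo = b * bin_size
                    hi = min(length, lo + bin_size)
                    starts.append(rng.integers(lo, hi, size=c))
            out[sample][chrom] = (
                np.sort(np.concatenate(starts)) if starts else np.array([], dtype=int)
            )
    return out


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort.

    A fixed seed yields byte-identical outputs.  Gene placement, the
    variant catalog and the planted differential-expression effects are
    shared across patients (the cohort-level truth); genotypes, tallies,
    counts and read tracks are drawn independently per patient.
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(rng, config)
    variants = _place_variants(rng, config)
    seg_lookup = _segment_lookup(config.cn_segments)

    gene_ids = [g.gene_id for g in genes]
    n_de = round(config.de_gene_fraction * len(genes))
    de_genes = list(rng.choice(gene_ids, size=n_de, replace=False))
    mu, sd = config.de_log2_effect
    effects = rng.normal(mu, sd, size=n_de)
    de_effects = pd.Series(effects, index=de_genes, dtype=float).sort_index()

    seg_rows = [
        (s.chrom, s.start, s.end, s.ratio, s.haplotype, s.total_ratio())
        for s in config.cn_segments
    ]
    breakpoints: Dict[str, List[int]] = {}
    for chrom, length in config.genome:
        pts = sorted(
            {s.start for s in seg_lookup.get(chrom, [])}
            | {s.end for s in seg_lookup.get(chrom, [])}
        )
        breakpoints[chrom] = [p for p in pts if 0 < p < length]

    patients = []
    genotypes = {}
    ai_truth = {}
    artifact_truth = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1}"
        tallies, geno, ai, artifacts = _simulate_patient_tallies(
            rng, config, variants, seg_lookup
        )
        counts, totals = _simulate_gene_counts(
            rng, config, genes, de_effects, seg_lookup
        )
        reads = _simulate_genomic_reads(rng, config, seg_lookup)
        patients.append(
            PatientData(
                patient=pid,
                tallies=tallies,
                gene_counts=counts,
                totals=totals,
                genomic_reads=reads,
            )
        )
        genotypes[pid] = geno
        ai_truth[pid] = ai
        artifact_truth[pid] = artifacts

    truth = TruthTables(
        genotypes=genotypes,
        planted_ai_sites=ai_truth,
        planted_artifact_sites=artifact_truth,
        planted_de_genes=de_effects,
        planted_breakpoints=breakpoints,
        planted_segment_ratios=pd.DataFrame(
            seg_rows,
            columns=["chrom", "start", "end", "ratio", "haplotype", "total_ratio"],
        ),
    )
    return Cohort(config=config, genes=genes, variants=variants,
                  patients=patients, truth=truth)


def simulate_qpcr_tables(
    truth: TruthTables,
    config: SimulationConfig,
    assay_genes: Optional[Sequence[Tuple[str, float]]] = None,
) -> pd.DataFrame:
    """Copy-number qPCR CT tables for a panel of assayed genes.

    Each assayed gene is measured in one tumor and ``qpcr_n_normals``
    normal samples with ``qpcr_replicates`` replicate reactions, twice —
    once per control locus (RNaseP, TERT).  Target-channel CT is
    ``base_ct - log2(copies) + noise`` with tumor copies ``2 * r`` for a
    planted total ratio ``r`` (normals carry 2 copies); the control
    channel always sees 2 copies.  With zero noise the recovered ddCT of a
    2x gain is exactly -1.

    ``assay_genes`` optionally overrides the panel as (gene id, planted
    total copy ratio) pairs; by default one assay per planted segment plus
    one copy-neutral control gene.
    """
    rng = np.random.default_rng(config.seed + 1)
    if assay_genes is None:
        assay_genes = [
            (f"SEG_{r.chrom}_{r.start}", float(r.total_ratio))
            for r in truth.planted_segment_ratios.itertuples(index=False)
        ]
        assay_genes.append(("NEUTRAL", 1.0))
    base_target, base_control = 26.0, 24.0
    rows = []
    samples = [("tumor", None)] + [
        (f"normal{i + 1}", None) for i in range(config.qpcr_n_normals)
    ]
    for gene, ratio in assay_genes:
        for control in ("RNaseP", "TERT"):
            for sample, _ in samples:
                copies = 2.0 * ratio if sample == "tumor" else 2.0
                for rep in range(config.qpcr_replicates):
                    ct_t = (
                        base_target
                        - math.log2(copies)
                        + rng.normal(0.0, config.qpcr_noise_sd)
                    )
                    ct_c = (
                        base_control
                        - math.log2(2.0)
                        + rng.normal(0.0, config.qpcr_noise_sd)
                    )
                    rows.append((gene, control, sample, rep + 1, "target", ct_t))
                    rows.append((gene, control, sample, rep + 1, "control", ct_c))
    return pd.DataFrame(
        rows, columns=["gene", "control_locus", "sample", "replicate",
                       "channel", "ct"]
    )


def qpcr_dct_arrays(
    ct_table: pd.DataFrame, gene: str, control_locus: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Extract (tumor dCT replicates, normal-panel dCT matrix) for one
    assay from a CT table produced by :func:`simulate_qpcr_tables`."""
    sub = ct_table[
        (ct_table["gene"] == gene) & (ct_table["control_locus"] == control_locus)
    ]
    wide = sub.pivot_table(
        index=["sample", "replicate"], columns="channel", values="ct"
    )
    dct = (wide["target"] - wide["control"]).unstack("replicate")
    tumor = dct.loc["tumor"].to_numpy(dtype=float)
    normals = dct.drop(index="tumor").to_numpy(dtype=float)
    return tumor, normals


# ---------------------------------------------------------------------------
# writers: everything the CLI dumps to disk, all plain text


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write tallies, gene counts, read-start BEDs, truth tables and the
    variant catalog under ``outdir`` (plain-text formats only)."""
    import os

    from oncopair.tally import write_tally_tsv

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "variants.tsv"), "w") as fh:
        fh.write("# variant catalog; pos is 1-based\nchrom\tpos\tref\talt\n")
        for v in cohort.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")
    with open(os.path.join(outdir, "genes.bed"), "w") as fh:
        for g in cohort.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )
    for pat in cohort.patients:
        pdir = os.path.join(outdir, pat.patient)
        os.makedirs(pdir, exist_ok=True)
        for sample, df in pat.tallies.items():
            write_tally_tsv(df, os.path.join(pdir, f"tally_{sample}.tsv"))
        pat.gene_counts.to_csv(os.path.join(pdir, "gene_counts.tsv"), sep="\t")
        with open(os.path.join(pdir, "totals.tsv"), "w") as fh:
            fh.write("sample\ttotal\n")
            for s, t in pat.totals.items():
                fh.write(f"{s}\t{t}\n")
        for sample, tracks in pat.genomic_reads.items():
            with open(os.path.join(pdir, f"reads_{sample}.bed"), "w") as fh:
                for chrom, starts in tracks.items():
                    for s in starts:
                        fh.write(f"{chrom}\t{s}\t{s + 1}\n")
        cohort.truth.genotypes[pat.patient].to_csv(
            os.path.join(pdir, "truth_genotypes.tsv"), sep="\t", index=False
        )
        cohort.truth.planted_ai_sites[pat.patient].to_csv(
            os.path.join(pdir, "truth_ai_sites.tsv"), sep="\t", index=False
        )
        cohort.truth.planted_artifact_sites[pat.patient].to_csv(
            os.path.join(pdir, "truth_artifacts.tsv"), sep="\t", index=False
        )
    cohort.truth.planted_de_genes.rename("log2_effect").to_csv(
        os.path.join(outdir, "truth_de_genes.tsv"), sep="\t"
    )
    cohort.truth.planted_segment_ratios.to_csv(
        os.path.join(outdir, "truth_segments.tsv"), sep="\t", index=False
    )
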