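# Methods

This note documents the statistical procedures implemented in `oncopair`,
the assumptions behind them, the tunable parameters and their defaults,
and what the synthetic-cohort generator does and does not emulate.

## Setting

The package targets the integrative analysis of a small cohort of
patients, each contributing a tumor sample and a matched normal sample
profiled by strand-specific RNA-seq (plus genomic read tracks for copy
number and qPCR assays for validation).  Four questions are addressed:

1. At which transcribed positions do the two alleles change their
   relative expression between normal and tumor (*relative allelic
   imbalance*, AI)?
2. Which genes are concordantly up- or down-regulated across patients?
3. Where has the tumor genome gained or lost copies relative to the
   normal genome?
4. How do copy-number changes relate to expression changes and to AI?

## Per-site tallies and upstream filters

Analysis starts from per-position nucleotide tallies over uniquely
aligned reads.  "Uniquely aligned" means an alignment score of at least
24 with a margin of at least 4 over the next-best placement of the same
read; a read with a single placement has no competitor and passes the
margin condition by definition.  The last 5 aligned positions of each
read *as sequenced* are masked before tallying, because
reverse-transcription and sequencing errors, and exon/intron mis-pairing
near splice junctions, concentrate at the read's 3' end.  Observations
flagged invalid upstream are excluded.  All coverage thresholds apply to
these filtered, trimmed tallies.

Alongside the four nucleotide counts, each tally row records
`max_same_start[n]`: the largest number of observations of nucleotide
`n` that share one (alignment start, strand).  Start+strand identifies
the placement of a sequenced fragment, so this statistic captures the
signature of an RT error that was amplified during library preparation
and over-sampled during sequencing — many "reads" that are really copies
of one molecule.

## Relative allelic imbalance

At each position covered in both samples, the 2 x 4 (sample x
nucleotide) table of counts is tested for independence with Pearson's
chi-square.  Nucleotide columns with zero marginal total are dropped
first — they carry no information and would produce 0/0 expected counts
— leaving a 2 x k table with k - 1 degrees of freedom; a single shared
nucleotide is degenerate (statistic 0, p = 1).  No continuity correction
and no minimum-expected-count rule are applied beyond the coverage
filter below.

A site is AI-positive when all four filters pass (each threshold is a
parameter of `AIThresholds`):

| filter | default | meaning |
|---|---|---|
| `min_cov` | 15 | coverage in **both** samples, post-trim |
| `max_p` | 1e-3 | chi-square p-value must be below this |
| `min_delta` | 0.10 | some nucleotide's absolute frequency must change by **more than** this |
| `max_dupstart_frac` | 0.90 | no nucleotide may have more than this fraction of its supporting reads at one start+strand, in either sample |
| `min_dupstart_count` | 2 | duplicate-start filter applies only to nucleotides with at least this many reads |

`min_dupstart_count` deserves a word.  A nucleotide supported by a
single read trivially has 100% of its reads at one start; a lone
observation carries no evidence of over-sampling, and treating it as
disqualifying would discard essentially every adequately covered site
that harbors one residual sequencing-error observation.  The filter
therefore only engages once a nucleotide has at least two supporting
reads, which is the minimum at which "all of its reads share one start"
is informative.  The planted-artifact recovery tests show this version
removes 100% of simulated RT bursts while discarding well under 1% of
clean true-signal sites.

Membership in the known-variant catalog is annotated but *not* required,
so imbalance caused by de novo point mutation remains detectable.

The scalar "|AI|" used downstream is `max_abs_delta`, the largest
absolute per-nucleotide frequency change between the samples.  An
alternative would be the change in log allelic ratio; the frequency
delta is bounded, defined without pseudo-counts, and is the quantity the
detection filter already uses, so we use it throughout.

### Genotypes from allelic ratios

The log2 allelic ratio (reference reads / first-alternate reads,
requiring 15x site coverage and both alleles observed) is trimodal over
catalogued sites: homozygous reference, heterozygous, homozygous
alternate.  Classification uses boundaries at +-2.0 on the log2 scale
(inclusive on the homozygous side), chosen to sit in the valleys between
the three modes at typical coverage; the boundaries are exposed as a
parameter since they are a convention, not an estimate.  Sites where
only one allele was observed at adequate coverage are classified
homozygous for that allele directly.

### Gene-level rollup

AI-positive sites are assigned to every gene whose span overlaps them,
on both strands — an imbalanced site inside an antisense overlap is
evidence about both annotations.  Each positive site gets a region
class: annotated 3' UTR, exonic, near-splice-site (intronic within 10 bp
of an exon boundary), or intronic.  Recurrence across patients is the
number of patients with at least one AI-positive site in the gene.

## Differential expression by rank aggregation

Raw gene counts sum the uniquely aligned reads whose alignment *start*
falls inside an exon, on the annotated strand (the protocol is
strand-specific; the start-position rule makes reads spanning exon
boundaries unambiguous).  Normalized expression is `(raw + 1) / total
uniquely aligned reads`; the single pseudo-count keeps tumor/normal
ratios finite.  No transcript-length normalization is applied: every
downstream quantity is a within-gene fold-change.  Genes are retained
only if in *every* patient at least one tissue has >= 50 raw reads.

Within each patient, genes are ranked by log2 tumor/normal ratio
(ascending, average ranks on ties).  The per-gene median rank across
patients — lower-median convention for even patient counts — defines
the commonly mis-regulated sets: the `set_size` (default 300) lowest
median ranks are the down set, the highest are the up set, with median
ties broken by gene identifier so the sets are deterministic.

The shuffled-pairing null permutes each patient's ratio vector over
genes independently, destroying shared signal while keeping the marginal
distributions; the per-gene exceedance is the fraction of (shuffle,
gene) median ranks at least as extreme as the observed one, toward the
tail the observed rank leans to.  With one patient the null median rank
is uniform, which the tests use as an analytic anchor.

## Copy-number segmentation

The tumor:normal ratio of uniquely aligned genomic read counts over a
window estimates the local copy-number change (CNC).  Windows are
delimited to contain exactly `W = 400` normal read starts each, so the
normal count per window is constant and the tumor count carries the
signal.  Candidate breakpoints are found by recursive binary splitting:
within a stretch of windows, the cut maximizing the two-proportion
chi-square of the flanking tumor-vs-normal read sums becomes a candidate
when its p-value is below `p_init`, and both flanks are split further.
Splitting on segment sums rather than single adjacent windows is what
gives the procedure power at modest ratio steps (a 1.5x step is
reliably found once a few thousand reads flank the cut).  Candidates are
then pruned by greedy merging — the adjacent pair with the least
significant between-segment test merges first, while that p-value
exceeds `p_merge`.

Defaults `p_init = 1e-4`, `p_merge = 1e-5` are calibrated so that a null
genome of ~5,000 windows yields on the order of one spurious segment
(the split step proposes a handful of false candidates genome-wide; the
merge step removes nearly all of them).  Per-segment
`cnc = ((tumor + 1) / (normal + 1)) / (tumor_total / normal_total)`;
the pseudo-counts keep deleted regions finite, and the library-total
ratio makes the genome-wide CNC 1 by construction — CNC is a *relative*
quantity, measured against the genome average, which matters when a
large fraction of the genome is aberrant.  An optional alignability mask
(e.g. 100 kb alignable windows) drops reads outside alignable regions
before windowing.  A split-and-rerun utility partitions the reads into
random subsets and verifies that segmentation is stable, the standard
internal-concordance check for read-ratio methods.

A segment's expression ratio is the tumor/normal ratio of transcriptome
reads (or summed gene counts) in the interval, pseudo-counted and
normalized by the library totals, mirroring the CNC normalization.

## Integration

* **CNC vs expression** — Pearson correlation of per-segment log2 CNC
  against log2 expression ratio, optionally restricted to segments with
  a copy change above a fold floor (e.g. 1.4x).
* **CNC bins vs |AI|** — heterozygous sites are taken from the *normal*
  sample alone: catalogued positions where both the reference and first
  alternate allele have >= 4 reads.  Each site inherits the |log2 CNC|
  bin of its covering segment — low [0, 1.2), moderate [1.2, 1.8),
  large [1.8, inf), boundary values to the higher bin; a site covered
  by no segment (masked region) is treated as copy-neutral.  The
  moderate and large bins are compared against the low bin with a
  one-sided Mann-Whitney test (alternative: shifted to higher |AI|),
  exact enumeration below 20 observations per side and the
  tie-corrected normal approximation otherwise.
* **Gene-set overlaps** — expected overlap `n*K/N` and hypergeometric
  upper tail `P(X >= k)` via the survival function (log-space
  internally).  The AI-vs-DE report returns whole-percent observed and
  expected overlap; the gene universe is a required input for any
  p-value, since overlap significance is meaningless without it.

## qPCR validation statistics

dCT is the mean CT difference between target and control channel (or
allele 1 and allele 2); ddCT is tumor dCT minus normal dCT; the fold
change is `2^(-ddCT)` (lower CT = more template, so negative ddCT is a
gain).  A genomic-DNA allele contrast with |dCT| > 4.0 is called
homozygous for the lower-CT allele, otherwise heterozygous.

The copy-number test contrasts one tumor against a panel of 6 normals,
4 replicate dCT values each.  The point estimate is the median tumor
dCT minus the median of per-normal median dCTs.  Replicate noise is
estimated by pooling the within-sample deviations of the 24 normal dCT
values (df = 18).  Because the estimator is built from medians, its
variance is not sigma^2/n: using order-statistic constants for normal
samples (variance of the median of 4 ~ 0.2983 sigma^2; median of 6
i.i.d. values ~ 0.2146x their variance), `Var(ddCT) ~ 0.2983 * (1 +
0.2146) * sigma^2`, and the t statistic uses that scale with 18 degrees
of freedom.  Simulation confirms the per-assay null rejection rate sits
at the nominal alpha.  A gene's copy change is accepted only when the
test rejects with *both* control loci (RNaseP and TERT), so the
genome-wide acceptance rate under the null is approximately alpha^2.

Validation-rate bookkeeping: the false-positive rate is failed
validations over assayed predicted-positives; the genotype attribution
is the fraction of failures traceable to a false heterozygous genotype;
when a revised filter chain is applied retrospectively, the post-filter
FP rate is computed over surviving predictions and the false-negative
rate counts validated positives lost to the filter, over all assayed
positions.  All rates are reported as whole percents.

## The synthetic cohort

`oncopair.simulate` generates everything the pipeline consumes, with
ground truth.  The model, in brief: genotypes at catalogued sites are
heterozygous with probability 1/3; site coverage is Poisson with mean
50 per sample (tumor scaled by local total copy ratio); observations
are multinomial over nucleotides with a 0.5% per-observation error
spread uniformly over the three non-true nucleotides (representing the
residue that survives upstream validity filtering); alignment starts
are uniform over a 50 bp window on two strands.  An allele-specific
copy segment with ratio r on one haplotype moves the het allele
proportion to r/(r+1) (copy-proportional expression).  A configurable
fraction of sites receives a duplicate-start burst: >= coverage/2
copies of a non-allele nucleotide at a single start in one sample —
exactly the artifact the 90% filter exists to remove.  Gene counts are
Poisson around a log-normal baseline (median ~200 reads), with tumor
means scaled by planted log2 effects (default N(0, 2.5) over 10% of
genes) and local copy ratio; library totals add ~10% intergenic
background.  Genomic read tracks are Poisson-multinomial per 1 kb bin
with tumor rates proportional to copy number.  qPCR CT values are
`base - log2(copies) + N(0, 0.15)` per replicate.

What it does *not* emulate: read-level sequences and alignment (tallies
are generated directly), splice structure beyond two-exon gene models,
mappability variation, GC or fragment-length bias, positional error
gradients within reads (trimming is exercised on constructed alignment
records, not on the cohort), subclonal heterogeneity, and correlated
errors between tumor and normal.  Passing parameter-recovery tests
therefore demonstrates that the statistics behave as designed under
their own model assumptions — binomial/Poisson counting noise with
planted effects — not that real tissue data is free of the systematic
artifacts the filters target; on real data the filter thresholds carry
the burden the tests cannot.

## Problem sizes and numerical choices

The tests and the acceptance script run deliberately scaled-down
cohorts (10,000-site null cohorts; 2,000-site cohorts for AI recovery
over 5 seeds; 30,000-read chromosomes over 10 seeds for breakpoint
recovery; a 50-chromosome null genome for the false-segment count;
3,000 random 2x4 tables plus exhaustive small-table enumeration for the
chi-square oracle), sizes at which every recovery statistic is stable
across seeds while the whole suite runs in well under a minute per
module.  Ties in ranks use average ranks; ties in the DE sets break on
gene identifier; chromosome order follows the input genome; all
internal coordinates are 0-based half-open with 1-based positions in
report tables.  Degenerate inputs (zero-coverage sites, single-column
tables, chromosomes with fewer reads than one window, zero-variance
qPCR panels) return defined results or named errors rather than NaNs.

## Known limitations

* The chi-square test at p < 1e-3 with the magnitude filter has a
  type-I rate of essentially 1e-3 per het site at 50x coverage (the
  >10% frequency-change filter only binds at higher coverage), so on a
  cohort of pure het null sites roughly one call per thousand sites is
  expected by chance; homozygous sites are untestable and dilute the
  cohort-wide rate.
* CNC is relative to the genome average; heavily aberrant genomes shift
  the baseline, and bin boundaries (1.2/1.8 on |log2 CNC|) are applied
  to the library-normalized values.
* The rank-aggregation null assumes exchangeability of genes within a
  patient; gene-length or expression-level dependence of ratio variance
  is not modeled.
* The qPCR variance constants assume approximately normal replicate
  noise; heavy-tailed replicate failures would call for a robust scale
  estimate instead.
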