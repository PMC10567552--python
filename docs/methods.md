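# Methods

This note records the models, parameter choices and numerical conventions
behind `epigerm`, and what a green test does and does not establish.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED convention) internally; 1-based
inclusive coordinates from external sources are converted on ingestion.
Supported formats are BED3/6/12, 10-column narrowPeak, 2-column chrom-sizes
and a 5-column `cpg_counts` TSV (chrom, start, end, n_mod, n_unmod), all
tab-delimited, headerless and gzip-transparent.  Every writer/reader pair is
round-trip exact.

## Methylation calling

The per-CpG modification level is `n_mod / (n_mod + n_unmod)` — in
pyridine-borane sequencing the modified cytosine reads as T, so `n_mod` is
the T channel and `n_unmod` the C channel.  TAPSβ reports 5mC and CAPS+
reports 5hmC directly; no subtraction between chemistries is needed or
performed.  "Covered more than 5 times" is read strictly as coverage ≥ 6.
CpGs are treated strand-combined (one record per CpG dinucleotide, position
of the C on the plus strand).

Spike-in conversion is the aggregate ratio `Σ n_mod / Σ coverage` over fully
modified control positions (false conversion: the same ratio over unmodified
controls).  Called rates are **not** corrected by the conversion estimate;
it is reported as QC only.  Consequently, a non-unit conversion rate
attenuates every called level multiplicatively.

Tiles are fixed 1,000-bp windows anchored at coordinate 0 on each
chromosome (the grid origin is a convention; nothing downstream depends on
it).  A tile is retained with ≥ 3 passing CpGs; its level is the unweighted
mean of passing CpG rates (bigWigAverageOverBed semantics over a per-CpG
track), and the genome-wide level is the unweighted mean over retained
tiles.  The distribution view is a Gaussian KDE with *absolute* bandwidth
0.05 on the [0, 1] rate scale (scipy's relative `bw_method` is divided by
the sample sd to achieve this).

Region averages use the same coverage filter; with the "covered in all
samples" flag a CpG counts only if it passes the filter in every supplied
track.  Regions failing an optional ≥ 3 CpG filter are NA, never silently
dropped.

## DMR detection

Per CpG with ≥ 2 defined replicate rates per group, a pooled-variance
two-sample t with df = n₁ + n₂ − 2 (unpaired; replicate pairing is not
assumed).  Zero pooled variance yields t = 0 for equal means, signed
infinity otherwise.  Candidates have |t| above the two-sided critical value
at α = 0.05.  Candidates merge into a run while the inter-CpG gap is
strictly < 300 bp *and* the per-CpG mean differences share a sign (sign
homogeneity prevents hyper/hypo chimeras).  A run is a DMR when it has
≥ 3 CpGs and |mean over the run of per-CpG (experimental − control)| clears
the modality cutoff: 0.2 for 5mC, 0.05 for 5hmC.  The `pct_min` parameters
exist in the config for fidelity but are inert at their default 0.

Numerical notes: run-count monotonicity in the merge gap holds for
unfiltered runs; the ≥ 3-CpG and mean-difference filters can break it by
fragmenting runs, which the tests acknowledge.  The reported DMR interval
spans the first candidate C through the last candidate's G.

## Peak handling and annotation

Replicate peak sets are filtered at −log₁₀(q) strictly greater than the
threshold (default 10) and reduced to peaks of replicate 1 overlapping
(≥ 1 bp) a passing replicate-2 peak; replicate-1 coordinates are retained
since the consensus representation is otherwise arbitrary.  Annotation
anchors each region at its midpoint: nearest gene minimizes |midpoint −
TSS| with ties broken lexicographically by gene id; the feature category is
evaluated against all genes with precedence promoter-TSS > exon > TTS >
intron > intergenic.  Windows follow HOMER's annotatePeaks defaults:
promoter-TSS = TSS −1,000/+100 bp and TTS = gene 3′ end −100/+1,000 bp,
strand-aware.  Repeat overlap ties go to the largest overlap, then
lexicographic subfamily.

Matched random regions draw lengths with replacement from a template set
and place them uniformly (chromosome chosen proportional to length),
rejection-sampling against an optional constraint with a bounded attempt
budget; fully deterministic per seed.

## Motif scanning and enrichment

Exact IUPAC scanning matches overlapping occurrences on both strands
(reverse-complement matches are reported on "−" with the motif-strand
sequence); count-matrix mode scores log-odds against a uniform background
with a +0.25 pseudocount per cell.  Enrichment counts a region as "with
motif" at ≥ 1 hit (presence/absence, matching the binomial model):
p = P(X ≥ k), X ~ Binomial(n_target, n_bg_with/n_bg), BH-adjusted across
motifs.  A zero background rate with target hits is floored at 1/(n_bg+1)
and flagged.  Because the original background construction is
unrecoverable, backgrounds are length-matched random regions sampled with a
recorded seed; this is a documented substitute, and only known-motif
enrichment is implemented (no de-novo discovery).

## Expression

`per1e8` scales every sample to a fixed total of 1×10⁸ (the repeat-element
convention); CPM and RPKM (`count·10⁹ / (length·library)`) are also
provided.  The differential test is a deliberate stand-in for a
negative-binomial GLM: two-sided Welch t on log2(CPM+1) across replicates,
BH correction, log2 fold change from mean CPM with pseudocount 1.  The
calling rule is strict: fold change > 2 and FDR < 0.05; a fold change of
exactly 2 is NS.  Published differential lists are therefore not
reproduction targets — only the threshold logic and recovery behavior on
synthetic data are.

"PGC genes" are genes enriched (logFC > 1, FDR < 0.05) in both the week-7
and week-9 comparisons, where within a week passing against gonadal somatic
cells *or* against conventional ES cells suffices (union; the stricter
intersection reading is available via `mode`).  Reported marker-set
percentages are rounded half-away-from-zero to integers with the unrounded
value retained.

## Imaging

Segmentation: DoG = Gaussian(σ_small) − Gaussian(σ_large) on the DAPI
channel, Otsu threshold on the DoG image, 8-connected labeling, area filter.
The kernel sizes are not specified by the upstream protocol; σ_small = 0.1×
and σ_large = 0.5× the expected nucleus diameter are used.  "Scale
normalization" (also unspecified upstream) is per-batch division by the
median intensity of control-condition nuclei, which makes cross-condition
dot plots acquisition-gain invariant; it is exposed as a strategy choice.
Analysis is 2-D single-plane; touching nuclei are not watershed-split.

## The synthetic world

The generator's defaults state the world the tests probe:

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 1 Mb, CpG density 0.01/bp | ~20k CpGs; desk-scale but large enough for stable tile statistics |
| stages | ES, nascent, committed; 2 methylome replicates | mirrors the profiled stages and replicate design |
| global 5hmC | 5.5% / 4.2% / 10.1% | the study-scale stage levels |
| global 5mC | 79% / 78% / 76% | "largely similar at ~76–79%" |
| per-CpG spread | Beta, concentration 30 | realistic tile-level spread without bimodality artifacts |
| bound sites | 40 × 300 bp, ≥ 5 CpGs each, exact DMRT1 motif `TTGAAACACTCTTTT` | every planted DMR spans ≥ 3 CpGs; every site is motif-positive |
| planted deltas | Δ5hmC +0.4, Δ5mC −0.3 at bound sites (committed) | strong locus-specific gain/loss on top of the global shift |
| coverage | Poisson, mean 30; conversion 1.0 | typical base-resolution depth; conversion left at 1 so configured stage levels are also the expected *called* levels (non-unit conversion is exercised explicitly in tests) |
| expression | NB, lognormal means (median 200), dispersion 0.05; 30 up / 15 down at |log2FC| = 3; 80% of up genes drawn from intron-bound genes | couples activation to binding, keeps the DE fraction small enough that library-size inflation does not swamp fold changes |
| peaks | jitter ≤ 50 bp, q = 10 + Exp(8), 10 replicate-private false peaks | every true peak clears the strict q > 10 filter, so zero-false-peak configs recover the planted count exactly |
| images | 512², 25 nuclei r = 8–14 px; 5hmC 2,000→4,000, 5mC 8,000→4,000 (control→induced), pixel noise sd 200 | planted 2× 5hmC gain and 0.5× 5mC loss, comfortably above noise |

Two structural choices matter for interpreting results:

1. **Stage coupling.** Each CpG keeps its rank across stages — a shared
   Beta quantile models CpG-intrinsic propensity, and stages differ through
   the Beta mean.  Background stage contrasts therefore carry the *genuine*
   global shift (5.5% → 10.1% 5hmC), exactly as real committed-stage data
   would.  A consequence worth knowing: the DMR caller legitimately finds
   hyper-5hmC DMRs beyond the planted bound sites (they are real shifts of
   the simulated world), so planted-site "precision" on the default world is
   ~0.35 by design, while on a shared-background scenario (equal stage
   means, planted blocks only) sensitivity and precision both exceed 0.9.
2. **Global-level contract.** The committed-stage background mean is
   calibrated (two fixed-point iterations against the analytically expected
   tile mean) so that the genome-wide 1-kb tile mean equals the configured
   global level *including* the planted mass.  Measured across 10 seeds the
   committed 5hmC tile mean is 0.1011 ± 0.0004 (sd), so the acceptance band
   of ±0.002 around 0.101 is ≈ 4σ of the generator's Monte-Carlo spread.

What the generator does **not** emulate: read-level errors and mapping
biases (simulation starts at converted-base counts), sequence evolution or
real repeat sequence content (repeats are placed intervals with subfamily
labels), bimodal CpG-island methylation structure, correlated replicate
batch effects, 3-D nuclear morphology, and scRNA-seq of any kind.  A green
recovery test therefore establishes correctness of the implemented
computations and their calibration on an idealized world — not robustness
to alignment artifacts or real biological confounders.

## Determinism

One seed drives everything; sub-streams derive from the seed plus stable
string tags (CRC32), so any stage can be re-simulated independently and
`run_all` is byte-identical across reruns of the same (config, seed).
Output directories are named by a hash of the full config rather than a
timestamp.

## Known limitations

- The DE stand-in underestimates the power of a proper NB GLM at small
  counts; on the default world (lognormal means) its sensitivity for
  planted |log2FC| = 3 genes is ~0.8, rising above 0.9 at uniform mean 200.
- Per-library normalization makes strong global induction depress apparent
  fold changes of unchanged features (a property shared with the upstream
  convention of fixed-total normalization).
- The per-CpG t with 2 replicates per group has heavy-tailed behavior at
  df = 2; calibration is tested under normal per-replicate rates, where the
  candidate rate is nominal by construction.
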