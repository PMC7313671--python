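# Methods

## Copy-number estimation

Copy number is the ratio of mean per-base read depth over the element
consensus to mean per-base depth over the host genome, both with zero-depth
positions in the denominator. Depth excludes secondary/supplementary records
and records below MAPQ 20 by default (`DepthFilters`); clipped reads that map
poorly are deliberately kept for split-read evidence at a separate, lower
threshold (MAPQ 1). A line with fewer than 0.5 estimated copies — less than a
single heterozygous copy — is classified M, at or above 0.5 P (the boundary
itself is P because the rule is *strictly fewer than* 0.5).

The estimator reports **sequence dosage**, not copy count: internally-deleted
copies contribute less depth than complete ones, so a line rich in truncated
copies sits below its true copy count (visible for the panel's `line08`).
This mirrors how depth-ratio estimates behave on real data and is why the
truncation profile exists.

On simulated homozygous lines (100-kb genome, 30× coverage, 150-bp pairs) the
median estimate over 20 replicates stays within a few percent of truth for
k ∈ {0,1,2,5,10,20} copies, and cytotype calls are 100% correct. Under
partial zygosity the expectation is z·k (carrier-fraction linearity).

## Truncation profiling

Per-base element coverage is accumulated half-open over [0, L). The exon
summary compares mean depth over the terminal exons (0 and 3) to the internal
exons (1 and 2): with truncated {0,3}-only copies three times as numerous as
complete copies the expected fold is (3+1)/1 = 4. Long reads that span an
insertion with ≥200 bp genomic anchors on both sides classify each copy
directly: an exon is *retained* when ≥80% of its bases are covered by the
read's element-aligned segments (the 80% threshold is this package's choice;
there is no field standard). A read is segmented into alternating genome /
element runs first, so one long read spanning several insertions yields one
call per insertion.

## Insertion-site calling

Short-read calls: a genome-aligned record clipped by ≥20 bp whose read also
aligns to a terminal (TIR-proximal, 200 bp) element window contributes a
breakpoint at the clipped edge. Breakpoints on one contig within 10 bp chain
into a group; groups with ≥3 reads emit a site. Precision is *exact* when the
modal breakpoint holds a strict majority of the support, otherwise
*approximate* with the support-weighted median position. All thresholds are
arguments.

The simulator duplicates 8 bp of target site at each insertion, so the two
junctions of one insertion sit 8 bp apart and truth records the duplication
midpoint; called positions land within ±4 bp of it, within the ±5 bp
recovery tolerance used throughout. Cross-line clustering is single-linkage
within 50 bp with at most one site kept per line per cluster (nearest to the
cluster median; surplus same-line sites split into singleton clusters so the
site count is conserved).

`haplotype_sites_per_copy` = sites / (lines × haplotypes per line × mean
copies) is reported truncated to three decimals, matching the printed
convention of the tallies it is used with (1311/(6·40·6.6) → 0.827).

## Phenotype models

Ovary count (0/1/2 functional ovaries) follows a three-category multinomial
logit with the healthy two-ovary state as the reference category, so positive
logit shifts read directly as dysgenesis. Fitting uses statsmodels' MNLogit;
separation (an empty category, divergence, or non-convergence) triggers a
small-ridge (α = 10⁻³) penalized refit by direct optimization, flagged and
without Wald SEs, never silent. Mean ovarioles per functional ovary is a
log-link Poisson GLM on the integer-rounded response; rounding is half-up to
the nearest integer by default with a ceiling option (`rounding="up"`), since
both conventions are in circulation for this assay. Fully atrophied females
are missing data for ovariole models but full data for ovary-count models;
a female with ≥1 atrophied ovary counts as dysgenic.

Terms are tuples of column names; categorical columns expand to
treatment-coded dummies and interactions are elementwise products. Type-III
tests delete one term at a time and compare by LRT, with marginality
enforced: a main effect is never deletable while any interaction containing
it remains. Stepwise simplification repeatedly removes the least significant
deletable term with p > α, which by construction works from the
highest-order interactions downward. The multinomial "type III" uses LR
statistics (not Wald).

The two-sample Fisher–Pitman test standardizes the group-sum statistic and
takes the two-sided permutation tail: exhaustive enumeration of label
assignments for pooled n ≤ 10, Monte Carlo (with the +1 correction)
otherwise. The pairwise-comparison threshold 0.05/6 ≈ 0.008 ships as
`presets.BONFERRONI_ALPHA`. D² = (null − residual)/null deviance; for the
multinomial, deviances use the −2·log-likelihood convention (individual-level
data, saturated log-likelihood 0), to which D² is invariant. The bootstrap
D² comparison resamples each dataset with replacement, refits, and compares
the two D² distributions by a permutation Wilcoxon rank-sum test.

### A dispersion caveat

The per-female response is the *mean* ovariole count over (up to) two
ovaries. Each ovary's count is Poisson in the generator, so the mean of two
has variance μ/2: the applied Poisson models are mildly under-dispersed and
therefore conservative (LRTs slightly under-reject; CIs slightly
over-cover). Calibration checks of the statistical engine — type-I error of
the LRT, CI coverage of the generator→fitter loop — are therefore run on
responses that exactly meet the model assumptions (directly Poisson draws,
or per-ovary counts), where type-I lands in [0.03, 0.07] and 95% CI coverage
in [92%, 98%]. The applied per-female-mean models match the study design;
their conservatism is a property of that design, not a defect of the engine.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions: a 2,907-bp four-exon element
with 31-bp terminal inverted repeats (and a 2,959-bp, 12-bp-TIR second
element), isofemale-line genomes carrying 0–25 full or {0,3}-truncated
copies placed uniformly with ≥2-kb separation and 8-bp target-site
duplications, 100–150-bp paired-end reads at ~30× (pair count =
cov·L/(2·read length), normal fragment lengths 400±40), and long reads with
gamma-distributed lengths (shape 4, mean 15 kb). Reads carry *truth
alignments* — the records an ideal mapper would emit, split at element
junctions with clip fields set, blocks under 15 bp dropped as unmappable —
so every downstream stage runs without an external aligner; an aligner can
be substituted by feeding real SAM/PAF through `formats.parse_alignments`.

Deliberately not modeled: realistic Illumina/Nanopore error profiles
(substitution errors are uniform; default 0.1% short, 5% long), base-quality
variation, reference bias and mappability (truth alignments are perfect, so
recovery rates here bound what a real mapper can achieve), piRNA repression
dynamics, and chromatin context of insertion sites. Passing tests therefore
demonstrate correctness of the estimators and callers given alignments, not
robustness to mapping artifacts.

Phenotype presets encode the qualitative dysgenesis pattern — atrophy and
ovariole loss only in ♀M×♂P progeny, only above 25 °C (the activated
temperature scale `temp_act` = max(0, (T−25)/4) is 0 at ≤25 °C and 1 at
29 °C), rising with paternal copy number — with synthetic magnitudes: the
study reports test statistics rather than reusable effect sizes. Two anchors
are taken from reported quantities: a healthy ovary averages ~20 ovarioles,
and the senescence preset's four-way coefficient (−0.00094) is set so that
at the population-mean paternal copy number (~6.6) the dysgenic cross's
age-slope contrast is ≈ −6.2×10⁻³ per day on the log scale, the size of
contrast the assay is meant to resolve. All randomness flows from one master
seed through per-operation `SeedSequence` children, so fixed seeds give
byte-identical FASTQ and phenotype output and partial re-runs are
reproducible.

## Problem sizes and numerical choices

Validation experiments use 100-kb genomes at 30× (20 replicates per copy
count), 1,000 null simulations for LRT calibration, 500 simulations for CI
coverage, samples of 1,000–2,000 females for coefficient recovery, and
300–500 bootstrap resamples for D² comparisons — sizes at which every
quantity is stable to well within its stated tolerance while the whole
suite runs in minutes. Ties in permutation tests are handled by the
≥-with-epsilon rule (|S| ≥ |S_obs| − 10⁻⁹); LRT χ² is floored at 0; the
copy-number ratio raises on a zero genome depth rather than returning 0.

## Known limitations

- The depth-ratio estimator conflates truncation with low copy number
  (dosage, as above); combining it with the long-read structure calls is the
  supported way to resolve the ambiguity.
- Short-read calling assumes the clipped-side element alignment survives in
  the input; with aggressive mapper filtering, junction evidence can vanish
  before it reaches the caller.
- The ridge fallback for separated multinomial fits reports no standard
  errors; downstream type-III tests still work (they are likelihood-based),
  but Wald-style summaries are flagged NaN.
- Orientation calls require unanimous element-side strands among supporting
  reads; mixed evidence reports "unknown" rather than guessing.
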