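# Methods

This note documents the models and procedures implemented in `germscan`,
the parameters that matter, the synthetic-data generator's assumptions, and
the numerical and design choices made where the design was genuinely open.

## Differential-coverage scan

The scan infers germline-restricted sequence from one germline (sperm) and
one somatic (blood) per-base depth track on the same assembly.

**Validity.** A base is valid when depth ≥ `dmin` (default 1) in at least
one sample and ≤ `dmax` in both. `dmax` guards collapsed repeats, where
depth piles up in both samples and the ratio is uninformative; when a run
is configured from a simulation block the pipeline sets
`dmax = 10 × max(λ_g, λ_s)`; on file inputs it is unbounded unless set.

**Equal-information intervals.** Each sequence is tiled by a linear pass
accumulating valid bases; an interval closes at its V-th valid base
(default V = 1000). A trailing partial interval is kept when it holds at
least V/2 valid bases, otherwise merged into its predecessor (kept alone if
it is the only one). This makes every interval carry the same amount of
evidence regardless of local coverage gaps, at the cost of variable genomic
width. Interval depth means d1, d2 are taken over valid bases only.

**Enrichment score.** E = log2((d1 + ψ)/(AFR · (d2 + ψ))), with
AFR = genome-wide mean sperm depth / mean blood depth over valid bases
(library standardization) and pseudodepth ψ = 1/V. One continuous formula
covers the zero-blood-depth case; as depth grows E converges to the pure
standardized log-ratio. Note AFR > 1 whenever part of the genome is
germline-restricted: blood reads concentrate on retained sequence, raising
mean blood depth there.

**Segmentation.** Interval scores are segmented per sequence by recursive
binary segmentation: the candidate split maximizes the pooled two-sample
t statistic (a perfect step with zero within-side variance maps to +inf);
it is accepted when a permutation p-value — best-split statistic over
`n_perm` (default 1000) seeded shuffles of the segment's scores, with the
+1/(n+1) correction — is below α (default 0.01) and both sides hold at
least `min_width` (default 2) intervals. The recursion equals an
exhaustive-split search with the same acceptance rule (tested against one).
Permutations are vectorized and chunked to bound memory.

**Calling and sequence classification.** Segments with mean score strictly
greater than τ = 2 are enriched (>4-fold standardized enrichment; the
threshold is strict and exposed). A sequence is *germline* when ≥ 50% of
its interval-covered bases are enriched and no single non-enriched segment
covers ≥ 20% of them; *somatic* with zero enriched bases; *mixed*
otherwise. Mixed sequences violate the whole-chromosome-elimination
expectation and are surfaced as a count in the report.

## Gene assignment

Same-name gene records whose spans overlap (transitively, ≥ 1 bp, same
sequence) collapse to the longest record — the "canonical transcript" rule;
exact-length ties break to the lexicographically smallest gene id.
Non-overlapping same-name records are paralogs and all survive. Assignment
uses any-overlap (≥ 1 bp) semantics against enriched segments, the default
behaviour of interval-intersection tools; coordinates are 0-based half-open
throughout, so a gene ending where a segment starts does not overlap it.
The default biotype filter retains protein-coding genes only (rRNA, tRNA,
lncRNA and pseudogene records are dropped before assignment). Families are
name-based — no sequence-similarity clustering — and per family the GSR and
somatic copy counts, single-copy status and presence of somatic paralogs
are reported.

## Expression cascade

Size factors are median-of-ratios: sf_j = median over genes with
all-positive counts of k_ij / (geometric mean of gene i). This is exactly
the conventional RNA-seq estimator; note it is scale-equivariant only up to
one global factor (scaling a single sample by λ moves the whole normalized
matrix by λ^(1/m) through the geometric means — the between-sample
structure is untouched).

The strongly-male-biased call is a three-stage cascade on normalized
counts, with male groups {PM, EM, MM, LM} (prospective plus definitive
males) and female groups {EF, MF, LF}; undifferentiated larvae belong to
neither:

1. *candidate*: log2((m̄+c)/(f̄+c)) > L (default 2) for either c = c1 = 1
   (light pseudocount) or c = c2 = 8 (shrunken, damping low-count ratios).
   The two-estimator union emulates taking the union of two differential
   expression pipelines that differ mainly in shrinkage strength.
2. *filter*: summed normalized count over male-group samples > T
   (default 1000) — removes genes male-biased only in ratio, not in
   magnitude. The filter uses normalized counts and includes prospective
   males, both exposed as parameters.
3. *strong*: the top ceil(q · n_passing) survivors (q = 0.20), ranked by
   max of the two estimators, exact ties broken by gene id. Ceiling
   rounding and the deterministic tie-break make the strong-set size an
   exact function of the passing count.

Group summaries report per-gene medians (midpoint convention) with a
low-expression flag at median < 5, strict. Embryo classification compares
mean raw counts between pre- and post-rearrangement sample groups:
*expressed* at mean ≥ 1 (a choice — the source analyses say "expressed"
without a threshold), *high* at mean > 50.

## Statistics

The 2×2 table (strong × compartment) yields the sample odds ratio
(a/b)/(c/d), reported as infinite when b·c = 0, and a two-sided Fisher
exact p by the "hypergeometric probabilities ≤ observed" rule with the
conventional 1 + 1e-7 relative tie tolerance; a doubled-one-sided
alternative is exposed. All pmf sums run in log space (cached
log-factorials), so p-values far below float underflow keep a finite
log10. When a pipeline run produces an empty strong set (as null
calibration runs do), the table has a zero margin, no association is
testable, and the report carries p = 1 with a note instead of aborting.

The published analysis compared stage-expression profiles between genomes
with a repeated-measures mixed model; that model is an off-the-shelf fit,
not a contribution, and is deliberately replaced here by a
distribution-free permutation test on the same response: per-gene stage
proportions (each male stage, females pooled; zero-total genes dropped and
counted), statistic |mean GSR − mean somatic| per stage, null from seeded
shuffles of compartment labels, p = (1 + #{perm ≥ obs})/(n_perm + 1),
Benjamini–Hochberg across the five stages at α = 0.05. `n_perm` below 100
records a warning in the result.

Log2 M:F distributions are summarized per compartment by a Gaussian KDE
with the classic Silverman bandwidth 0.9·min(sd, IQR/1.34)·n^(-1/5); the
mode is the argmax on a 512-point grid spanning the data range, with a
zero-bandwidth guard returning the common value for degenerate input.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes, with one
seed expanded into named substreams (genome, depth, counts, embryo,
segmentation, permutation) so components regenerate independently and
results are single-threaded deterministic.

* **Genome**: 8 somatic chromosomes + 6 germline scaffolds, 10 Mb total,
  20% germline content (lengths drawn with ±30% variation and rescaled).
  Elimination is whole-sequence in truth; an `n_mosaic` switch plants
  half-eliminated scaffolds for negative testing of the mixed-sequence
  detector.
* **Genes**: 30 germline families with geometric copy numbers clipped to
  [1, 77]; 55% of families also receive 1–3 somatic paralogs; 1000
  single-copy somatic background genes; a few non-coding records exercise
  the biotype filter. Genes are placed non-overlapping via random cuts.
* **Depth**: per-base Poisson — sperm λ_g = 30 genome-wide; blood λ_s = 30
  on retained sequence and λ_r = 0.6 (λ_s/50) on eliminated sequence.
  Poisson per-base depth, not read placement: the scan consumes depth only.
  Planted regions exceed the score-2 threshold in expectation whenever
  λ_s/λ_r > 4; setting λ_r = λ_s is the no-elimination null.
* **Counts**: NB with variance μ + φμ² (φ = 0.2) on group means × a
  log-normal per-sample library multiplier (σ = 0.15). 28 gonadal samples
  (UD 2, EF 2, MF 6, LF 2, PM 4, EM 4, MM 6, LM 2). Germline genes follow
  a male profile peaking in prospective and mid males (μ 800/150/800/150
  for PM/EM/MM/LM) and μ = 1 in female-like groups, reproducing the
  published contrast (high male medians, female medians < 5). A set of
  moderately male-biased somatic genes (logFC uniform in 2.6–4.8,
  baselines floored so they clear the count filter) populates the
  classifier's candidate pool: genome-wide, strong genes are the top slice
  of a much larger male-biased pool, and without such a pool the top-q cut
  would tautologically cap recovery of planted genes at q. Their count is
  4.2× the planted-GSG count, placing the top-20% cut at about the planted
  count with margin for the normalization shift (median-of-ratios pulls
  all logFCs down ~0.3 because male libraries carry the planted signal).
  `sex_symmetric=True` switches every gene to the shared baseline.
* **Embryo** (optional): pre-/post-rearrangement groups of 3 samples;
  somatic genes keep their baseline, most germline genes are near-silent
  (μ 0.3), 30% lowly expressed (μ 3), and a small planted set high (μ 80).

What the generator does **not** model — and hence what passing tests do not
establish about real data: mappability and GC bias, repeat structure and
collapsed assemblies, fragment-level read placement, partial or mosaic
elimination beyond the synthetic switch, isoform structure, batch effects,
and dispersion trends across expression strata. Recovery rates on synthetic
data are a correctness check of the inference chain under its stated
assumptions, not a field-accuracy estimate.

## Problem sizes and runtime choices

The default synthetic genome is 10 Mb — large enough that every sequence
holds hundreds of equal-information intervals and base-level recovery rates
are meaningful to three digits, small enough that the full pipeline runs in
seconds. Null-calibration sweeps (20 seeds) and most unit tests use a 2 Mb
genome with the same structure and proportionally fewer genes, chosen so
the candidate pool and compartment sizes stay in the regime the defaults
target. Permutation-uniformity checks use 200 replicates of 60-gene
proportion tables at n_perm = 199.

## Known limitations

* Single germline and single somatic sample; no multi-sample or
  replicate-aware depth model.
* The binary segmentation is a deliberate simplification of circular binary
  segmentation: it is fully specifiable and oracle-checkable, but can split
  conservatively on gradual trends.
* The logFC estimators are group-mean ratios with pseudocounts, not
  dispersion-estimating differential-expression models; per-gene DE
  p-values are out of scope by design.
* Name-based paralogy inherits annotation quality; genes with inconsistent
  naming split or merge families.
* The printed odds ratio in the source analysis (36.5068) is not exactly
  the sample OR of its printed counts (36.19); the sample OR is reported
  here and both round to the headline 36×.
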