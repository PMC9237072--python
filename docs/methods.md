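# Methods

This note documents the models behind each pipeline, the defaults and why
they were chosen, the numerical and calibration decisions that were
genuinely open, what the synthetic data does and does not emulate, and the
known limitations.

## Data model

Counts are genes × units in memory (a *unit* is a cell, a bulk sample or a
pseudobulk aggregate), non-negative integers with unique string labels on
both axes; matrices stored units × genes on disk are re-oriented using the
companion label files.  Phase labels `G2/M`, `G2M`, `g2m` normalize to
`G2M`.  Missing values serialize as `NA`.  All stochastic steps draw from
a seed recorded in `PipelineConfig` (default 1), so identical
configuration yields bit-identical outputs.

## Bulk differential test

Genes are kept when they exceed 5 CPM in every member of at least one
replicate set (a (stage, phase) group) and average above 5 CPM overall.
Between-sample scaling uses trimmed-mean-of-M-values factors with the
canonical defaults: reference column by upper-quartile proximity to the
mean, 30% two-sided trim on M, 5% on A, delta-method precision weights,
factors normalized to product 1 (verified against edgeR to < 0.2%).  Note
the M-values are scale-free but the precision weights are not, so the
factors are only approximately invariant to rescaling a single column.

The per-gene test fits `log mu = b0 + b1·[G2M]` by quasi-likelihood IRLS
**on the CPM scale** with gene-wise method-of-moments dispersion
(variance = μ + φμ², pooled within-group variance on n − 2 df, floored at
1e-8) estimated on the same scale.  Two consequences of working on the
normalized scale: the size offsets cancel exactly, so the call set is
invariant to globally rescaling all counts; and the dispersion plug-in
matches the scale of the fitted model.  Because that plug-in is noisy at
small n, the Wald statistic (b1/se)² is referred to **F(1, n − 2)** rather
than chi-square(1); the two agree as n grows, and the F reference keeps
the type-I error at the nominal level down to 3 replicates per phase
(measured 0.05 at n = 10+10 on null NB data).  No dispersion trend or
shrinkage across genes is applied, and numeric identity with any published
differential-expression package is not a goal — calibration on data with
known truth is the acceptance standard.

## Exon/intron decomposition

Introns are degraded quickly, so intronic abundance tracks transcription.
Three empirical-Bayes moderated t-tests of phase are run on log2(CPM+1):
exonic abundance (expression), intronic abundance (transcription) and the
per-unit exon − intron log difference (stability; pseudocount 1 guards
zeros).  The difference-matrix formulation was chosen over an interaction
model because it tests exactly the quantity of interest (the change in the
exon/intron ratio) with a per-unit pairing.  Each test is BH-adjusted at
the same level as the expression call (0.1).  Genes whose intron CPM never
clears the expression floor in any replicate set are UNRESOLVED — the
data cannot distinguish the two mechanisms there.  Among resolved phasic
genes: transcription-significant only → TRANSCRIPTION, stability-only →
STABILITY, both → BOTH, neither → UNRESOLVED.

The moderated t follows the standard hierarchical model: gene-wise
residual variances are shrunk toward a prior estimated by moment-matching
the scaled-F distribution of sample variances (prior df from the trigamma
equation, solved by Newton iteration with a bisection fallback; no finite
root → infinite prior df, i.e. fully pooled variance); the moderated t is
referred to residual + prior df.  The implementation matches limma to
machine precision on shared instances.

## Hurdle model

Expression is modeled on log2(CPM+1) of the pseudobulk counts.  Each gene
has a logistic detection component and a Gaussian abundance component on
detected units; a term is tested by the summed likelihood-ratio
chi-square with df equal to the deleted columns per live component.  The
LRT was chosen over Wald because the two components are naturally
combined by adding log-likelihood differences.

Component adequacy rules (degenerate components are dropped and contribute
nothing):

* continuous: needs at least `#coefficients + 2` detected units (one more
  than the coefficients, plus one observation for the variance);
* discrete: needs **more units than coefficients in each detection
  class**.  This covers all-/none-detected genes, and also the
  near-saturation regime (1–3 undetected units with 3 coefficients) where
  the logistic ML quasi-separates through the detection covariate and the
  LRT statistic's null distribution is far from chi-square (measured
  median ≈ 1.2 vs 0.455) — retaining it visibly mis-calibrates the
  combined p-value.

Two further calibration choices:

* The Gaussian LRT `n·log(RSS_r/RSS_f)` is liberal at pseudobulk sample
  sizes (n ≈ 50–100).  Its null mean has the closed form
  `n·(ψ((n−p+q)/2) − ψ((n−p)/2))` from the log-chi-square moments, and the
  statistic is divided by this exact Bartlett factor (per gene, using its
  detected-unit count) before the chi-square lookup.  The raw summed
  2·Δloglik is still reported as `chisq`.
* Logistic separation is kept finite by a ridge penalty of 1e-6 on the
  discrete coefficients; the reported log-likelihood is the unpenalized
  one at the penalized optimum (the difference is O(ridge²) and below the
  1e-6 oracle tolerance).

With no zeros the test reduces exactly to the normal-theory LRT; with the
continuous part dropped it reduces exactly to a logistic LRT; both
reductions, and agreement of the full fit with a generic optimizer of the
exact likelihood, are asserted in the test suite.  Effect sizes
(`log2fc`) come from the continuous component's phase coefficient
(G2M − G1 difference of modeled means); genes with a dropped continuous
component report a valid p but NA effect.

For lineage interactions the design is treatment-coded with a declared
reference lineage; per-lineage contrasts delete one interaction column at
a time (asking which lineage's phasing differs from the reference), which
is the default reported output; deleting the whole interaction block is
available through the same machinery.

## Pseudobulk permutation caller

Within each (phase[, lineage]) group, cells are shuffled and partitioned
into disjoint blocks of exactly 10; block counts are exact sums, and
leftover cells are dropped *per permutation* (re-randomized each round, so
every cell participates in expectation).  Each permutation computes
log2(CPM+1), the detection covariate (detected genes relative to the
best pseudobulk sample), the hurdle LRT of phase, and BH adjustment over
the testable genes of that permutation (untestable genes are excluded
from the family).  Per gene, the median adjusted p and median log2
fold-change are taken across the 100 permutations (NAs excluded when at
most half; otherwise the gene is uncalled).  A call requires median
adjusted p below α (0.05 within-lineage, 0.1 for genotype comparisons)
**and** |median log2fc| > log2(1.1).  The 1.1 gate is read as a
fold-change ratio (≈ 0.138 log2 units), the idiomatic interpretation of
"fold-change of 1.1"; it is configurable.

The scrambled-lineage null draws blocks within phase ignoring lineage and
assigns lineage labels so each (phase, lineage) stratum has exactly as
many samples as the matched construction — identical statistical power,
no lineage signal.  The genotype comparison draws the same number of
cells per phase from each genotype in each of 100 rounds and runs one
pseudobulk pass per genotype per round; the median adjusted p across
rounds is the per-gene evidence (the resampling rounds *are* the
permutations).

## Synthetic data

The single-cell generator plants, for a cell in phase p and lineage l,
gene means `μ_g · λ_gl · 2^(s_p · β_gl)` with `s_G1 = −½`, `s_G2M = +½`
(phase-balanced average expression), NB counts with variance μ + φμ²
(φ = 0.2) scaled to log-normal library sizes (median ≈ 8000 UMI, healthy
cells truncated above 6500 so the planted low-quality cells — shrunken
libraries or ≈ 17% mitochondrial load — are exactly the QC casualties).
Baselines are log-normal (σ = 1.5), leaving roughly 90% of genes past the
20%-detection filter.  Default conditions per experiment: null 2000
genes × 300 cells/phase; recovery 2000 × 500 with 10% of genes at
|log2FC| = 1; interaction 1000 genes, 3 lineages × 120 cells/phase with
40 lineage-B-only effects at |log2FC| = 1.5 and lineage baseline noise
(σ = 0.3); genotype pair 1500 genes × 300 cells/phase with 30 vs 80
planted phasic genes (the mutant's 50 extra).  The bulk generator uses 3
replicates/phase at 2×10⁶ depth, dispersion 0.02, intron abundance at 35%
of exonic, and 50/50/20 TRANSCRIPTION/STABILITY/BOTH drivers at 1 log2
unit.  These sizes keep every end-to-end run on one CPU in minutes while
leaving the statistical questions non-trivial.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, gene-length effects, realistic lineage proportions, correlated
gene programs beyond the planted phase effects, or empirical mean–
dispersion trends.  Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under the stated model, not
robustness to every artifact of real embryo data.

## Co-expression and auxiliary statistics

Cohort correlations use log2(CPM+1) (invariant to per-cell depth),
pairwise Pearson over the canonical panel genes within 50-cell cohorts
drawn without replacement; zero-variance genes are excluded pairwise.
Twenty cohorts per stage is the default summary depth.  The
hypergeometric enrichment p sums the exact upper tail in log space (and
returns exactly 1 when the overlap is at the lower support bound); BH
adjustment is the step-up formula; the KS phase-preference test is the
standard two-sample two-sided test with the stringent 1e-12 cut-off for
calling an activity phase-specific.

## Limitations

* The NB dispersion is per-gene method-of-moments; power at 2–3
  replicates is modest for sub-unit effects (by design, no cross-gene
  information sharing).
* The hurdle model has no random effects and no zero-inflated NB
  alternative; pseudobulk aggregation is the dropout mitigation.
* Lineage labels are inputs; clustering, batch alignment and pseudotime
  are out of scope.
* The fold-change gate interpretation (ratio 1.1 vs 1.1 log2 units) is a
  documented reading of an ambiguous convention and is configurable.
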