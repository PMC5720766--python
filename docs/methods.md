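# Methods

This note records the model, the processing conventions, the numerical
choices, and what the synthetic worlds do and do not emulate.

## Enrichment matrices

For each gene the annotation is reduced to the outermost TSS and TTS over
all of its transcripts (minimal genomic start for + strand, maximal genomic
end for −, and symmetrically for the TTS).  Three region types are derived:
`[tss − 2000, tss + 2000)`, the gene body, and `[tts − 2000, tts + 2000)`,
in 0-based half-open coordinates (GTF input is converted once at parse
time).  40-bin resolution (100-bp bins) is only defined for TSS flanks and
is used only for expression modelling; bins are ordered in genomic
coordinates regardless of strand.  Regions clamped at a chromosome edge
keep their nominal bin grid, with out-of-range bins empty, so truncation
never changes bin widths or gene counts silently.

Tag counting treats a track as signal mass: a run of value *v* contributes
`v × |run ∩ bin| / bin_width` to a bin.  Raw tag-count tracks and
pre-computed coverage tracks are thereby handled identically.  DNA
methylation is additionally divided per bin by the CpG count (the
dinucleotide CG on the forward strand, assigned to the bin containing its
C); bins without CpGs map to 0, which keeps the output bounded.  Both the
absolute and the CpG-normalised variant are carried as separate matrix
columns.

Regions overlapping a blacklist interval by ≥ 1 bp, and genes on
chrX/chrY, are removed per region set before assembly.  Each mark's pooled
bin values are then quantile-scaled: values at or below the q-quantile map
to 0, at or above the (1 − q)-quantile to 1, linear in between, with
q = 0.01 by default and q = 0.05 supported.  Quantiles use numpy's
linear-interpolation estimator and are computed per constellation (per
assembled matrix), not genome-wide.  A constant mark scales to all zeros
with a warning rather than propagating NaNs.

## Model engine

**OLS.**  Least squares with intercept via `numpy.linalg.lstsq`.
Rank-deficient designs (possible at 40-bin resolution with many marks)
return the minimum-norm pseudoinverse solution with a warning; an optional
ridge stabiliser is available but off by default.

**Pearson r / p.**  The p-value is the two-sided Student-t transform
`t = r·sqrt((n−2)/(1−r²))` with n − 2 degrees of freedom; constant inputs
raise a dedicated `ConstantInputError` so degenerate tracks are reported,
not silently scored.

**BIC.**  Gaussian-likelihood convention
`n·ln(RSS/n) + (p + 2)·ln(n)` — p slopes, the intercept, and the noise
variance all count as parameters.

**MARS.**  Additive only (degree 1): the fit is
`c0 + Σ coef_t · B_t(x_col(t))` with hinge bases `max(0, x − c)` and
`max(0, c − x)`.  The forward pass adds reflected hinge pairs greedily by
exact RSS reduction, computed against an incrementally maintained
orthonormal basis; ties break to the lowest (column index, knot value).
Knot candidates are observed predictor values — all unique values when a
column has ≤ 256 of them, otherwise 256 quantile-spaced unique values (a
tractability cap; small-sample and noiseless behaviour is unaffected).
Defaults: `max_terms = min(200, max(20, 2·n_columns))`, forward stop when
the relative RSS gain falls below 1e-4.  The backward pass removes terms
one at a time by exact RSS (via the Gram matrix) and keeps the subset
minimising `GCV = (RSS/n)/(1 − C(m)/n)²` with
`C(m) = m + penalty·(m−1)/2`, penalty 2 (the standard additive-model
choice), m counting the intercept; surviving coefficients are refit by
OLS.

**Cross-validation.**  k = 10 folds; gene indices are shuffled with a
stated seed and cut into k near-equal contiguous blocks.  Folds are drawn
once per matrix and shared across targets (and across candidates within a
selection round) for comparability and determinism; the seed is recorded in
every result.

## Imputation, transfer, selection semantics

Predicting DNA methylation targets the CpG-normalised column and excludes
the absolute column from the predictors; predicting anything else keeps the
absolute column and drops the normalised one.  The best-correlated-mark
baseline uses the maximum *signed* r — anti-correlated predictors are the
model's job, not the baseline's.  Per-mark failures (constant columns) are
excluded from medians and logged.

Transfer fits a mark's model on 100 % of the source cell line's genes
(restricted to marks common to both cell lines, methylation flavors matched
pairwise, gene rows intersected) and scores it on the target cell line.
Per-mark drops pool all available values: the median intra-CV r over
(cell lines × locus constellations) minus the median transfer r over
(ordered pairs × locus constellations); drops ≥ 0.3 are flagged, and a
two-sample Kolmogorov–Smirnov test compares drop distributions between
user-supplied mark groups.  For clustering, the asymmetric median-r matrix
(rows = target cell line) is symmetrised as `d = 1 − (r_ij + r_ji)/2` and
average-linkage clustered; the tree is a convenience on top of the
asymmetric heatmap.

Greedy selection follows the round structure literally: with selected set
S, each unselected candidate j is scored by the median CV r of models
predicting every mark in K \ (S ∪ {j}) from S ∪ {j}; the candidate's own
predictability is not part of its score, argmax ties break to the lowest
mark index, and the final round (no targets left) has an undefined score by
construction.  Round 1 therefore *is* the single-mark information ranking.
The literal algorithm is O(n³) model fits; fold sharing keeps it exact and
deterministic.

## Expression

`GEx` sums the densities of the two central 100-bp bins (1-based bins 20
and 21, i.e. the ±100 bp window around the TSS) of the 40-bin flank from
both strand tracks; minus-strand CAGE coverage is read as absolute values
since it is sometimes emitted signed.  The response is
`gex = quantile_scale(ln(GEx + ε))` — natural log, log-then-clip order,
q = 0.01; the log base is absorbed by the affine rescale.  ε is scanned
over {0.001, 0.01, 0.1, 1} and chosen to maximise CV r in the (source)
cell line, ties to the smaller ε; cross-cell-line expression transfer uses
the source-optimal ε on both sides.  Mark inputs use only the absolute
methylation flavor.  Feature variants: all 40 bins per mark, the middle
two bins, or the 1-bin value.

## Synthetic worlds

Each cell line assigns every gene a latent state `z ~ N(0, I)` split into a
shared-program block (dimension L_s) and a cell-specific-program block.
A mark observes `m = wᵀz + σ·ε` through a sparse unit-norm loading vector
w: shared-rule ("activating-like") marks reuse w across cell lines on the
shared block; cell-specific-rule ("silencing-like") marks load on the
specific block with w resampled per cell line.  Resampling is constrained
to pairwise cosine < 0.5 across cell lines: in a low-dimensional latent
space unconstrained draws occasionally align by chance, which would make
the planted shared/specific dichotomy unidentifiable in any given run.

**Noise calibration.**  The headline statistic is a *cross-mark CV r*, so
noise is set for the achievable prediction, not the oracle one.  With M
marks on an L-dimensional block and unit-norm loadings, the best linear
predictor of mark i from the other M − 1 noisy marks reconstructs z with
per-direction error ≈ σ²·L/(M−1), giving
`r² ≈ (1 − σ²L/(M−1)) / (1 + σ²)`.  Solving for the target r:

    σ² = (1 − r²) / (r² + L/(M−1)).

This closed form is validated against Monte-Carlo estimates in the tests
(agreement within 0.02–0.03).

**Tracks.**  Bin values over the ±2 kb TSS flank are
`baseline + amplitude·m·profile_b + jitter`, rounded to 6 decimals and
written as 100-bp bedGraph runs, so file-based counting inverts the
generator exactly and byte-identical reproduction under a seed is testable.
Two profiles exist: `flat` (signal in every bin — used for imputation,
transfer and selection worlds) and `promoter` (signal concentrated in the
central bins with a gene-level background confound in the flanking bins —
used for expression worlds, where it makes the 1-bin average a genuinely
diluted readout).  Expression responds to the *observed* mark levels:
`ln GEx ∝ Σ β_i·f(m_i) + noise` with f identity or a hinge at 0, noise set
by the same r-targeting rule; a detection floor zeroes the bottom 5 % of
genes, which is what makes the pseudocount scan non-trivial.  CAGE mass is
split between strands per gene and placed in the two central bins.
Methylation, when enabled, writes per-bin mass `fraction × CpG count` over
an even CpG grid at gene-specific density, so the CpG-normalised value
recovers the planted methylated fraction; a FASTA with planted CpGs (and a
C-free background alphabet) can be emitted for sequence-based counting.
A blacklist overlapping a known 2 % of autosomal genes and a 2 % chrX gene
subset exercise the filters with assertable counts.

**What the worlds do not emulate:** read-level sampling noise, peak shape,
mappability structure, inter-gene signal spill-over, realistic genome
sequence, isoform diversity, or non-linear mark–mark couplings beyond the
expression hinge.  Passing tests therefore demonstrate that the pipeline's
statistics recover planted linear/hinge structure at calibrated noise —
not that real epigenomes satisfy those structural assumptions.

## Study sizes

The test and acceptance studies use: imputation at 2000 genes × 20 marks
(5 seeds), transfer at 1000 genes × 15 marks × 3 cell lines (5 seeds),
hub selection at 600 genes × 8 marks (20 seeds), expression at 1200 genes ×
8 marks (linear link) and 700 genes (hinge link), with greedy-vs-exhaustive
checks on ≤ 6-mark worlds at 300 genes.  These sizes give sampling error
comfortably inside the asserted tolerances (±0.03 on r at n = 2000) while
keeping the whole suite in tens of seconds.

## Known limitations

* The MARS forward pass scores reflected hinge pairs jointly; models whose
  best next step is a *single* unpaired hinge can differ slightly from
  implementations that score the pair members separately (the backward
  pass prunes unhelpful twins, which restores agreement in practice).
* Quantile scaling is per constellation; matrices built from subsets of
  genes are not scale-identical to subsets of a scaled matrix.
* `transfer_expression` expects features already restricted to common
  marks; it does not re-derive the intersection itself.
* The similarity matrix diagonal mixes CV (out-of-fold) with off-diagonal
  100 %-fit transfer values, mirroring the analysis it reproduces; the two
  are not numerically commensurable estimators of the same quantity.
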