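# Methods

This note documents the statistical procedures implemented in `seromir`, the
choices made where the underlying methodology is underdetermined, and what
the synthetic-data generator does and does not emulate.

## Normalization of TaqMan-array Ct matrices

Serum circulating miRNAs have no consensus reference gene, so the pipeline
selects endogenous controls from the data, per comparison:

1. **Reference profile.** For the samples of a two-group comparison, the
   per-sample median and mean Ct are computed over all miRNAs — but a miRNA
   is excluded from both statistics in *every* sample as soon as one of its
   wells among those samples is flagged (failed/undetermined amplification).
   These profiles track the loaded cDNA mass per array, in the spirit of
   global-median normalization.
2. **Control ranking.** Each fully detected miRNA's Ct vector is Pearson-
   correlated with the reference profiles. The procedure computes r against
   both the median and the mean profile; because neither is canonically
   preferred, the default ranking key is their average (either one can be
   selected instead, and both are reported). Ties in r break toward lower
   mean Ct, then lexicographic id, so output is deterministic. Zero-variance
   rows have undefined r and are dropped from ranking with a logged note.
3. **Selection.** Stability and abundance are both desirable in a control.
   This is implemented as a two-stage rule: take the top *m* (default 10)
   miRNAs by r, then select the *k* (default 3) most abundant (lowest mean
   Ct) among them. A single-stage "top k by r" is the special case m = k.
4. **ΔCt.** ΔCt(miRNA, sample) = Ct − mean Ct of the selected controls in
   that sample (the arithmetic mean of the controls is an assumption; no
   other combination rule is documented for this design). Cells with flagged
   targets are missing; a flagged control well leaves the sample's reference
   undefined and is an error unless the drop-sample fallback is enabled.
   Fold change between groups is 2^−ΔΔCt with ΔΔCt the difference of group
   mean ΔCt.

Flag semantics are absolute: no downstream computation ever consumes a
flagged Ct as a number (the test suite asserts this by poisoning flagged
cells).

## SAM-style permutation differential expression

The discovery arm uses a two-class unpaired moderated statistic

    d_i = (mean₂ − mean₁) / (s_i + s₀)

with s_i the pooled standard error of the difference. The fudge factor s₀
damps d for low-variance features; it is chosen from the percentile grid of
the s values (0th–100th in steps of 5) to minimize the coefficient of
variation of the median absolute deviation of d across s-quantile windows.
With fewer than 20 features the window statistics are unstable and the
median of s is used; s₀ can always be overridden.

Significance is calibrated by label permutation (at least 100 permutations;
all C(n, n₁) distinct assignments are enumerated when fewer exist). The FDR
at threshold t is the *average* number of permuted |d*| values exceeding t
divided by the observed count exceeding t, and the q-value of feature i is
the minimum FDR over all observed thresholds ≤ |d_i|, clipped to [0, 1].
The average (rather than a median or upper percentile) of the permutation
counts is the classical choice for this estimator and behaves smoothly at
the extreme thresholds where counts are 0/1-valued. π₀ is not estimated
(conservatively set to 1). Features with no observation in either group are
dropped with a note. The default call cutoff is q ≤ 0.15.

## Validation-arm testing

Per-group normality is checked with both the D'Agostino–Pearson K² omnibus
test (requires n ≥ 8; omitted with a note below that) and Shapiro–Wilk
(n ≥ 3). The combined verdict is conservative: non-normal as soon as either
test rejects in any involved group, or any group is degenerate (constant
vectors leave Shapiro–Wilk undefined and are non-normal by convention).

Differential expression across the four groups uses ordinary one-way ANOVA
(α = 0.05) followed by Tukey's multiple comparisons; adjusted p-values come
from the studentized-range distribution, not simulation, so results are
deterministic. Pairwise fold changes reuse the 2^−ΔΔCt computation.

## Outlier screening

Within a candidate group, each screened variable (marker ΔCt and the four
ADOS item scores) defines the interval mean ± 2·SD on the pre-exclusion data
— a single pass, no re-screening after removal. The SD is the sample SD
(n − 1 denominator). "Out of range" is strict inequality; a zero-SD variable
screens nobody; missing values are never out of range. Because "value and/or
score" is ambiguous as a combination rule, both are implemented: the default
`"and"` excludes a sample only when it is out of range on the expression
variable *and* on at least one item; `"or"` excludes on either. An audit log
records the triggering variables per exclusion. Under Gaussian data the
per-variable flag rate is ≈ 4.55% (two-sided 2σ), which the acceptance suite
checks by simulation.

## Clinical-score correlation family

The planned family comprises 16 tests across four scopes: all patients and
controls (ΔCt vs IQ, YGTSS, ADOS A–D), ASD + NC (ADOS A–D), TS + NC (YGTSS),
and TS+ASD + NC (YGTSS, ADOS A–D). Per test, the method is Pearson when both
variables pass the normality checks within the scope and Spearman otherwise;
zero-variance variables or fewer than 3 complete pairs yield a not-testable
(NT) record. Three corrections are applied across the *fixed* family size
m = 16 — NT records still consume a slot, so the Bonferroni threshold stays
α/16 ≈ 0.003 regardless of how many tests were computable: a Bonferroni
verdict, Holm step-down adjusted p, and BH step-up adjusted p (one shared
implementation with the enrichment module). Confidence intervals use the
Fisher transform; for Spearman this is the usual large-sample approximation.
Follow-up OLS regression of score on ΔCt is gated on passing all three
corrections (Bonferroni, Holm ≤ 0.05, BH ≤ 0.01).

## Biomarker evaluation

ROC curves are computed over all distinct ΔCt thresholds with the decision
direction "positive class at ΔCt ≤ cutoff" (ASD is upregulated, hence at
lower ΔCt). The trapezoid AUC equals the Mann–Whitney concordant-pair
fraction to numerical precision (tested). The operating point maximizes the
Youden index J = sensitivity + specificity − 1; ties break toward higher
specificity, then lower cutoff. The AUC 95% CI is a stratified bootstrap
percentile interval (default 1000 resamples) — a bootstrap rather than an
analytic CI because the CI construction is not otherwise pinned down.

The predictive model is a one-predictor maximum-likelihood logistic
regression; under complete separation a ridge-regularized fit takes over
with a logged note (or an error, configurably). Cross-validation is repeated
random sub-sampling: each of 100 repeats draws a *stratified* 2/3 train :
1/3 test split — stratification is required for test folds of ~18 samples to
reliably contain both classes — fits on train, and scores test. Reported are
the average test AUC, an average ROC curve obtained by vertical averaging of
TPR on a fixed 101-point FPR grid (the "average ROC curve" is otherwise
underdetermined), and per-sample predicted probabilities averaged over
exactly the repeats in which the sample was in the test fold. Sensitivity
and specificity are read from those per-sample averages at the probability
0.5 rule, which also defines the misclassified-sample list.

Permutation testing re-assigns class labels at random and re-evaluates the
model identically with a short 3-repeat CV, 100 times; the observed
statistic is the same 3-repeat CV average AUC on the true labels, and the
p-value uses the add-one rule (b + 1)/(m + 1) so p is never 0.

## Network enrichment

The regulatory network is consumed as an undirected, deduplicated edge list
(self-loops dropped). Analysis is the induced subgraph on the seed genes and
their first neighbors, reporting within-subgraph degrees (hubs). ORA tests
each annotation term by the upper-tail hypergeometric probability of the
query/term overlap against an annotated background universe; the universe
defaults to all genes in the annotation file (ratios in published ORA tables
are consistent with an annotated universe rather than the whole genome) and
is overridable. Terms with zero overlap are not emitted, and the BH family
is the emitted set; significance defaults to BH ≤ 0.05. GeneRatio = k/n and
BgRatio = K/N accompany every record. The log2FC filter uses strict
inequalities (up: > 1, down: < −1; boundary values excluded).

## Synthetic-data generator

The generator encodes the study conditions the pipeline targets, and its
defaults are fixed rather than tuned per analysis:

* **Profiling arm**: two 377-miRNA panels over 4 ASD / 5 TS / 4 TS+ASD /
  3 NC samples. Ct = per-miRNA baseline + per-sample loading offset
  (N(0, 0.5) cycles, shared across the array) + group shift on marker rows
  (default −3 cycles in ASD) + Gaussian noise. Baseline means are uniform on
  [22, 35] and noise SDs uniform on [0.5, 1.5] cycles — serum Ct
  distributions are not otherwise documented, so these ranges are stated
  here as the package's assumption. Designated stable controls are abundant
  (baseline [19, 23]) with near-zero biological SD (0.02). Wells are flagged
  missing-at-random at probability 0.05 by default; an optional high-Ct
  mode concentrates dropout at low abundance, as real undetermined wells do.
* **Validation arm**: 30/24/25/25 cohort; the marker's ΔCt is Normal(μ_g, 1)
  with μ = 2.0 (ASD), 2.783 (NC), 2.867 (TS), 3.092 (TS+ASD). These means
  were derived once by inverting the target pairwise AUCs (≈ 0.71 ASD vs NC,
  0.73 vs TS, 0.78 vs TS+ASD) through the binormal identity AUC = Φ(δ/√2);
  the same separations reproduce Tukey p-values of roughly 0.03 / 0.01 /
  < 0.001 at these group sizes — an internal consistency of the emulated
  design, not a separate calibration.
* **Clinical scores**: YGTSS = 4.537·ΔCt − 3.269 + N(0, σ), with σ = 14 by
  default so that the marginal ΔCt–YGTSS correlation is ≈ 0.33 at n = 104;
  experiments that need a different σ (e.g. slope-recovery checks at σ = 5)
  set it explicitly. IQ and ADOS items are group-conditional Gaussians with
  structural zeros (controls score 0 on all ADOS items; TS on items A–C).
  Scores are rounded to integers *after* generation so the latent linear
  model stays exact; YGTSS is deliberately not clipped at 0, which keeps the
  latent model recoverable but lets a minority of simulated scores go
  negative — a known unrealism.
* Identical seed + config give bit-identical outputs.

What the generator does **not** emulate: real miRNA identities or sequence
content, inter-miRNA correlation beyond the shared loading offset,
panel-specific chemistry effects, or abundance-dependent variance. Passing
tests therefore demonstrate the *procedures* behave correctly under the
assumed stochastic model, not that the biological conclusions transfer to
any particular real cohort.

## Problem sizes and numerical choices

The test and acceptance suites size their simulations for a single CPU:
calibration experiments use 200 replicate experiments (permutation type-I
error with 60 permutations per test, ANOVA null uniformity, 2σ exclusion
rate), parameter-recovery experiments use 20–200 replicates, and the
acceptance script averages 10–30 replicate cohorts (medians for p-values,
which are right-skewed across replicates). Degenerate inputs fail loudly:
empty classes, constant predictors, all-flagged matrices, zero permutations,
and family sizes smaller than the number of tests all raise errors rather
than returning silently wrong numbers.

## Known limitations

* The SAM q-value definition above is one concrete member of the family of
  permutation-FDR estimators; other implementations differ in s₀ search
  grids, π₀ estimation, and asymmetric (up/down) thresholding, and will not
  match numerically.
* Spearman CIs use the Fisher approximation, which is mildly anticonservative
  for n < 25.
* The discovery arm at 4-vs-3 samples has limited power by design; the
  acceptance report includes the observed detection fraction rather than
  hiding it.
* Repeated sub-sampling CV with per-sample averaged probabilities yields
  sensitivity/specificity estimates whose class asymmetry depends on class
  imbalance through the logistic intercept; they are reported as computed.
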