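# Methods

## The model

`sparsecmtf` analyses a cohort in which every subject contributes three
coupled views: a three-way block **X** of repeated paraclinical
biomarkers (subjects × biomarkers × visit months, with missing entries),
a baseline block **Y** of onset characteristics (subjects × variables),
and a genotype block **Z** of additive risk-allele counts
(subjects × SNPs, 0/1/2, with a mask for failed genotyping). The three
blocks are factorized jointly with a shared subject mode:

```
X ≈ Σ_r  a_r ∘ b_r ∘ c_r        (CP / PARAFAC structure)
Y ≈ A Dᵀ
Z ≈ A Eᵀ
```

where `A = [a_1 … a_R]` are subject scores shared across blocks and
`b_r, c_r, d_r, e_r` are biomarker, time, baseline and gene loadings.
Each component is one association pattern: *which* biomarkers move
(`b_r`), *how* they evolve over the visit grid (`c_r`), and which
baseline characteristics and genotypes go along with that trajectory
(`d_r`, `e_r`). The default rank is 2.

The fitted objective is

```
F = w₁‖W_X ∘ (X − [[A,B,C]])‖² + w₂‖Y − ADᵀ‖² + w₃‖W_Z ∘ (Z − AEᵀ)‖²
    + λ(‖B‖₁ + ‖D‖₁ + ‖E‖₁) + ρ(‖A‖² + ‖C‖²)
```

* **Masked least squares.** `W_X`, `W_Z` restrict the loss to observed
  entries; no imputation is performed. This gives a single well-defined
  objective whose monotone descent the test-suite asserts on every fit.
* **Block weights.** `w_b = 1 / (observed sum of squares of block b)`,
  so each standardized block contributes exactly 1 to the loss of the
  zero model and no block dominates by size.
* **Sparsity.** The L1 penalty on the variable modes (biomarkers,
  baseline, genes — never the time mode, whose four-point profiles stay
  dense) produces exact zeros, so each component names a subset of
  variables. Coordinate updates are exact soft-thresholding steps.
* **Scale anchor.** `ρ = 0.01·λ`. Without it, the scale indeterminacy of
  the factorization lets the subject mode absorb the penalty (A grows,
  B/D/E shrink, the effective penalty decays towards zero over sweeps);
  a small ridge on the unpenalized modes pins a finite equilibrium while
  leaving the fit essentially unbiased.

### Optimization

Block-coordinate descent: per-subject ridge least squares for A,
per-row least squares for C, cyclic coordinate descent with exact
soft-threshold updates for B, D, E. Every update is an exact minimizer
(or exact 1-D minimizer), so the penalized loss is non-increasing —
violations would indicate an implementation error, and the tests treat
them as such. Defaults: 10 starts (one spectral-initialized from the
singular vectors of the zero-filled unfoldings, nine random),
convergence when the relative loss drop falls below 1e-8, at most 500
sweeps; the best start by final penalized loss is returned.

### Identifiability conventions

CP solutions are unique only up to permutation, scale and paired sign
flips. `align_components` normalizes B and C columns to unit norm
(absorbing tensor scale into A), normalizes D and E while recording
their per-component strengths as explicit gains (a shared A cannot
absorb every block's scale simultaneously, so the gains keep the
matrix-block reconstructions exact), pins signs so the
largest-magnitude biomarker and time loadings are positive (flips
propagate to A, D, E so reconstruction never changes), and orders
components by tensor-block explained variation. Two aligned fits of the
same data are therefore directly comparable column by column.

### Choosing the penalty

λ is selected from a log-spaced grid (1e-4 … 1e-1, 7 points) by
split-half stability: for each candidate, subjects are halved, models
are fitted independently on the halves, components matched, and the
mean absolute congruence over the sparse modes recorded; the largest λ
within 0.05 of the best median stability is chosen, favouring the
sparsest among equally stable models. A single λ is shared by the three
sparse modes — the block weights already equalize block scales, so a
per-mode grid would triple the search for little benefit. On
cohort-scale synthetic data the procedure selects λ = 0.01 almost
always; that value is also the pipeline's reference penalty in the
acceptance checks.

## Preprocessing

Designated skewed biomarkers are log-transformed. Every
biomarker-by-time column, baseline column and SNP column is centered
and scaled to unit *sample* variance (ddof = 1) over its observed
entries; genotype counts are standardized per SNP so loadings are
comparable across allele frequencies. Constant columns are dropped
(matrix blocks) or masked out (tensor columns) with a warning.
Column-wise scaling is not exactly multilinearity-preserving (the
per-column sd need not factor over biomarker × time); with realistic
noise this deformation is second-order, but on exactly noiseless data
the sds are purely signal-driven and the deformation is large — the
noiseless recovery tests therefore fit the raw, weighted blocks.

## Validation

**Pattern-to-pattern permutation test.** For one component, the
statistic is the absolute Pearson correlation between two blocks'
subject scores (per-block least-squares projections of that block's
observed data onto its loading structure). The null permutes the
subject rows of the tested block; p = (1 + #{null ≥ obs}) / (1 + N),
default N = 9999. Because loadings fitted jointly to both blocks adapt
to the observed pairing, holding them fixed inflates the observed
statistic relative to the permutation null (measured null rejection at
α = 0.05: ≈ 0.44 fixed-loadings, ≈ 0.16 with per-draw loading refits
against the joint model's scores). The default method therefore refits
the model with the tested block's weight set to zero — the anchor
scores then depend only on the untested blocks — and refits the tested
block's loadings per permutation draw by closed-form regression.
Measured null rejection: 0.05 at α = 0.05; power on shared-factor
cohorts reaches the minimum attainable p. The anchor model's components
are matched to the reference model on the modes the tested block does
not touch.

**Split-half consistency.** Subjects are randomly halved; each half is
re-standardized, re-weighted and fitted independently; components are
matched by Tucker congruence (cosine) averaged over modes, using
absolute values per mode because per-mode signs are a CP gauge. The
consistency p-value compares the matched congruence against a null of
congruences from refits on column-permuted data (each variable column
independently permuted across subjects, destroying within- and
cross-block linkage). Under pure noise the observed congruence is
exchangeable with the null draws, so the p-values are uniform by
construction. Defaults: 20 splits, 19 null refits per split; summaries
are the median congruence and worst-case p per mode and component.

**Gene-selection homogeneity.** The sparse gene supports selected in
the two halves are cross-tabulated over the SNP universe and tested
with Fisher's exact test (one-sided, more overlap than chance);
degenerate tables give p = 1.

**Component matching.** Optimal one-to-one assignment
(`linear_sum_assignment`) on the across-mode mean of absolute
congruences. Matching on a signed concatenation would spuriously
penalize legal gauge flips, which is why each mode enters through its
absolute value.

## The synthetic cohort generator

Defaults emulate the target study's shape: 129 subjects, 20 biomarkers
at visit months {1, 3, 6, 12}, 10 baseline variables, 51 SNPs, rank 2.
Subject scores are i.i.d. standard normal; sparse-mode loadings are
Gaussian with an exact fraction of zeros per component (defaults 0.5 /
0.3 / 0.7 for biomarker / baseline / gene) and unit-norm columns; time
loadings are random orthonormal columns (with only four timepoints,
plain random profiles are occasionally near-collinear, which destroys
CP identifiability for reasons irrelevant to anything under test).
Gaussian residual noise has sd 0.3 per block by default; with this
convention the tensor block is ≈ 78% noise per entry, so a rank-2 model
explains ≈ 13–15% of the tensor variation — the same order as reported
multi-block analyses of real remission-phase cohorts. Tensor entries
are deleted completely at random (default 10%) with rejection
resampling so every subject keeps at least one observation. The
genotype block is discretized by cutting each latent Gaussian column at
the tertiles of its exact marginal distribution, which preserves a
monotone association with the latent score while producing legal
0/1/2 counts; tertile coding attenuates the latent correlation by a
factor ≈ 0.89, uniform across SNPs.

What the generator does **not** emulate: realistic pharmacokinetic
trajectories, informative missingness, linkage disequilibrium between
SNPs, binary/ordinal baseline variables, or batch structure. Passing
recovery tests therefore demonstrate correctness of the estimator under
the generating model, not robustness to those real-data features.

### Measuring recovery

Fitted loadings live in the standardized analysis space, so ground
truth is mapped there before comparison: matrix-block loading rows are
divided by the empirical raw column sds, and truth subject scores are
column-centered (the model sees centered data). Recovery of a mode is
summarized as the mean absolute matched congruence across components;
at cohort scale with noise sd 0.3 this exceeds 0.95 for every mode in
≈ 19/20 replicates. The minimum over individual component-mode pairs
occasionally dips to ≈ 0.94 — driven by true loadings drawn near zero,
whose omission by the lasso is statistically correct but costs
congruence — which is an information floor of these conditions, not an
estimator defect (restricting congruence to the true support reproduces
the same values). A relaxed-lasso debiasing step (restricted OLS on the
selected support) was evaluated and discarded: it inflates variance and
degrades gene-mode recovery.

## Clinical derivations

IDAA1c = HbA1c(%) + 4 × daily insulin dose (U/kg/24 h); partial
remission iff IDAA1c ≤ 9 (boundary inclusive). DKA from standard
bicarbonate: severe if ≤ 5 mmol/L, present if ≤ 15 mmol/L, both
inclusive; severe implies the DKA flag in block encodings. HLA-DQB1
risk uses the four-level template rules (very high = 0302/02; high =
0302/0302, 0302/X, 02/02, 02/X; moderate = 0302/0301, 0302/0603,
02/0301, 02/0603, X/X; low = 0302/0602, 02/0602, 0301/X, 0603/X), with
X standing for alleles not named in the templates, evaluated in
priority order very high → high → moderate → low; pairs matching no
template carry only protective or neutral alleles and are assigned low;
a three-level collapse (very high / high / moderate-low) is used for
modelling. Autoantibody positivity cutoffs: ICA 2.5 JDFU, IAA 2.80 RU,
GADA 5.36 RU, IA-2A 0.43 RU, ZnT8 Arg/Trp/Gln/Triple 60/58/65/58 U/ml;
all treated as inclusive (≥) — the ZnT8 thresholds are defined with ≥
and the conventional antibodies are assumed to follow the same
convention. Genotypes are additively coded as risk-allele counts; age
groups are the half-open bins [0, 5), [5, 10), [10, ∞).

## Problem sizes used in the automated checks

Oracle equivalence uses 20 random 15×8×4 rank-2 tensors against a
direct L-BFGS minimizer of the CP loss. Factor recovery uses 20
cohort-scale replicates (129×20×4; 10; 51). Calibration of the
permutation test uses 200 independent-block datasets of 60 subjects
with 499 permutations each. Split-half checks use one cohort-scale
strong-signal dataset (20 splits) and 200 consistency p-values from
pure-noise cohorts of 32 subjects. These sizes give binomial/KS
tolerances tight enough to detect miscalibration while keeping the
whole suite runnable on a laptop in a few minutes.

## Known limitations

* The objective is non-convex; multi-start ALS finds good optima
  reliably at these sizes but offers no global guarantee.
* λ selection by split-half stability is itself a randomized procedure;
  with very small cohorts its choice can vary between runs.
* The permutation test's exactness argument requires the tested block
  to be exchangeable across subjects under the null; covariate-driven
  structure (e.g. age-stratified genotype frequencies) would need
  restricted permutations, which are not implemented.
* Baseline blocks are modelled as complete; missing baseline values
  must be handled upstream.
* Genotype discretization in the generator attenuates but never
  reverses associations; estimators are compared against the
  attenuated (standardized-space) truth, which is the estimable target.
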