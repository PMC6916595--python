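# Methods

## Scope

`treeletomics` implements a pattern-based analysis of targeted plasma
metabolomics in a 1:1 matched (incidence-density sampled) case-control
design: a treelet decomposition of the metabolite covariance fitted on
controls, data-driven cut-level selection, participant-level component
scores, and conditional-logistic effect estimation with subtype,
heterogeneity, follow-up-stratified, mutually adjusted and
disease-death contrasts.  Because individual-level cohort data of this
kind are application-only, the package ships a synthetic-cohort
generator with known ground truth; every statistical claim the test
suite makes is a claim about recovery of that ground truth, not about
any real cohort.

## Treelet transform

Given a covariance matrix `C` of natural-log concentrations, the
transform repeatedly (p − 1 times) selects the pair of *active*
variables with the largest absolute correlation implied by the current
rotated covariance, zeroes their cross-covariance with a 2×2 Jacobi
(Givens) rotation

    theta = 1/2 · atan2(2 C_ab, C_aa − C_bb),   |theta| <= pi/4,

and retires the lower-variance rotated coordinate (the *difference*
variable); the higher-variance *sum* variable remains available for
later merges.  Cutting the resulting tree at level `c` and keeping the
`K` highest-variance active sum variables yields unit-norm components
whose support is exactly the leaf set of their subtree — the zeros are
structural (columns never touched by a rotation), not thresholded.

Numerical conventions, all chosen for determinism and verified by test:

* pair selection by |correlation|, rotation on the covariance (so
  high-variance metabolites keep their weight in the merged pattern);
  both the selection and rotation operate on the same evolving matrix;
* ties in |correlation| break to the lexicographically smallest index
  pair; equal post-rotation variances make the lower index the sum;
* component sign fixed so the largest-|loading| entry is positive;
* orthonormality and trace conservation hold to 1e−10 at every level,
  and for p = 2 the transform reproduces PCA exactly.

Scores are uncentred weighted sums `s = X w`.  Per-1-SD effect scaling
is shift-invariant, so centring would not change any reported odds
ratio; uncentred scores keep the score file directly comparable across
populations.

## Cut-level selection

For fixed `K`, candidate cut-levels are scored by 5-fold
cross-validation: fit the tree on the training folds, take the `K`
components at the candidate cut, and compute the fraction of held-out
variance captured by the held-out scores.  The optimum is the *lowest*
cut attaining the maximal mean score, trading variance explained
against sparsity.  Fold assignment is a seeded permutation; reruns are
bit-identical.  The fold count is a package default (the underlying CV
objective is not uniquely fixed by prior art); held-out variance
explained was chosen because it is the quantity the components are
meant to maximise out of sample.

Bootstrap stability refits the tree on participant resamples and
matches components to the original by absolute Tucker congruence
|w·w′|; per-component medians and IQRs are reported, degenerate
resamples (a constant variable) are skipped and counted.

## Conditional logistic regression

For one case and one control per set the conditional likelihood is
`prod_i sigma(d_i' beta)` with `d_i` the case-minus-control covariate
difference — an intercept-free logistic regression on differences with
all outcomes 1.  The solver is damped Newton-Raphson with a gradient
infinity-norm tolerance of 1e−10 and at most 100 iterations; the
observed information at the optimum gives Wald SEs, and 95% CIs use
z = 1.96.  Agreement with an independent difference-regression oracle
(statsmodels GLM) is verified to 1e−8 on random cohorts, and with the
discordant-pair closed form for binary exposures.

Degenerate designs are handled explicitly: design columns with no
within-pair variation anywhere are dropped with a warning (they are not
identified — e.g. an 'unknown' covariate level present in only one pair
member across a small stratum); diverging coefficients raise a
separation error rather than returning a spurious estimate; sets with
zero difference rows contribute no information and a fully
uninformative exposure is refused.

Risk contrasts built on this solver:

* **per-SD**: exposure divided by its SD in a reference population —
  controls by default, matching the population the treelet basis is
  fitted on (configurable to all participants);
* **quintiles**: indicator coding against Q1, cutpoints at the
  20/40/60/80th percentiles (linear interpolation) of the reference
  population;
* **subtypes**: refit on the sets whose case carries the label;
* **heterogeneity LRT**: unconstrained = sum of subtype fits,
  constrained = shared exposure coefficient with subtype-specific
  covariate coefficients (covariates interacted with subtype),
  chi² = 2(l_u − l_c) on S − 1 df.  Sharing covariate coefficients
  across subtypes would also be defensible; subtype-specific covariates
  make the test exactly the comparison of the subtype fits;
* **follow-up strata**: split at 10 years of time to diagnosis;
* **mutual adjustment**: other components with |Pearson r| > 0.2 in the
  reference population enter as continuous covariates;
* **death analysis**: restricted to sets whose case died of the disease
  and whose control was under observation at that death; excluded sets
  are counted and reported.

Matching factors are never entered as covariates — they are conditioned
out by the design.

## Synthetic cohorts

The generator emulates a 119-metabolite targeted panel (8
acylcarnitines, 21 amino acids, 5 biogenic amines, 8 lysoPC, 31 diacyl
PC, 33 acyl-alkyl PC, hexose, 5 SM(OH), 7 SM) with three latent
blocks: all PC aa/ae plus three SM(OH) (block1), acylcarnitines
C18:1/C18:2 with glutamate, ornithine and taurine (block2), and all
lysoPC (block3).  Latent block scores are standard normal with
corr(block1, block3) = 0.46.  Log concentrations are class mean +
0.3 × block score + N(0, 0.2²) noise for block members (within-block
correlation ≈ 0.69), and class-level log-normal noise (SD 0.35) with a
small random cross-loading (SD 0.03) for background metabolites, so the
covariance is block-structured but not exactly block-diagonal.  Class
means use typical plasma scales (amino acids ~80 µM, hexose ~5 mM,
acylcarnitines ~0.15 µM, …); only ratios of loading to noise matter for
the pattern analysis.

Case status is assigned **within** each pair with probability
`exp(eta_1)/(exp(eta_1) + exp(eta_2))`, `eta = sum_b ln(OR_b) · s_b`
over standardized latent scores.  This is the exact 1:1
conditional-logistic model, so the generating per-SD odds ratios are
recoverable without approximation — the construction turns
parameter-recovery tests into exact-in-expectation checks rather than
asymptotic ones.  Covariates (BMI, smoking, alcohol, education, marital
status, with explicit 'unknown' categories at realistic rates of
1–25%) are drawn independently of case status by default, so adjusted
fits remain unbiased recovery checks; confounding can be introduced via
configuration of the covariate model.  Matching factors (center, age
±6 months, blood-draw hour ±1 h, fasting category, follow-up length)
are shared within set.  Subtype labels are drawn at a configurable mix
(advanced 30.8% of staged cases, aggressive a 19.5% subset, high grade
12.8% of graded, ~10.7% disease deaths with ~8.9% of those sets losing
the control to censoring first), with the aggressive ⊆ advanced
constraint enforced.

What the generator does **not** emulate: assay drift, batch effects,
limit-of-detection truncation, multi-control matching, or within-pair
correlation of the latent scores induced by matching on shared causes
(default 0, configurable).  Passing tests therefore demonstrate
correctness of the estimators under a correctly specified design, not
robustness to those artefacts.

## Problem sizes in the validation suite

Recovery runs use the analysed-set sizes of the motivating design (580
advanced, 367 aggressive, 297 death sets) with 200–400 replicates;
cut-level cross-validation is validated on 24-variable 10/8/6-block
data over 50 replicates; type-I error uses 500 null replicates at 580
sets and the false-discovery check 300 null replicates of a full
119-metabolite screen at 100 sets.  These sizes make the mean recovered
log-OR's Monte-Carlo SE (≈ 0.004) an order of magnitude larger than the
finite-sample bias of the conditional MLE, so the two-MC-SE acceptance
band is a real test of unbiasedness.

## Known limitations

* Only 1:1 matching is supported; n:m conditional likelihoods are out
  of scope.
* Wald inference only by default; profile-likelihood CIs are not
  implemented.
* QC thresholds (CV ≤ 0.25, missingness ≤ 0.05, half-minimum floor)
  are generic targeted-metabolomics defaults, configurable per run.
* The PCA comparator retains 9 components by default and is fitted on
  all participants (deliberately asymmetric to the control-only treelet
  fit); both choices are configuration knobs.
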