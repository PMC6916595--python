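# treeletomics

Sparse metabolite-pattern analysis for matched case-control studies.

Targeted metabolomics panels (acylcarnitines, amino acids, biogenic
amines, phosphatidylcholines, sphingomyelins, hexose) produce dozens to
hundreds of strongly correlated concentrations.  Pattern methods
summarise them into a few interpretable axes, but ordinary PCA loads
every metabolite on every component.  `treeletomics` implements the
**treelet transform** — a hierarchical alternative that repeatedly
merges the two most correlated variables by a local 2×2 PCA (Jacobi
rotation) until all variables join a cluster tree — and couples it with
**conditional logistic regression** for 1:1 incidence-density-matched
case-control sets, the standard design of nested cancer biomarker
studies (here framed around prostate cancer subtypes: localized /
advanced / aggressive stage, Gleason grade, disease death).

Cutting the tree at level *c* and keeping the *K* highest-variance
*sum* variables yields unit-norm components `w_k` whose loadings are
**exactly zero** outside the subtree that produced them.  Participant
scores `s_ik = Σ_j w_kj · x_ij` on natural-log concentrations are then
tested against case status with the exact 1:1 conditional likelihood

    L(β) = Π_i  exp(x_case,i'β) / (exp(x_case,i'β) + exp(x_control,i'β)),

reported as `OR_1SD = exp(β·SD)` per one standard deviation of score in
the control population, with Wald 95% CIs.  The package covers the full
analysis surface: data-driven cut-level selection by cross-validation,
scree tables over K = 1…10, bootstrap stability (Tucker congruence),
covariate-adjusted per-SD and quintile contrasts, subtype analyses with
likelihood-ratio heterogeneity tests, ≤10/>10-year follow-up
stratification, mutual adjustment between correlated components
(|r| > 0.2), a censoring-aware disease-death contrast, a PCA comparator
and a per-metabolite screen with Benjamini-Hochberg control — plus a
synthetic matched-cohort generator with known latent-pattern ground
truth, so every estimator is validated by parameter recovery.

## Worked example

Simulate 580 matched pairs in which three latent metabolite patterns
(phospholipids, long-chain acylcarnitines with glutamate/ornithine/
taurine, and lysophosphatidylcholines) lower the odds of advanced-stage
disease with per-SD odds ratios 0.77, 0.72 and 0.81; then recover them:

```python
import treeletomics as tm
from treeletomics import risk
from treeletomics.preprocess import qc_filter, log_transform

panel = tm.build_panel()                       # 119-metabolite panel
effects = tm.EffectSpec({("block1", "advanced"): 0.77,
                         ("block2", "advanced"): 0.72,
                         ("block3", "advanced"): 0.81})
cohort = tm.simulate_matched_pairs(panel, effects, 580, "advanced", seed=11)

X = log_transform(qc_filter(cohort.concentrations())[0]).values
controls = X.loc[cohort.controls()["participant_id"]]

tt = tm.TreeletTransform(n_components=3, cut_level=77).fit(controls)
scores = tt.transform(X)
print("nonzero loadings:", (tt.components_ != 0).sum(axis=1))
for comp in scores.columns:
    fit = risk.clogit_fit(cohort, risk.ExposureSpec(scores[comp], name=comp))
    lo, hi = fit.or_ci
    print(f"{comp}: OR_1SD = {fit.odds_ratio:.2f} "
          f"(95% CI {lo:.2f}-{hi:.2f}), p = {fit.p_value:.2g}")
```

prints

```
nonzero loadings: [67  8  5]
TC1: OR_1SD = 0.76 (95% CI 0.68-0.86), p = 5.3e-06
TC2: OR_1SD = 0.77 (95% CI 0.68-0.86), p = 1.3e-05
TC3: OR_1SD = 0.76 (95% CI 0.67-0.86), p = 1.5e-05
```

The three components are exactly the generating blocks (67
phosphatidylcholines + hydroxysphingomyelins, 8 lysoPC, 5
acylcarnitine/amino-acid members — all other loadings exact zeros), and
each adjusted conditional-logistic odds ratio sits on its generating
value within sampling error.  The cut-level 77 is the level at which
the three blocks have just finished merging;
`treeletomics.cross_validate_cut` scans candidate cuts by held-out
variance explained when the structure is unknown.  Because the
phospholipid and lysoPC latents are generated with correlation 0.46,
their scores correlate (r = 0.45 in controls) and mutual adjustment
(`risk.mutual_adjust`, threshold |r| > 0.2) attenuates TC1 from 0.76
to 0.82 — the behaviour expected when two protective patterns share
variance.

The same analysis runs end to end from the shell:

```
treeletomics run-all --seed 7 --outdir run1 --n-sets 600
```

writing the cohort tables, merge history, sparse loadings, scores, the
forest-style risk table, PCA comparison, metabolite screen and a JSON
run manifest into `run1/` (bit-identical on rerun with the same seed).

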