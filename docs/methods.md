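# Methods

This note documents the statistical model, the synthetic data generator, the
numerical choices, and the limitations of `cohortsig`. Every empirical number
cited here is computed by the test suite (`tests/`) or the acceptance script
(`scripts/acceptance.py`); nothing is asserted that the repository does not
itself compute.

## Per-feature mixed model

For one study, feature abundance is modeled on the log10 scale after depth
normalization:

    y_ij = beta_0 + sum_t beta_t · 1[time(j) = t] + u_i + eps_ij

* `y_ij`: normalized abundance of the feature in sample *j* of subject *i*,
  `log10(count / depth × mean-depth + 1)` with the mean depth taken within the
  study; pathway tables (already library-size normalized upstream) instead use
  `log10(x + 1)` (`pathway_mode`).
* Timepoint is an unordered categorical with the pre-intervention baseline
  (month 0) as reference, so each `beta_t` is the log10 change at month *t*
  versus baseline.
* `u_i ~ N(0, sigma_u^2)` is a subject random intercept; `eps ~ N(0,
  sigma_e^2)`. The random intercept is what lets the model use unbalanced
  longitudinal designs in which not every subject appears at every timepoint.

Estimation is restricted maximum likelihood (REML). Because the random
structure is a single intercept per subject, `V = sigma_e^2 (I + lambda Z Z')`
with `lambda = sigma_u^2 / sigma_e^2` is block diagonal with rank-one blocks;
`V^{-1}` has a Sherman–Morrison closed form per subject and the REML criterion
profiles to a one-dimensional optimization over `lambda`. The optimizer is
bounded scalar minimization over `log lambda ∈ [−12, 12]` (absolute tolerance
1e-8), with the boundary `lambda = 0` (ordinary least squares) compared
explicitly; a failed optimization falls back to `lambda = 0` and is flagged
`converged = False`. The test suite checks the fit against statsmodels
`MixedLM` (coefficients to ~1e-5, variance components to ~1e-4) and checks the
standard errors against a dense-matrix evaluation of the model-based GLS
covariance `sigma^2 (X' V^{-1} X)^{-1}`; statsmodels reports a slightly
different Hessian-based SE approximation, which is why the SE oracle is the
GLS formula rather than `MixedLM.bse_fe`.

Two-sided p-values use `t = beta_t / se_t` with a within-subject degrees of
freedom convention `df = n_obs − n_subjects − (n_timepoints − 1)`. On null
synthetic cohorts the resulting per-test type-I error rate at alpha = 0.05 is
~0.05 (asserted within [0.01, 0.10] over 500 features × 10 seeds).

The per-feature signature statistic is the signed log10 p-value
`sign(beta_t) × (−log10 max(p, 1e-16))`; the floor (`p_floor`, configurable)
prevents infinities, and `sign(0) = 0`.

## Concordance

Each (study, post-timepoint) contrast gives a signature vector over features.
Comparison pairs are every cross-study combination of post-timepoints
("between") and every unordered pair of post-timepoints within one study
("within"); the four-study follow-up design used throughout yields 23 between
and 5 within pairs. Concordance is the Spearman rank correlation over the
features shared by the two contrasts, pairwise-complete (missing estimates
dropped, never imputed), reported only when ≥ 3 shared features exist. Its
p-value uses the t approximation `t = rho sqrt((n−2)/(1−rho^2))` with `n − 2`
degrees of freedom. All pair p-values are Benjamini–Hochberg adjusted as one
family per run, and within- versus between-study correlations are contrasted
with the Wilcoxon rank-sum test (exact null enumeration when both groups have
≤ 20 untied values, else a normal approximation with tie and continuity
corrections). Reported spreads of correlation coefficients are standard
deviations, labeled as such. For heatmap-style displays, the feature ×
contrast signature matrix is hierarchically clustered (Euclidean distance,
complete linkage) with missing entries imputed as 0 — imputation happens only
in the clustering display path, never in the correlation analysis.

## Community-level analysis

Bray–Curtis dissimilarities feed (a) principal coordinates analysis via
eigendecomposition of the Gower-centered matrix — negative eigenvalues
(possible for non-Euclidean dissimilarities) are reported but excluded from
coordinates and from proportion-explained — and (b) a multi-term PERMANOVA
with sequential (Type I) sums of squares for `distance ~ study + timepoint
(+ interaction)`, with timepoint coded pre/post. P-values come from free
permutation of sample labels with the add-one rule (or exhaustive enumeration
for small n); permuted pseudo-F values are compared to the observed value with
a 1e-9 relative tolerance so that permutations equivalent to the observed
labeling count as ties despite floating-point summation-order noise. Free
permutation ignores the repeated-measures structure of longitudinal designs —
a property of the published analysis this mirrors — and that caveat is
recorded in the result metadata. The null-calibration test therefore uses
randomly assigned sample-level labels, under which samples are exchangeable
and the test is exact (measured rejection rate ≈ 0.05 at alpha = 0.05).
Shannon diversity is `−Σ p ln p` (natural log) on raw counts.

## Classifier transfer

Per training set, relative abundances are transformed as z-scores of
`log10(x + 1e-5)` with per-feature mean and population SD *frozen* on the
training data and applied unchanged to external data; zero-variance features
are dropped at fit time, and features absent from external data are imputed as
relative abundance 0 before the log transform. Models are L1-penalized
logistic regression (inner stratified CV over `C ∈ logspace(−2, 3, 8)`) or a
500-tree random forest. Cross-validation is 8-fold × 10 repeats with folds
grouped by subject, so repeated measures never leak between train and test
(property-tested). Within-study AUROC is the mean over repeats of the AUROC of
pooled held-out predictions. For external validation and leave-one-study-out
pooling, all trained models score every external sample, per-sample scores are
averaged across models, and a single AUROC is computed on the averaged scores
(the score-averaging rule is asserted by a constructed counter-example where
it differs from averaging per-model AUROCs).

## Synthetic generator

The generator works on the log10 scale so planted effects are commensurate
with the pipeline's normalization. For study *s*, feature *f*, subject *i*,
sample *j* at timepoint *t*:

    L = mu_f + a_{s,f} + delta_{s,f,t} + u_i + e_{j,f}

with `mu_f ~ N(0, 1.5^2)` (global rank-abundance skew), `a ~ N(0,
sigma_study^2)` (the compositional batch effect), `u ~ N(0, sigma_subject^2)`,
`e ~ N(0, sigma_noise^2)`, and `delta = 0` at baseline. Sample composition is
`softmax_10(L)` and counts are `Multinomial(D_j, composition)` with lognormal
depths. The planted effect decomposes as

    delta_{s,f,t} = rho_between · delta_f + sqrt(1 − rho_between^2) · eta_{s,f}

over a random signal subset of `ceil(pi_signal × n_features)` features, both
components drawn `N(0, tau_effect^2)` and **persistent** across post-baseline
timepoints. Persistence is a deliberate design decision: independently
redrawn per-timepoint effects would make every cross-timepoint comparison —
i.e. all between-study pairs under unequal follow-up schedules —
structurally uncorrelated, contradicting the invariant that between-study
concordance approaches within-study concordance as `rho_between → 1`. Each
`delta_{s,f,t}` remains marginally `N(0, tau_effect^2)`.

Randomness is managed with `numpy.random.SeedSequence` substreams (one for the
signature, one per study), so identical configs are bit-identical and studies
do not interact. Defaults emulate four published 16S cohorts: 30/25/19/9
subjects, timepoint sets {0,1,6}, {0,3,12,24}, {0,6}, {0,6,12} months, 60 %
post-baseline retention.

**Scope.** The generator produces compositional, overdispersed,
batch-affected, longitudinally correlated count data — enough to exercise
every pipeline stage against ground truth. It does not model taxon–taxon
correlation beyond the compositional constraint, phylogenetic structure,
time-varying effect magnitudes, covariates (antibiotics, diet, surgery
subtype), or platform differences beyond a per-study compositional offset.

## Calibration of the acceptance regimes

Rank concordance over a *sparse* signature is structurally bounded by the
unaffected features: even with near-perfect effect-estimate recovery, the
null features' random relative ranks dilute Spearman rho (at `pi_signal =
0.2`, measured rho plateaus near 0.55 while the Pearson correlation of
planted-feature estimates exceeds 0.99). The "strong effects" regime used for
the monotonicity and endpoint checks is therefore a dense strong signature —
`pi_signal = 0.4`, `tau_effect = 1.5`, full retention, 30 subjects/study, two
post-timepoints per study — under which the measured between-study rho at
`rho_between = 1` averages ≈ 0.70. These conditions were chosen on that
structural analysis and then frozen.

## Numerical choices

* Spearman rho from scipy; its p recomputed from the t approximation.
* BH adjustment implemented directly (step-up with a reverse cumulative
  minimum); tested against statsmodels `multipletests` and a literal
  brute-force evaluation of the definition.
* p-values are clamped to `(nextafter(0, 1), 1]`; exact-zero p is never
  reported.
* Wilcoxon exact branch uses scipy's exact Mann–Whitney null; the asymptotic
  branch applies tie and continuity corrections and returns p = 1 when the
  tie-corrected variance is 0.
* AUROC via sklearn `roc_auc_score` (tied scores count 1/2), brute-force
  pair-counting oracle in tests.
* All derived seeds are drawn below 2^31.

## Limitations

* PERMANOVA's free permutation null is anticonservative under subject-nested
  repeated measures; restricted (within-subject) permutation is not
  implemented. Interpret longitudinal PERMANOVA p-values with care.
* The LMM t-test uses a fixed within-subject df convention rather than
  Satterthwaite/Kenward–Roger approximations; for very small cohorts the
  p-values are approximate.
* Depth normalization and relative abundance do not remove compositional
  coupling; planted single-feature effects induce small opposite-signed
  spillover on other features (visible as a small positive bias of
  between-study rho at `rho_between = 0`, measured ≈ 0.04–0.14 depending on
  the design).
* The classifier ensemble pools studies by simple feature-union with absent
  features imputed as zero; no batch correction is applied before pooling.
* Wall-clock performance targets one CPU; the per-feature scan parallelizes
  with joblib but results are independent of thread count.
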