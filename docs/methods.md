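# Methods

## The model

`gaitprog` analyses longitudinal Parkinson's disease (PD) cohorts in which
patients enter at different — and unknown — points of their disease course.
Comparing raw trajectories of clinical scores (UPDRS I–III, tremor-dominance
and PIGD subscores, the axial score) against time since diagnosis therefore
mixes early and advanced patients.  The core of the package is a latent-time
joint mixed-effect model (LTJMM) that aligns all patients on a common
disease clock:

```
y_ijk = beta_k' x_ij + gamma_k (t_ij + delta_i)
        + alpha0_ik + alpha1_ik t_ij + eps_ijk
```

for patient *i*, visit *j*, outcome *k*, where

* `t_ij` — years since PD diagnosis at the visit;
* `delta_i ~ N(0, sigma_delta^2)` — the patient's time shift, shared across
  all outcomes; `t + delta_i` is the *latent disease time*;
* `gamma_k` — the population progression rate of outcome *k*
  (score units/yr);
* `(alpha0_ik, alpha1_ik)` — correlated random intercept and slope per
  outcome; `alpha1_ik` is the patient's *individual* progression rate
  relative to the population, and is the target of the downstream
  prediction experiments;
* `x_ij` — adjustment covariates: age at diagnosis, sex, and per-visit
  medication state (ON/OFF);
* `eps_ijk ~ N(0, sigma_k^2)` — residual noise, independent across cells.

Trajectories are linear in time; no sigmoid or ordinal-score likelihoods
are modelled.  Missing outcome cells are excluded from the likelihood, not
imputed.

### Estimation

All random effects are jointly Gaussian, so they are integrated out
analytically: each patient contributes a multivariate-normal likelihood
with mean `beta_k' x + gamma_k t` and covariance
`Z G Z' + diag(sigma_k^2)`, where the random-effect design `Z` carries a
`gamma_k`-weighted column for the shared shift and per-outcome
intercept/slope columns.  The exact marginal likelihood is maximised with
L-BFGS-B over the fixed effects and the variance parameters on bounded log
scales, plus a weak shrinkage penalty on the intercept–slope correlations
(a MAP-style regulariser that keeps them off the ±1 boundary).  Per-patient
effects are then empirical-Bayes posterior means, with posterior standard
deviations from the conditional covariance.  `method="mcmc"` samples the
same marginal posterior with an affine-invariant ensemble sampler (emcee)
and returns posterior means; it is an optional cross-check, not the
default, because the marginal-ML optimum is the same estimand at a fraction
of the cost.  Standard errors of the fixed effects, when requested, come
from a central-finite-difference Hessian at the optimum (Laplace
approximation).

Numerical choices that matter:

* **Internal centering.**  Time and covariates are centered (and the
  centered design rounded at 1e-9, far below data precision) before
  optimisation.  A constant shift of all observation times then reproduces
  a bit-identical optimisation problem, so the fit is exactly equivariant
  under time reparameterisation — verified to ~1e-14 in the tests.
* **Identifiability.**  `E[delta] = 0` is enforced by the marginal model;
  after fitting, the mean posterior shift is additionally subtracted and
  absorbed into the per-outcome intercepts.  With a single outcome the
  shift and the intercept trade off and a warning is emitted; with K ≥ 2
  the cross-outcome covariance (offsets proportional to `gamma_k`)
  identifies the shift.
* **ML, not REML**, everywhere a likelihood-ratio test is taken downstream.
* **Convergence**: relative objective change below 1e-8 (configurable) or
  the iteration cap; the objective trace is recorded and is non-increasing
  across accepted iterates.
* Degenerate noise-free inputs are handled by bounding all log-scales from
  below; a tiny diagonal jitter (1e-9) guards the Cholesky factorisations.

### Validation procedures

Two checks mirror how such a model is validated in practice: (1) the
visit-level Spearman correlation between fitted latent time and the Hoehn &
Yahr stage, with a per-stage latent-time mean table (stages tie many
visits, so even a perfect ordering yields Spearman slightly below 1 —
about 0.99 at n = 1000); (2) last-visit holdout — each patient's final
visit per outcome is removed, the model refitted once, the held-out values
predicted from the refitted patient effects, and per-outcome Pearson
correlations (with Fisher 95% CIs) plus their mean ("pooled") reported.

## Association testing

Gait sessions are matched to same-day clinical visits (configurable
tolerance, nearest visit wins, ties to the earlier visit).  For each
outcome family the adjustment covariates follow a fixed rule — age and sex
when modelling latent time itself; only the latent disease time when
modelling scores or slopes (the latent time already comes from a model
adjusted for age and sex).  Feature sets are all features jointly
(`allGait`), per-task sets, and optional single-feature sets.  Features are
z-scored within the analysis sample so coefficients are per-SD and
comparable across units.  Each set is tested against the covariate-only
null by a likelihood-ratio test (chi-squared reference, df = number of
added columns; the random-effects structure is identical in null and full,
so no boundary correction arises).  A patient random intercept is used for
repeated-gait designs.  All cells of one cohort scan form the
multiple-testing family and are adjusted with Benjamini–Yekutieli
(`p~_(i) = min_{j>=i} min(1, m c(m) p_(j)/j)`, `c(m) = sum 1/l`), which
controls the FDR under arbitrary dependence — appropriate because the
cells share patients and features.  Note that step-up adjusted p-values
are *not* monotone under family growth: adding a smaller p can lower
another cell's adjusted p through a rank shift; the property suite asserts
the correct monotonicity (componentwise in the raw p's at fixed family
size).

## Slope prediction

The LTJMM random slope of a motor outcome is predicted from the first (or
first two, column blocks suffixed `__v1`/`__v2`) gait visits, one row per
patient, optionally with age and sex.  Learners (random forest, gradient
boosting, L1-penalised linear) are tuned by randomized search inside an
inner 5-fold on each outer training split only, and scored as
`R^2 = 1 − SSE/SST` on each outer test fold over 10 repeats of an outer
5-fold (both counts configurable; the repeated 5-fold default matches the
more detailed of the two protocols the source literature reports).  A gait
model is compared against the age+sex baseline with a paired two-sided
Wilcoxon signed-rank test on fold-level R² (zero differences dropped; a
fully tied comparison returns p = 1).  Feature attribution offers exact
interventional Shapley values by full coalition enumeration against a
background sample — additive by construction, feasible to 15 features —
and a permutation fallback (mean |prediction change| under column
permutation) beyond that.

## Trial power

A one-year two-arm trial with common visit schedules (day 0 and every
f days, f ∈ {7, 30, 60}; days/365.25 = years) is analysed under the
random-slope mixed model.  The treatment effect is a 30% reduction of the
mean control slope (Δ = 0.30 |mu_s|); defaults alpha = 0.01 two-sided,
power 0.80, 1:1 allocation.  The closed-form (Edland) per-arm size is

```
n_arm = 2 (z_{1−a/2} + z_pow)^2 (sigma_s^2 + sigma_eps^2 / Sxx) / Delta^2
```

with `Sxx = sum_j (t_j − t_bar)^2`; totals are rounded up to the next even
integer.  The companion Monte-Carlo simulator generates per-patient random
intercepts/slopes, fits a random intercept+slope mixed model with a
group-by-time interaction per replicate, and applies the two-sided Wald
test; non-convergent replicates are excluded and counted.  A gait-predicted
UPDRS III endpoint is modelled as the observed endpoint plus independent
measurement noise whose sd defaults to the residual sd of the endpoint
model (UPDRS III ~ z-scored 4×10m features + patient random intercept,
ML); variance components for the observed endpoint are taken from config
or estimated from data with a random intercept+slope fit.  Whether the
surrogate's error should instead be handled by refitting variance
components on predicted scores is genuinely open; both modes exist
(`with_extra_noise` vs `estimate_variance_components` on predictions).

## The synthetic cohorts

The generator emulates the two study designs end to end and returns the
generative truth for recovery testing.

* **lux_like** — 612 patients (161 with one gait visit over TUG, Turn,
  Tray, Count); outcomes UPDRS I–III, TD, PIGD, MDS-axial; near-annual
  visits (mean 5.32, sd 1.53, ≥ 2); age at diagnosis N(59.8, 8.6²) with
  Gamma-distributed baseline disease duration so baseline age averages
  ≈ 64.7; 73% male.
* **erl_like** — 264 patients (178 with repeated gait visits: count
  N(2.84, 2.37²) rounded and truncated at 1, drawn from the patient's
  clinical dates); outcomes UPDRS III and original-scale axial; irregular
  lognormal visit gaps with median 364 days; an 11-year observation
  window caps follow-up (7 years for lux_like), mimicking each study's
  recruitment period.

Outcome parameters (`gamma`, residual sd, random-effect sds) were set so
that baseline score means and cross-sectional sds approximate the
published cohort tables, with the spread split between latent-time
dispersion (`sigma_delta` = 3 yr) and intercept heterogeneity.  Scores are
left continuous and unclipped (the model is Gaussian); the cohort declares
correspondingly widened valid ranges, and `clip_scores=True` restores
clinical bounds when wanted.

Gait features follow
`a + b (t + delta_i) + c alpha1_i(target) + patient effect + noise` with
signs matching the clinical picture (speed and stride length fall with
disease time; stride and stance time rise).  The ratio c/b varies across
features — some mark current severity, others specifically separate fast
progressors at equal severity — because with proportional loadings the
slope signal would be linearly inseparable from the (much larger) severity
signal and no slope-prediction experiment could succeed; heterogeneous
loadings match the attribution findings reported for real devices.  Swing
time is generated as stride − stance plus clipped measurement noise so
the gait phases always satisfy the schema's 5% consistency tolerance.
H&Y stages are ordinal bins of jittered latent time (7 thresholds over
0–14 yr, jitter sd 0.5).  A `with_null_task` preset zeroes b and c for one
task to support specificity experiments.

What the generator does **not** emulate: raw sensor signals, dropout or
informative missingness, floor/ceiling effects of bounded scores,
nonlinear trajectory shapes, and measurement-protocol drift.  Passing
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not performance on real cohort data — the
published cohort-specific numbers are computed on restricted data and are
out of reach by design.

## Problem sizes in the test and acceptance runs

The shipped experiments use reduced but honest sizes chosen as the
smallest cohorts at which the planted effects are comfortably identified:
recovery benchmark 200 patients × 3 outcomes × 5 visits; association
power/specificity 20 replicates of 110 patients; slope prediction 150
patients with 50 outer folds; Monte-Carlo power 500 replicates at the
Edland sample size (98 in the shipped configuration).  All seeds are
explicit.

## Known limitations

* The random-effect covariance is a full 2×2 per outcome but random
  effects are independent *across* outcomes (the shared shift carries all
  cross-outcome dependence).
* Gradients are finite-difference; fits with many outcomes (K = 6, full
  covariate set) take a few minutes at cohort scale.
* The chi-squared LR reference is asymptotic; at very small n the test is
  mildly miscalibrated (the calibration suite runs at n = 150).
* Exact Shapley enumeration is exponential in the feature count and
  guarded at 15 features.
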