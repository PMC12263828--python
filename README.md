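# gaitprog

Latent-time progression modelling of Parkinson's disease (PD) with digital
gait endpoints.

Longitudinal PD cohorts recruit patients at every stage of the disease, so
raw trajectories of clinical scores against time since diagnosis mix
mildly and severely affected patients.  `gaitprog` is a toolbox for
biostatisticians working with such cohorts plus wearable gait data.  It

1. aligns multi-outcome score trajectories (UPDRS I–III, TD, PIGD, axial
   score) on a common latent disease timescale with a **latent-time joint
   mixed-effect model (LTJMM)**;
2. tests whether digital gait features (stride length, gait speed,
   stride/stance/swing time, …, per walking task) are associated with
   disease stage, severity and individual progression rate, via
   likelihood-ratio tests against covariate-only nulls with
   Benjamini–Yekutieli FDR control;
3. predicts patient-specific progression slopes from gait features in a
   nested cross-validation harness with paired Wilcoxon comparison against
   an age+sex baseline and exact Shapley attribution;
4. quantifies the clinical-trial value of a gait-predicted UPDRS III
   endpoint: Edland random-slope sample sizes and Monte-Carlo verified
   power across weekly / monthly / bi-monthly visit schedules.

Because the motivating cohort data are available only on request from the
study teams, the package ships a first-class synthetic-cohort generator
(`gaitprog.simulate`) that emulates both study designs — a LuxPARK-like
cohort (single gait visit) and an Erlangen-like cohort (repeated irregular
gait visits) — with known ground truth for every recovery experiment.

## The model

For patient *i*, visit *j*, outcome *k*:

```
y_ijk = beta_k' x_ij + gamma_k (t_ij + delta_i) + alpha0_ik + alpha1_ik t_ij + eps_ijk
delta_i ~ N(0, sigma_delta^2),   (alpha0_ik, alpha1_ik) ~ N(0, Psi_k),   eps_ijk ~ N(0, sigma_k^2)
```

`t + delta_i` is the latent disease time (the common disease clock);
`gamma_k` the population progression rate; `alpha1_ik` the patient's
individual progression rate — the quantity the gait features are asked to
predict.  Fitting maximises the exact marginal likelihood (random effects
integrated analytically) and recovers per-patient effects as
empirical-Bayes posterior means; see `docs/methods.md` for estimation
details, identifiability and numerical choices.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from gaitprog import (SimConfig, simulate_full, LTJMM,
                      match_gait_to_clinical, hy_alignment_check)
from gaitprog.association import (build_feature_sets,
                                  default_outcome_specs, association_scan)
from gaitprog.cohort import GaitSchema

cfg = SimConfig.erl_like(n_patients=120, n_gait_patients=120)
cohort, truth = simulate_full(cfg, 7)

res = LTJMM.from_cohort(cohort, ["updrs3", "axial"]).fit()
print(res.summary())

hy = hy_alignment_check(res, cohort)
print(f"latent time vs H&Y stage: Spearman rho = {hy['spearman']:.3f}")

matched = match_gait_to_clinical(cohort)
sets = build_feature_sets(GaitSchema(), ["TUG", "W2x10", "W4x10"],
                          available=list(matched.columns))
scan, _ = association_scan(matched, res,
                           default_outcome_specs("erl_like"), sets)
print(scan[scan.feature_set == "W4x10"]
      [["outcome", "family", "lr_stat", "df", "p_adj"]]
      .round(4).to_string(index=False))
```

prints

```
Latent-time joint mixed-effect model
====================================================
patients: 120   observations: 1624   outcomes: 2
log-likelihood: -3979.419   converged: True   iterations: 136
sigma_delta (time-shift sd, yr): 3.0964

         gamma (units/yr)  intercept  sigma   tau0   tau1    rho  beta[age_at_diagnosis]  beta[sex]  beta[med_on]
outcome
updrs3             1.8262     8.9137 3.0752 4.8463 0.9333 0.3698                  0.0184     1.3876       -2.9410
axial              0.4524    -1.3215 1.1952 1.8974 0.3391 0.5393                  0.0539     1.1699       -0.4655

latent time vs H&Y stage: Spearman rho = 0.926
    outcome      family  lr_stat  df  p_adj
     updrs3       score   2.4607   7 1.0000
      axial       score  27.5036   7 0.0018
     updrs3       slope   0.0000   7 1.0000
      axial       slope  49.3708   7 0.0000
latent_time latent_time 552.0019   7 0.0000
```

Reading the output: the cohort was generated with a UPDRS III progression
rate of 2 points/yr, residual sd 3 and time-shift sd 3 yr; the fit
recovers `gamma = 1.83`, `sigma = 3.08`, `sigma_delta = 3.10`.  Latent
time orders the (planted) Hoehn & Yahr stages almost perfectly.  In the
association scan, the 4×10m walking features are strongly associated with
the axial score, its progression slope, and latent disease time — the
signals planted by the generator — while the UPDRS III slope, to which the
gait features are not coupled, stays at p = 1.

## Command-line pipeline

A config-driven runner executes the whole analysis and writes CSV/JSON
artifacts plus a reproducibility manifest:

```sh
gaitprog all --config run.yaml --out results/ --seed 1
```

with stages `simulate`, `fit-ltjmm`, `associate`, `predict-progression`,
`trial-power` also runnable individually (later stages require the
artifacts of earlier ones).

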