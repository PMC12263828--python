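"""Trial power for slope endpoints: Edland formula and Monte-Carlo check.

A two-arm one-year randomized trial is analysed with a random-slope linear
mixed model; the treatment effect is a fractional reduction of the mean
control-arm progression slope.  Under the Edland random-slope method the
per-arm sample size to detect a slope difference Delta with two-sided
level alpha and a common visit schedule t_1..t_J is

    n_arm = 2 (z_{1-alpha/2} + z_power)^2 (sigma_s^2 + sigma_eps^2 / Sxx)
            / Delta^2,        Sxx = sum_j (t_j - t_bar)^2

where sigma_s^2 is the between-patient slope variance and sigma_eps^2 the
residual variance.  Denser visit schedules increase Sxx, shrinking the
residual term — the mechanism by which a frequently measured digital
endpoint can compensate for its extra measurement noise.

The gait-predicted endpoint is a UPDRS III surrogate predicted from the
4x10m walking task's features by a linear mixed model with a patient
random intercept; its residual sd can be propagated into the simulated
trial as additional endpoint noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["VisitSchedule", "VarianceComponents", "PowerSpec", "PowerCurve",
           "make_schedule", "edland_n", "analytic_power", "mc_power",
           "power_curve", "gait_endpoint_model", "EndpointModel",
           "estimate_variance_components"]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class VisitSchedule:
    """Common visit times (years) of both arms."""

    times: tuple[float, ...]
    frequency_days: int | None = None
    duration_days: int = 365

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if len(t) < 2 or np.any(np.diff(t) <= 0) or t[0] != 0:
            raise ValueError("times must start at 0 and strictly increase, "
                             ">= 2 visits")

    @property
    def sxx(self) -> float:
        t = np.asarray(self.times)
        return float(np.sum((t - t.mean()) ** 2))


def make_schedule(frequency_days: int, duration_days: int = 365
                  ) -> VisitSchedule:
    """Visits at day 0 and every multiple of the frequency within duration."""
    if frequency_days <= 0:
        raise ValueError("frequency_days must be positive")
    if frequency_days > duration_days:
        raise ValueError("frequency_days must not exceed duration_days")
    days = np.arange(0, duration_days + 1, frequency_days)
    return VisitSchedule(times=tuple(days / DAYS_PER_YEAR),
                         frequency_days=frequency_days,
                         duration_days=duration_days)


@dataclass
class VarianceComponents:
    """Random-slope model components of an endpoint (score units, years)."""

    sigma_s2: float      # between-patient slope variance ((score/yr)^2)
    sigma_eps2: float    # residual variance (score^2)
    mu_s: float          # mean control-arm slope (score/yr)
    intercept_sd: float = 0.0   # between-patient intercept sd (simulation)

    def __post_init__(self):
        if self.sigma_s2 < 0 or self.sigma_eps2 < 0 or self.intercept_sd < 0:
            raise ValueError("variance components must be >= 0")

    def with_extra_noise(self, extra_sd: float) -> "VarianceComponents":
        """Add independent endpoint measurement noise (e.g. surrogate error)."""
        return VarianceComponents(self.sigma_s2,
                                  self.sigma_eps2 + extra_sd ** 2,
                                  self.mu_s, self.intercept_sd)


@dataclass
class PowerSpec:
    alpha: float = 0.01
    power: float = 0.80
    effect_fraction: float = 0.30

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        # 0 is allowed for null (type-I calibration) trials; the sample-size
        # formula itself requires a positive effect
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must lie in [0, 1]")


def _delta(vc: VarianceComponents, spec: PowerSpec) -> float:
    d = spec.effect_fraction * abs(vc.mu_s)
    if d == 0:
        raise ValueError("treatment effect is zero (mu_s = 0)")
    return d


def edland_n(vc: VarianceComponents, schedule: VisitSchedule,
             spec: PowerSpec) -> int:
    """Total sample size (both arms, rounded up to even) at target power."""
    sxx = schedule.sxx
    if sxx <= 0:
        raise ValueError("schedule has zero time spread (Sxx = 0)")
    d = _delta(vc, spec)
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    n_arm = 2 * (z_a + z_b) ** 2 * (vc.sigma_s2 + vc.sigma_eps2 / sxx) / d ** 2
    return 2 * int(np.ceil(n_arm))


def edland_n_arm_raw(vc: VarianceComponents, schedule: VisitSchedule,
                     spec: PowerSpec) -> float:
    """Unrounded per-arm sample size (useful for scaling identities)."""
    d = _delta(vc, spec)
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    return 2 * (z_a + z_b) ** 2 * (vc.sigma_s2 + vc.sigma_eps2
                                   / schedule.sxx) / d ** 2


def analytic_power(vc: VarianceComponents, schedule: VisitSchedule,
                   total_n: int, spec: PowerSpec) -> float:
    """Normal-approximation power of the slope-difference Wald test.

    With a zero effect this returns alpha/2 — the probability mass of one
    tail of the two-sided test.
    """
    if total_n < 4 or total_n % 2:
        raise ValueError("total_n must be even and >= 4")
    sxx = schedule.sxx
    if sxx <= 0:
        raise ValueError("schedule has zero time spread (Sxx = 0)")
    d = spec.effect_fraction * abs(vc.mu_s)
    se = np.sqrt(2 * (vc.sigma_s2 + vc.sigma_eps2 / sxx) / (total_n / 2))
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(d / se - z_a))


def mc_power(vc: VarianceComponents, total_n: int, schedule: VisitSchedule,
             spec: PowerSpec, endpoint: str = "observed",
             extra_noise_sd: float = 0.0, reps: int = 2000, seed: int = 0
             ) -> dict:
    """Monte-Carlo power of the mixed-model slope test.

    Each replicate simulates two equal arms with per-patient random
    intercepts/slopes (treatment slope = (1 - effect_fraction) * mu_s),
    optionally adds surrogate-endpoint noise, fits a random intercept+slope
    mixed model with a group-by-time interaction and applies the two-sided
    Wald test at level alpha.  Non-convergent replicates are excluded and
    counted.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if total_n < 4 or total_n % 2:
        raise ValueError("total_n must be even and >= 4")
    if endpoint not in ("observed", "gait_predicted"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    rng = np.random.default_rng(seed)
    t = np.asarray(schedule.times)
    J = len(t)
    n_arm = total_n // 2
    group = np.repeat(np.r_[np.zeros(n_arm), np.ones(n_arm)], J)
    tt = np.tile(t, total_n)
    pid = np.repeat(np.arange(total_n), J)
    X = np.column_stack([np.ones_like(tt), tt, group, tt * group])
    sd_s = np.sqrt(vc.sigma_s2)
    sd_e = np.sqrt(vc.sigma_eps2)
    noise_sd = extra_noise_sd if endpoint == "gait_predicted" else 0.0

    rej = 0
    n_fail = 0
    n_done = 0
    for _ in range(reps):
        slope = vc.mu_s * (1 - spec.effect_fraction * group[::J]) \
            + rng.normal(0, sd_s, total_n)
        inter = rng.normal(0, vc.intercept_sd, total_n)
        y = inter[pid] + slope[pid] * tt + rng.normal(0, sd_e, len(tt))
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, len(y))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = sm.MixedLM(y, X, groups=pid,
                                 exog_re=np.column_stack([np.ones_like(tt), tt]))
                res = mod.fit(reml=False, method="lbfgs", maxiter=200)
            if not np.isfinite(res.llf):
                raise ValueError("non-finite likelihood")
            z = res.fe_params[3] / np.asarray(res.bse_fe)[3]
            p = 2 * stats.norm.sf(abs(z))
        except Exception:
            n_fail += 1
            continue
        n_done += 1
        rej += int(p < spec.alpha)
    if n_done == 0:
        raise RuntimeError("all Monte-Carlo replicates failed to converge")
    p_hat = rej / n_done
    return {"power": p_hat,
            "mc_se": float(np.sqrt(p_hat * (1 - p_hat) / n_done)),
            "reps_used": n_done, "reps_failed": n_fail}


@dataclass
class PowerCurve:
    endpoint: str
    schedule: VisitSchedule
    grid: pd.DataFrame           # n_total, power_analytic [, power_mc, mc_se]
    n_required: int


def power_curve(vc_by_endpoint: dict[str, VarianceComponents],
                schedules: list[VisitSchedule], spec: PowerSpec,
                n_grid: list[int] | None = None, mc_reps: int = 0,
                seed: int = 0) -> list[PowerCurve]:
    """One analytic (optionally MC-verified) power curve per condition."""
    curves = []
    for endpoint, vc in vc_by_endpoint.items():
        for sched in schedules:
            n_req = edland_n(vc, sched, spec)
            grid_n = n_grid or sorted({max(4, int(2 * round(f * n_req / 2)))
                                       for f in (0.25, 0.5, 0.75, 1.0, 1.25,
                                                 1.5, 2.0)})
            rows = []
            for n in grid_n:
                if n < 4:
                    continue
                row = {"n_total": n,
                       "power_analytic": analytic_power(vc, sched, n, spec)}
                if mc_reps >= 100:
                    m = mc_power(vc, n, sched, spec, reps=mc_reps, seed=seed)
                    row["power_mc"] = m["power"]
                    row["mc_se"] = m["mc_se"]
                rows.append(row)
            curves.append(PowerCurve(endpoint=endpoint, schedule=sched,
                                     grid=pd.DataFrame(rows),
                                     n_required=n_req))
    return curves


@dataclass
class EndpointModel:
    """Linear mixed model mapping gait features to a clinical score."""

    feature_cols: list[str]
    params: pd.Series
    means: pd.Series
    sds: pd.Series
    resid_sd: float
    rho_insample: float
    random_intercepts: pd.Series | None
    predictions: pd.DataFrame
    mixed: bool

    def predict(self, df: pd.DataFrame, use_random_effects: bool = False
                ) -> np.ndarray:
        """Predict the score from gait features (fixed effects by default)."""
        z = (df[self.feature_cols] - self.means) / self.sds
        X = np.column_stack([np.ones(len(df)), np.asarray(z, float)])
        pred = X @ self.params.to_numpy()
        if use_random_effects and self.random_intercepts is not None:
            re = df["patient_id"].map(self.random_intercepts).fillna(0.0)
            pred = pred + re.to_numpy()
        return pred


def gait_endpoint_model(matched: pd.DataFrame, task: str = "W4x10",
                        outcome: str = "updrs3") -> EndpointModel:
    """Fit the gait-predicted endpoint: score ~ z-scored task features.

    A patient random intercept is used where patients contribute repeated
    gait visits; with single visits throughout, the model falls back to
    ordinary least squares with a warning.  Returns per-visit predictions
    (random effects included where available) and the in-sample Pearson
    correlation with the observed score.
    """
    feat_cols = [c for c in matched.columns if c.startswith(f"{task}__")]
    if not feat_cols:
        raise ValueError(f"no feature columns for task {task!r}")
    sub = matched.dropna(subset=feat_cols + [outcome]).copy()
    means = sub[feat_cols].mean()
    sds = sub[feat_cols].std(ddof=0)
    if (sds == 0).any():
        raise ValueError(f"zero-variance features: "
                         f"{list(sds.index[sds == 0])}")
    z = (sub[feat_cols] - means) / sds
    X = np.column_stack([np.ones(len(sub)), np.asarray(z, float)])
    y = sub[outcome].to_numpy(float)
    names = ["const"] + feat_cols
    repeated = sub.groupby("patient_id").size().max() > 1
    ri = None
    if repeated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=sub["patient_id"].to_numpy()) \
                .fit(reml=False)
        params = pd.Series(res.fe_params, index=names)
        ri = pd.Series({g: float(v.iloc[0]) for g, v in
                        res.random_effects.items()})
        pred = X @ res.fe_params + \
            sub["patient_id"].map(ri).fillna(0.0).to_numpy()
        resid_sd = float(np.sqrt(res.scale))
    else:
        warnings.warn("single gait visit per patient everywhere; endpoint "
                      "model falls back to fixed effects only", UserWarning,
                      stacklevel=2)
        res = sm.OLS(y, X).fit()
        params = pd.Series(res.params, index=names)
        pred = res.fittedvalues
        resid_sd = float(np.sqrt(res.mse_resid))
    rho = float(stats.pearsonr(pred, y).statistic)
    predictions = pd.DataFrame({
        "patient_id": sub["patient_id"].to_numpy(),
        "observed": y, "predicted": pred})
    return EndpointModel(feature_cols=feat_cols, params=params, means=means,
                         sds=sds, resid_sd=resid_sd, rho_insample=rho,
                         random_intercepts=ri, predictions=predictions,
                         mixed=repeated)


def estimate_variance_components(df: pd.DataFrame, response: str,
                                 time: str = "years_since_diagnosis",
                                 patient_col: str = "patient_id",
                                 intercept_sd: float | None = None
                                 ) -> VarianceComponents:
    """Variance components from a random intercept+slope mixed model (ML)."""
    sub = df.dropna(subset=[response, time])
    t = sub[time].to_numpy(float)
    X = np.column_stack([np.ones(len(sub)), t])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(sub[response].to_numpy(float), X,
                         groups=sub[patient_col].to_numpy(),
                         exog_re=X).fit(reml=False)
    cov_re = np.asarray(res.cov_re)   # statsmodels reports data units
    return VarianceComponents(
        sigma_s2=float(cov_re[1, 1]), sigma_eps2=float(res.scale),
        mu_s=float(res.fe_params[1]),
        intercept_sd=float(np.sqrt(max(cov_re[0, 0], 0.0)))
        if intercept_sd is None else intercept_sd)
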