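"""Seeded synthetic cohorts with latent-time structured trajectories.

Two templates emulate the designs this package targets:

``lux_like``
    A LuxPARK-style observational cohort: six outcome scores
    (UPDRS I-III, TD, PIGD, axial on the MDS scale), near-annual visits,
    and a patient subset with a *single* digital gait assessment over four
    dual-task walking exercises (TUG, Turn, Tray, Count).

``erl_like``
    An Erlangen-style clinical-routine cohort: UPDRS III and the original
    (no freezing-of-gait) axial score, irregular visit gaps with median
    about one year, and repeated gait sessions (mean 2.84, sd 2.37 per
    patient, truncated at one) over TUG and the 2x10m / 4x10m walks.

Outcome trajectories follow the latent-time joint mixed model: for patient
``i``, visit ``j``, outcome ``k``

    y_ijk = beta_k' x_ij + gamma_k (t_ij + delta_i)
            + alpha0_ik + alpha1_ik t_ij + eps_ijk

with a shared time shift delta_i ~ N(0, sigma_delta^2) and correlated
per-outcome random intercepts/slopes.  Gait features drift with latent
disease time (loading ``b``) and with the patient's random slope on a
target outcome (loading ``c``), so slope-prediction experiments have a
recoverable planted signal.  Ground truth is returned for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, GaitSchema, HY_STAGES

__all__ = [
    "OutcomeParams", "GaitLoadings", "SimConfig", "GroundTruth",
    "simulate_cohort", "simulate_gait_sessions", "assign_hy", "simulate_full",
    "recovery_benchmark_config",
]


class ConfigError(ValueError):
    """Raised before any sampling when a simulation config is invalid."""


@dataclass
class OutcomeParams:
    """Generative parameters of one clinical outcome score.

    ``gamma`` is the common progression rate along latent disease time
    (score units/yr); ``tau0``/``tau1``/``rho`` parameterise the random
    intercept-slope covariance; ``sigma`` is the residual sd.
    """

    intercept: float
    gamma: float
    sigma: float
    tau0: float
    tau1: float
    rho: float = 0.2
    beta_age: float = 0.0   # per year of age at diagnosis above 60
    beta_sex: float = 0.0   # male minus female
    beta_med: float = 0.0   # ON minus OFF


@dataclass
class GaitLoadings:
    """Generative parameters of one gait feature within one task.

    feature = a + b*(t + delta_i) + c*alpha1_i(target) + patient effect
              + N(0, noise_sd^2)
    """

    a: float
    b: float
    c: float
    patient_sd: float
    noise_sd: float


def _base_gait() -> dict[str, GaitLoadings]:
    # Signs follow the clinical picture: speed and stride length fall with
    # disease time, stride and stance time rise.  The ratio of the
    # slope loading c to the latent-time loading b varies across features:
    # some features mark current severity, others specifically distinguish
    # fast progressors at equal severity, so the two signals are separable.
    return {
        "gait_speed": GaitLoadings(1.25, -0.025, -0.35, 0.08, 0.05),
        "stride_length": GaitLoadings(1.30, -0.020, -0.08, 0.08, 0.05),
        "stride_time": GaitLoadings(1.05, 0.015, 0.04, 0.06, 0.04),
        "stance_time": GaitLoadings(0.66, 0.011, 0.18, 0.04, 0.03),
        "swing_time": GaitLoadings(0.39, 0.004, 0.01, 0.025, 0.015),
        "landing_impact": GaitLoadings(1.00, 0.020, 0.00, 0.15, 0.10),
        "max_sensor_lift": GaitLoadings(15.0, -0.120, -0.80, 1.50, 1.00),
    }


_TASK_LEVEL = {"TUG": 1.0, "Turn": 0.95, "Tray": 0.97, "Count": 0.96,
               "W2x10": 1.0, "W4x10": 1.02}

_LUX_OUTCOMES = {
    "updrs1": OutcomeParams(6.5, 0.40, 2.0, 4.5, 0.30, 0.2, 0.05, 0.0, -0.5),
    "updrs2": OutcomeParams(6.5, 0.60, 2.0, 5.0, 0.35, 0.2, 0.05, 0.0, -0.5),
    "updrs3": OutcomeParams(20.5, 2.00, 3.0, 5.0, 1.00, 0.2, 0.10, 1.0, -3.0),
    "axial": OutcomeParams(2.8, 0.50, 1.2, 2.0, 0.35, 0.2, 0.02, 0.2, -0.5),
    "pigd": OutcomeParams(0.28, 0.05, 0.15, 0.45, 0.04, 0.2, 0.0, 0.0, -0.05),
    "td": OutcomeParams(0.45, 0.01, 0.12, 0.38, 0.01, 0.1, 0.0, 0.0, 0.0),
}

_ERL_OUTCOMES = {
    "updrs3": OutcomeParams(11.0, 2.00, 3.0, 5.0, 1.00, 0.2, 0.10, 1.0, -3.0),
    "axial": OutcomeParams(2.7, 0.50, 1.2, 2.0, 0.35, 0.2, 0.02, 0.2, -0.5),
}

#: Declared score ranges of the *Gaussian* generative model (trajectories
#: are not clipped by default, so ranges are wider than the clinical ones).
_SIM_RANGES = {
    "updrs1": (-40.0, 120.0), "updrs2": (-40.0, 120.0),
    "updrs3": (-60.0, 200.0), "axial": (-20.0, 70.0),
    "pigd": (-4.0, 8.0), "td": (-4.0, 8.0),
}


@dataclass
class SimConfig:
    """Full generative configuration of a synthetic cohort."""

    template: str = "lux_like"
    n_patients: int = 612
    n_gait_patients: int = 161
    outcomes: dict[str, OutcomeParams] = field(
        default_factory=lambda: dict(_LUX_OUTCOMES))
    sigma_delta: float = 3.0
    # visit process
    visits_mean: float = 5.32
    visits_sd: float = 1.53
    visits_min: int = 2
    visits_max: int = 40
    spacing: str = "annual"            # 'annual' or 'lognormal'
    spacing_jitter: float = 0.15       # sd of annual gap (yr)
    gap_median_days: float = 364.0     # lognormal spacing
    gap_log_sd: float = 0.80
    min_gap_days: float = 14.0
    max_followup_years: float = 7.0    # study observation window
    # demographics: age at diagnosis ~ N, baseline disease duration ~ Gamma
    age_mean: float = 59.8
    age_sd: float = 8.6
    duration_shape: float = 0.865
    duration_scale: float = 5.69
    p_male: float = 0.73
    p_med_on: float = 0.70
    # gait process
    tasks: tuple[str, ...] = ("TUG", "Turn", "Tray", "Count")
    gait: dict[str, dict[str, GaitLoadings]] = field(default_factory=dict)
    gait_target_outcome: str = "axial"
    gait_sessions_mean: float = 1.0    # >1 only for repeated-gait designs
    gait_sessions_sd: float = 0.0
    # Hoehn & Yahr staging thresholds on latent time (yr) and stage jitter
    hy_thresholds: tuple[float, ...] = (0.0, 2.0, 4.0, 6.5, 9.0, 11.5, 14.0)
    hy_jitter_sd: float = 0.5
    clip_scores: bool = False
    score_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_SIM_RANGES))
    date_origin: str = "2016-01-01"

    def __post_init__(self) -> None:
        if not self.gait:
            base = _base_gait()
            self.gait = {
                task: {name: replace(p, a=p.a * _TASK_LEVEL.get(task, 1.0))
                       for name, p in base.items()}
                for task in self.tasks
            }

    @classmethod
    def lux_like(cls, **overrides) -> "SimConfig":
        return cls(**{"template": "lux_like", **overrides})

    @classmethod
    def erl_like(cls, **overrides) -> "SimConfig":
        defaults = dict(
            template="erl_like", n_patients=264, n_gait_patients=178,
            outcomes=dict(_ERL_OUTCOMES),
            visits_mean=12.08, visits_sd=9.12, spacing="lognormal",
            max_followup_years=11.0,
            age_mean=57.1, age_sd=9.3,
            duration_shape=1.35, duration_scale=3.93,
            p_male=0.62, tasks=("TUG", "W2x10", "W4x10"),
            gait_sessions_mean=2.84, gait_sessions_sd=2.37,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def with_null_task(self, task: str) -> "SimConfig":
        """Return a copy where ``task`` carries no disease signal (b=c=0)."""
        if task not in self.gait:
            raise ConfigError(f"unknown task {task!r}")
        gait = {t: dict(fs) for t, fs in self.gait.items()}
        gait[task] = {n: replace(p, b=0.0, c=0.0) for n, p in gait[task].items()}
        cfg = replace(self, gait=gait)
        return cfg

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.template not in ("lux_like", "erl_like"):
            raise ConfigError(f"unknown template {self.template!r}")
        sds = [self.sigma_delta, self.visits_sd, self.spacing_jitter,
               self.gap_log_sd, self.age_sd, self.hy_jitter_sd,
               self.gait_sessions_sd]
        sds += [p.sigma for p in self.outcomes.values()]
        sds += [p.tau0 for p in self.outcomes.values()]
        sds += [p.tau1 for p in self.outcomes.values()]
        for task in self.gait.values():
            sds += [p.patient_sd for p in task.values()]
            sds += [p.noise_sd for p in task.values()]
        if any(s < 0 for s in sds):
            raise ConfigError("all standard deviations must be >= 0")
        if any(abs(p.rho) >= 1 for p in self.outcomes.values()):
            raise ConfigError("random-effect correlations must lie in (-1, 1)")
        thr = np.asarray(self.hy_thresholds, float)
        if len(thr) != len(HY_STAGES) - 1 or np.any(np.diff(thr) <= 0):
            raise ConfigError("hy_thresholds must be 7 strictly increasing values")
        if not self.outcomes:
            raise ConfigError("at least one outcome is required")
        if self.gait and self.n_gait_patients > 0 \
                and self.gait_target_outcome not in self.outcomes:
            raise ConfigError(
                f"gait_target_outcome {self.gait_target_outcome!r} "
                "is not a configured outcome")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        d["hy_thresholds"] = list(self.hy_thresholds)
        return d


@dataclass
class GroundTruth:
    """Generative truth of a simulated cohort, for recovery tests.

    ``patients``: one row per patient with ``delta`` and per-outcome
    ``alpha0_<k>`` / ``alpha1_<k>``; ``visits``: realized (patient, date, t);
    ``gait_effects``: per-patient feature offsets shared across tasks.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    gait_effects: pd.DataFrame

    def delta(self) -> pd.Series:
        return self.patients.set_index("patient_id")["delta"]

    def alpha1(self, outcome: str) -> pd.Series:
        return self.patients.set_index("patient_id")[f"alpha1_{outcome}"]

    def to_json(self, path) -> None:
        payload = {
            "patients": self.patients.to_dict(orient="list"),
            "visits": {
                **self.visits.drop(columns="visit_date").to_dict(orient="list"),
                "visit_date": self.visits["visit_date"].astype(str).tolist(),
            },
            "gait_effects": self.gait_effects.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _visit_times(cfg: SimConfig, rng: np.random.Generator,
                 t0: float) -> np.ndarray:
    n = int(np.clip(np.round(rng.normal(cfg.visits_mean, cfg.visits_sd)),
                    cfg.visits_min, cfg.visits_max))
    if cfg.spacing == "annual":
        gaps = np.maximum(rng.normal(1.0, cfg.spacing_jitter, n - 1), 0.3)
    elif cfg.spacing == "lognormal":
        days = rng.lognormal(np.log(cfg.gap_median_days), cfg.gap_log_sd, n - 1)
        gaps = np.maximum(days, cfg.min_gap_days) / 365.25
    else:
        raise ConfigError(f"unknown spacing {cfg.spacing!r}")
    times = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
    # the study's observation window caps follow-up; always keep the first
    # two visits so every patient stays longitudinally usable
    keep = times <= t0 + cfg.max_followup_years
    keep[: min(2, len(times))] = True
    return times[keep]


def simulate_cohort(config: SimConfig, seed: int) -> tuple[Cohort, GroundTruth]:
    """Generate the clinical part of a synthetic cohort plus ground truth.

    Identical (config, seed) pairs give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    outs = config.outcomes
    origin = pd.Timestamp(config.date_origin)

    pat_rows, visit_rows, clin_rows = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        age = rng.normal(config.age_mean, config.age_sd)
        sex = "M" if rng.random() < config.p_male else "F"
        t0 = rng.gamma(config.duration_shape, config.duration_scale)
        delta = rng.normal(0.0, config.sigma_delta)
        alphas = {}
        for name, p in outs.items():
            cov = np.array([[p.tau0 ** 2, p.rho * p.tau0 * p.tau1],
                            [p.rho * p.tau0 * p.tau1, p.tau1 ** 2]])
            a0, a1 = rng.multivariate_normal([0.0, 0.0], cov)
            alphas[name] = (a0, a1)
        times = _visit_times(config, rng, t0)
        base_date = origin + pd.Timedelta(days=float(rng.integers(0, 1461)))
        male = 1.0 if sex == "M" else 0.0
        for t in times:
            date = base_date + pd.Timedelta(days=round((t - t0) * 365.25))
            med = float(rng.random() < config.p_med_on)
            row = {"patient_id": pid, "visit_date": date,
                   "years_since_diagnosis": float(t),
                   "age_at_diagnosis": float(age), "sex": sex, "med_on": med}
            for name, p in outs.items():
                a0, a1 = alphas[name]
                y = (p.intercept + p.beta_age * (age - 60.0) + p.beta_sex * male
                     + p.beta_med * med + p.gamma * (t + delta)
                     + a0 + a1 * t + rng.normal(0.0, p.sigma))
                if config.clip_scores and name in config.score_ranges:
                    lo, hi = config.score_ranges[name]
                    y = float(np.clip(y, lo, hi))
                row[name] = float(y)
            clin_rows.append(row)
            visit_rows.append({"patient_id": pid, "visit_date": date,
                               "t": float(t)})
        prow = {"patient_id": pid, "delta": float(delta),
                "age_at_diagnosis": float(age), "sex": sex, "t0": float(t0)}
        for name, (a0, a1) in alphas.items():
            prow[f"alpha0_{name}"] = float(a0)
            prow[f"alpha1_{name}"] = float(a1)
        pat_rows.append(prow)

    patients = pd.DataFrame(pat_rows)
    visits = pd.DataFrame(visit_rows)
    clinical = pd.DataFrame(clin_rows)

    # gait-feature patient offsets, shared across tasks
    feat_names = sorted({f for task in config.gait.values() for f in task})
    eff = {f: [] for f in feat_names}
    sds = {f: max(ls.patient_sd for task in config.gait.values()
                  for n, ls in task.items() if n == f)
           for f in feat_names}
    for _ in range(config.n_patients):
        for f in feat_names:
            eff[f].append(float(rng.normal(0.0, sds[f])))
    gait_effects = pd.DataFrame({"patient_id": patients["patient_id"], **eff})

    truth = GroundTruth(patients=patients, visits=visits,
                        gait_effects=gait_effects)
    hy_seed = int(rng.integers(0, 2 ** 31))
    clinical["hy_stage"] = assign_hy(truth, list(config.hy_thresholds),
                                     config.hy_jitter_sd, hy_seed).to_numpy()

    ranges = {k: config.score_ranges.get(k, (-np.inf, np.inf)) for k in outs}
    cohort = Cohort(clinical=clinical, label=config.template,
                    score_ranges=ranges,
                    meta={"seed": int(seed), "template": config.template})
    return cohort, truth


def assign_hy(truth: GroundTruth, thresholds: list[float], jitter_sd: float,
              seed: int) -> pd.Series:
    """Ordinal-bin jittered latent time into Hoehn & Yahr stages.

    Latent time below the first threshold maps to stage 0; each subsequent
    interval maps to the next stage of {0, 1, 1.5, 2, 2.5, 3, 4, 5}.
    """
    thr = np.asarray(thresholds, float)
    if len(thr) != len(HY_STAGES) - 1 or np.any(np.diff(thr) <= 0):
        raise ConfigError("thresholds must be 7 strictly increasing values")
    rng = np.random.default_rng(seed)
    delta = truth.delta()
    latent = truth.visits["t"].to_numpy() + \
        delta.loc[truth.visits["patient_id"]].to_numpy()
    jitter = rng.normal(0.0, jitter_sd, len(latent)) if jitter_sd > 0 else 0.0
    idx = np.searchsorted(thr, latent + jitter, side="right")
    stages = np.asarray(HY_STAGES, float)[idx]
    return pd.Series(stages, index=truth.visits.index, name="hy_stage")


def simulate_gait_sessions(cohort: Cohort, truth: GroundTruth,
                           config: SimConfig, seed: int) -> pd.DataFrame:
    """Generate task-level gait sessions on (a subset of) clinical dates.

    ``lux_like`` emits exactly one gait date per gait-subset patient;
    ``erl_like`` draws a per-patient session count (truncated >= 1).  Gait
    dates coincide with clinical visit dates, matching a same-day clinical
    assessment protocol.  Stance/stride are drawn from their loadings and
    swing time is their difference, keeping the gait phases consistent.
    """
    config.validate()
    for task, feats in config.gait.items():
        for f in feats:
            if f not in truth.gait_effects.columns:
                raise ConfigError(f"feature {f!r} has no patient effects")
    rng = np.random.default_rng(seed)
    delta = truth.delta()
    a1 = truth.alpha1(config.gait_target_outcome)
    eff = truth.gait_effects.set_index("patient_id")

    pids = truth.patients["patient_id"].tolist()
    gait_pids = pids[: min(config.n_gait_patients, len(pids))]
    rows = []
    for pid in gait_pids:
        pvis = truth.visits[truth.visits["patient_id"] == pid]
        n_avail = len(pvis)
        if config.template == "erl_like" or config.gait_sessions_sd > 0:
            m = int(np.round(rng.normal(config.gait_sessions_mean,
                                        config.gait_sessions_sd)))
            m = int(np.clip(m, 1, n_avail))
            chosen = np.sort(rng.choice(n_avail, size=m, replace=False))
        else:
            chosen = np.array([rng.integers(0, n_avail)])
        for j in chosen:
            vrow = pvis.iloc[j]
            lt = float(vrow["t"]) + float(delta[pid])
            for task, feats in config.gait.items():
                values = {}
                for name, p in feats.items():
                    if name == "swing_time" and {"stride_time", "stance_time"} \
                            <= set(feats):
                        continue
                    values[name] = (p.a + p.b * lt + p.c * float(a1[pid])
                                    + float(eff.loc[pid, name])
                                    + rng.normal(0.0, p.noise_sd))
                if "swing_time" in feats and {"stride_time", "stance_time"} \
                        <= set(feats):
                    # swing carries its own measurement noise, clipped so
                    # the phases stay consistent (|st+sw-str| <= 5% stride)
                    bound = 0.8 * 0.05 * abs(values["stride_time"])
                    noise = float(np.clip(
                        rng.normal(0.0, feats["swing_time"].noise_sd),
                        -bound, bound))
                    values["swing_time"] = (values["stride_time"]
                                            - values["stance_time"] + noise)
                rows.append({"patient_id": pid,
                             "visit_date": vrow["visit_date"],
                             "task": task, **values})
    return pd.DataFrame(rows)


def recovery_benchmark_config(n_patients: int = 200, n_visits: int = 5,
                              sigma_delta: float = 3.0) -> SimConfig:
    """Three-outcome benchmark for time-shift/slope recovery experiments.

    All three scores load substantially on latent disease time relative to
    their residual intercept heterogeneity, the regime in which a shared
    time shift is identified from the cross-outcome covariance.  Fixed
    regular visits isolate estimator behaviour from the visit process.
    """
    cfg = SimConfig.lux_like(
        n_patients=n_patients, n_gait_patients=0,
        visits_mean=float(n_visits), visits_sd=0.0,
        sigma_delta=sigma_delta)
    cfg.outcomes = {
        "updrs3": OutcomeParams(20.5, 2.0, 3.0, 4.0, 1.00, 0.2, 0.10, 1.0, -3.0),
        "updrs2": OutcomeParams(6.5, 1.2, 2.0, 2.0, 0.40, 0.2, 0.05, 0.0, -0.5),
        "axial": OutcomeParams(2.8, 0.7, 1.2, 1.2, 0.35, 0.2, 0.02, 0.2, -0.5),
    }
    return cfg


def simulate_full(config: SimConfig, seed: int,
                  ) -> tuple[Cohort, GroundTruth]:
    """Convenience wrapper: clinical cohort plus attached gait sessions."""
    ss = np.random.SeedSequence(seed).spawn(2)
    s_clin = int(ss[0].generate_state(1)[0] % (2 ** 31))
    s_gait = int(ss[1].generate_state(1)[0] % (2 ** 31))
    cohort, truth = simulate_cohort(config, s_clin)
    gait = simulate_gait_sessions(cohort, truth, config, s_gait)
    cohort = Cohort(clinical=cohort.clinical, gait=gait, label=cohort.label,
                    score_ranges=cohort.score_ranges, meta=cohort.meta)
    return cohort, truth
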