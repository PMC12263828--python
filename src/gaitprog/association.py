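"""Association of gait feature sets with clinical scores, slopes and stage.

Each test compares a linear (mixed) model containing a gait feature set
against a null model with only the adjustment covariates, via a likelihood
ratio test; the resulting p-values over a whole cohort scan are adjusted
with the Benjamini-Yekutieli step-up procedure, which controls the FDR
under arbitrary dependence between tests.

Covariate rules by outcome family:

``latent_time``
    Response is the latent disease time at the gait date (t + delta_hat);
    adjustment covariates are age at diagnosis and sex.
``score``
    Response is the clinical score at the matched visit; the single
    adjustment covariate is the latent disease time at that visit (age and
    sex are *not* re-added: the latent time already comes from a model
    adjusted for them).
``slope``
    Response is the patient's random slope alpha1 for the outcome;
    adjustment covariate is again the latent disease time.

A patient-specific random intercept is used when gait sessions repeat
within patients (Erlangen-style designs); all fits are ML so nested LR
tests are valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import TASKS, GaitSchema

__all__ = [
    "FeatureSet", "AssocOutcomeSpec", "AssocFit", "build_feature_sets",
    "default_outcome_specs", "assemble_design", "fit_assoc", "lr_test",
    "by_adjust", "association_scan",
]


@dataclass(frozen=True)
class FeatureSet:
    """A named list of matched-table feature columns."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self):
        if not self.columns:
            raise ValueError(f"feature set {self.name!r} has no columns")


@dataclass(frozen=True)
class AssocOutcomeSpec:
    """One modelled outcome: family, name and random-intercept flag."""

    family: str                 # 'score' | 'slope' | 'latent_time'
    outcome: str
    random_intercept: bool = False

    def __post_init__(self):
        if self.family not in ("score", "slope", "latent_time"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def label(self) -> str:
        return f"{self.family}:{self.outcome}"


def build_feature_sets(schema: GaitSchema, tasks: list[str],
                       include_single: bool = False,
                       available: list[str] | None = None
                       ) -> list[FeatureSet]:
    """allGait, one set per task, and optionally one singleton per column.

    ``available`` restricts columns to those actually present in a matched
    table (tasks do not all export every feature).
    """
    unknown = [t for t in tasks if t not in TASKS]
    if unknown:
        raise ValueError(f"unknown task(s): {unknown}; valid: {list(TASKS)}")
    sets: list[FeatureSet] = []
    per_task: dict[str, list[str]] = {}
    for task in tasks:
        cols = [f"{task}__{f}" for f in schema.names]
        if available is not None:
            cols = [c for c in cols if c in available]
        per_task[task] = cols
    all_cols = tuple(c for task in tasks for c in per_task[task])
    sets.append(FeatureSet("allGait", all_cols))
    for task in tasks:
        sets.append(FeatureSet(task, tuple(per_task[task])))
    if include_single:
        for task in tasks:
            for c in per_task[task]:
                sets.append(FeatureSet(f"single:{c}", (c,)))
    return sets


def default_outcome_specs(template: str) -> list[AssocOutcomeSpec]:
    """The score/slope/latent-time scan grid of each cohort design."""
    if template == "lux_like":
        scores = ["axial", "pigd", "td", "updrs1", "updrs2", "updrs3"]
        ri = False
    elif template == "erl_like":
        scores = ["updrs3", "axial"]
        ri = True
    else:
        raise ValueError(f"unknown template {template!r}")
    specs = [AssocOutcomeSpec("score", s, ri) for s in scores]
    specs += [AssocOutcomeSpec("slope", s, ri) for s in scores]
    specs.append(AssocOutcomeSpec("latent_time", "latent_time", ri))
    return specs


def assemble_design(matched: pd.DataFrame, fit, spec: AssocOutcomeSpec
                    ) -> pd.DataFrame:
    """Build the model frame (response + adjustment covariates) for a spec.

    ``fit`` must expose ``delta`` (Series by patient) and ``alpha1``
    (DataFrame patient x outcome), as :class:`~gaitprog.ltjmm.LTJMMResults`
    does.  The returned frame carries its response/covariate roles in
    ``frame.attrs``; feature columns are passed through untouched.
    """
    missing = set(matched["patient_id"]) - set(fit.delta.index)
    if missing:
        raise KeyError(f"matched patients absent from fit: {sorted(missing)[:5]}")
    frame = matched.copy()
    latent = frame["years_since_diagnosis"].to_numpy(float) + \
        fit.delta.loc[frame["patient_id"]].to_numpy(float)
    frame["latent_time"] = latent
    if spec.family == "latent_time":
        frame["_response"] = latent
        covars = ["age_at_diagnosis", "sex_male"]
        frame["sex_male"] = frame["sex"].astype(str).str.upper().eq("M") \
            .astype(float)
    elif spec.family == "score":
        if spec.outcome not in frame.columns:
            raise KeyError(f"score {spec.outcome!r} not in matched table")
        frame["_response"] = frame[spec.outcome].astype(float)
        covars = ["latent_time"]
    else:  # slope
        if spec.outcome not in fit.alpha1.columns:
            raise KeyError(f"outcome {spec.outcome!r} absent from fit")
        frame["_response"] = fit.alpha1[spec.outcome] \
            .loc[frame["patient_id"]].to_numpy(float)
        covars = ["latent_time"]
    frame.attrs["response"] = "_response"
    frame.attrs["covariates"] = covars
    frame.attrs["patient_col"] = "patient_id"
    frame.attrs["spec"] = spec
    return frame


@dataclass
class AssocFit:
    """A fitted association model: likelihood, coefficients, bookkeeping."""

    loglik: float
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    n_patients: int
    n_fixed: int
    feature_names: tuple[str, ...]
    rows: tuple
    random_intercept: bool
    response_digest: str = ""

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "p": self.pvalues})


def _design_matrix(frame: pd.DataFrame, features: tuple[str, ...]):
    covars = frame.attrs["covariates"]
    y = frame[frame.attrs["response"]].to_numpy(float)
    cols, names = [np.ones(len(frame))], ["const"]
    for c in covars:
        cols.append(frame[c].to_numpy(float))
        names.append(c)
    for c in features:
        v = frame[c].to_numpy(float)
        sd = v.std(ddof=0)
        if not np.isfinite(sd) or sd <= 1e-12 * (np.abs(v).mean() + 1.0):
            raise ValueError(f"zero-variance feature column {c!r}")
        cols.append((v - v.mean()) / sd)   # z-score within analysis sample
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * abs(R).max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return y, X, names


def fit_assoc(frame: pd.DataFrame, features=(),
              random_intercept: bool = False) -> AssocFit:
    """ML-fit the association model for one feature set.

    Rows with a missing value in the response, a covariate or an active
    feature are dropped listwise.  Features are z-scored within the
    analysis sample so coefficients are comparable across units.
    """
    if isinstance(features, FeatureSet):
        features = features.columns
    features = tuple(features)
    used = [frame.attrs["response"]] + list(frame.attrs["covariates"]) \
        + list(features)
    sub = frame.dropna(subset=[c for c in used if c in frame.columns])
    if len(sub) < 10:
        raise ValueError(f"need >= 10 complete rows, have {len(sub)}")
    y, X, names = _design_matrix(sub, features)
    groups = sub[frame.attrs["patient_col"]].to_numpy()
    import hashlib
    digest = hashlib.sha256(np.ascontiguousarray(y).tobytes()).hexdigest()
    if random_intercept:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        params = pd.Series(res.fe_params, index=names)
        bse = pd.Series(np.asarray(res.bse_fe), index=names)
        pvals = pd.Series(np.asarray(res.pvalues)[:len(names)], index=names)
    else:
        res = sm.OLS(y, X).fit()
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        pvals = pd.Series(res.pvalues, index=names)
    llf = float(res.llf)
    if not np.isfinite(llf):
        # degenerate perfect fit: floor the residual variance so the ML
        # log-likelihood stays finite (and enormous)
        n = len(y)
        llf = float(-n / 2 * (np.log(2 * np.pi * 1e-30) + 1))
    return AssocFit(loglik=llf, params=params, bse=bse,
                    pvalues=pvals, nobs=len(sub),
                    n_patients=len(pd.unique(groups)), n_fixed=X.shape[1],
                    feature_names=features, rows=tuple(sub.index),
                    random_intercept=random_intercept,
                    response_digest=digest)


def lr_test(full: AssocFit, null: AssocFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits on identical rows."""
    if full.rows != null.rows or full.response_digest != null.response_digest:
        raise ValueError("full and null models were fitted on different rows")
    if full.random_intercept != null.random_intercept:
        raise ValueError("full and null differ in random-effects structure")
    if not set(null.params.index) <= set(full.params.index):
        raise ValueError("null model is not nested in the full model")
    df = full.n_fixed - null.n_fixed
    if df < 1:
        raise ValueError("full model adds no parameters over the null")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return stat, df, float(stats.chi2.sf(stat, df))


def by_adjust(p_raw) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values, in input order.

    p_adj_(i) = min_{j >= i} min(1, m * c(m) * p_(j) / j) with the harmonic
    factor c(m) = sum_{l=1..m} 1/l.
    """
    p = np.asarray(p_raw, float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    c = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def association_scan(matched: pd.DataFrame, fit,
                     specs: list[AssocOutcomeSpec],
                     feature_sets: list[FeatureSet]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full (outcome spec x feature set) LR-test grid.

    BY adjustment is applied over all successful cells of the scan (the
    reporting unit is one adjusted table per cohort).  Returns the scan
    table and a long coefficient table of the full models.  Cells whose
    model fails to fit are marked ``failed`` and excluded from adjustment.
    """
    rows, coef_rows = [], []
    for spec in specs:
        frame = assemble_design(matched, fit, spec)
        for fs in feature_sets:
            try:
                fullfit = fit_assoc(frame, fs, spec.random_intercept)
                nullframe = frame.loc[list(fullfit.rows)]
                nullfit = fit_assoc(nullframe, (), spec.random_intercept)
                stat, df, p = lr_test(fullfit, nullfit)
            except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
                rows.append({"outcome": spec.outcome, "family": spec.family,
                             "feature_set": fs.name, "failed": str(exc)})
                continue
            rows.append({"outcome": spec.outcome, "family": spec.family,
                         "feature_set": fs.name, "lr_stat": stat, "df": df,
                         "p_raw": p, "n_rows": fullfit.nobs,
                         "n_patients": fullfit.n_patients, "failed": ""})
            for feat in fs.columns:
                coef_rows.append({
                    "outcome": spec.outcome, "family": spec.family,
                    "feature_set": fs.name, "feature": feat,
                    "estimate": fullfit.params[feat],
                    "se": fullfit.bse[feat], "p": fullfit.pvalues[feat]})
    scan = pd.DataFrame(rows)
    ok = scan["failed"] == ""
    scan["p_adj"] = np.nan
    if ok.any():
        scan.loc[ok, "p_adj"] = by_adjust(scan.loc[ok, "p_raw"].to_numpy())
    scan["flag_sig05"] = scan["p_adj"] < 0.05
    scan["flag_sig10"] = scan["p_adj"] < 0.10
    return scan, pd.DataFrame(coef_rows)
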