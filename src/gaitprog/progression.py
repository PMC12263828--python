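"""Nested cross-validated prediction of progression slopes from gait.

The target is the LTJMM random slope of a motor outcome — the patient's
individual progression rate.  Learners are tuned by randomized search in an
inner K-fold on each outer training split only (no leakage into the outer
test fold), and evaluated as out-of-sample R^2 = 1 - SSE/SST per outer test
fold over repeated outer K-folds.  A gait model is compared against an
age+sex baseline with a paired two-sided Wilcoxon signed-rank test on the
fold-level R^2 values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold, RandomizedSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["LearnerSpec", "CVResult", "AttributionReport",
           "build_progression_dataset", "nested_cv", "compare_r2",
           "attribute"]

_MAX_SHAPLEY_FEATURES = 15


def _default_space(kind: str) -> dict:
    if kind == "random_forest":
        return {"n_estimators": stats.randint(100, 1000),
                "max_depth": [2, 4, 8, 16, None],
                "min_samples_leaf": stats.randint(1, 11)}
    if kind == "gradient_boosting":
        return {"n_estimators": stats.randint(50, 500),
                "learning_rate": stats.loguniform(0.01, 0.3),
                "max_depth": stats.randint(2, 7)}
    if kind == "l1_linear":
        return {"lasso__alpha": stats.loguniform(1e-3, 1e2)}
    raise ValueError(f"unknown learner kind {kind!r}")


@dataclass
class LearnerSpec:
    """A learner kind plus its randomized hyperparameter search."""

    kind: str = "random_forest"
    space: dict | None = None
    n_candidates: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.space is None:
            self.space = _default_space(self.kind)
        if not self.space:
            raise ValueError("hyperparameter space must be non-empty")

    def make_estimator(self):
        if self.kind == "random_forest":
            return RandomForestRegressor(random_state=self.seed)
        if self.kind == "gradient_boosting":
            return GradientBoostingRegressor(random_state=self.seed)
        if self.kind == "l1_linear":
            return Pipeline([("scale", StandardScaler()),
                             ("lasso", Lasso(max_iter=20000,
                                             random_state=self.seed))])
        raise ValueError(f"unknown learner kind {self.kind!r}")


def build_progression_dataset(fit, sessions: pd.DataFrame, outcome: str,
                              visit_selection: str = "first",
                              include_age_sex: bool = True
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """One predictor row per patient from their first (and second) gait visit.

    ``sessions`` is a wide per-(patient, gait date) table with
    ``<task>__<feature>`` columns, as produced by
    :func:`~gaitprog.cohort.match_gait_to_clinical`.  For
    ``visit_selection="first_two"`` the two visit blocks are concatenated
    with ``__v1``/``__v2`` suffixes; patients with fewer than two gait
    visits are excluded (count recorded in ``X.attrs['n_excluded']``).
    The target is the patient's random slope for ``outcome``.
    """
    if visit_selection not in ("first", "first_two"):
        raise ValueError("visit_selection must be 'first' or 'first_two'")
    if outcome not in fit.alpha1.columns:
        raise KeyError(f"outcome {outcome!r} absent from fit")
    feat_cols = [c for c in sessions.columns if "__" in c]
    date_col = "gait_date" if "gait_date" in sessions.columns else "visit_date"
    sess = sessions.sort_values(["patient_id", date_col])

    rows, idx = [], []
    n_excluded_visits = n_excluded_fit = 0
    for pid, sub in sess.groupby("patient_id", sort=False):
        if pid not in fit.alpha1.index:
            n_excluded_fit += 1
            continue
        if visit_selection == "first_two" and len(sub) < 2:
            n_excluded_visits += 1
            continue
        row = {}
        if visit_selection == "first":
            row.update({c: sub.iloc[0][c] for c in feat_cols})
        else:
            row.update({f"{c}__v1": sub.iloc[0][c] for c in feat_cols})
            row.update({f"{c}__v2": sub.iloc[1][c] for c in feat_cols})
        if include_age_sex:
            row["age_at_diagnosis"] = float(sub.iloc[0]["age_at_diagnosis"])
            row["sex_male"] = 1.0 if str(sub.iloc[0]["sex"]).upper() == "M" \
                else 0.0
        rows.append(row)
        idx.append(pid)
    X = pd.DataFrame(rows, index=idx)
    X.attrs["n_excluded"] = {"too_few_visits": n_excluded_visits,
                             "absent_from_fit": n_excluded_fit}
    y = fit.alpha1[outcome].loc[idx].rename("alpha1")
    return X, y


@dataclass
class CVResult:
    """Fold-level out-of-sample R^2 of one learner/feature configuration."""

    scores: pd.DataFrame          # repeat, fold, r2
    learner: str
    feature_set: str = ""
    visit_selection: str = ""
    chosen_params: list = field(default_factory=list)
    fold_signature: tuple = ()

    @property
    def r2(self) -> np.ndarray:
        return self.scores["r2"].to_numpy()

    def summary(self) -> dict:
        q = np.percentile(self.r2, [25, 50, 75])
        return {"median_r2": float(q[1]), "iqr": (float(q[0]), float(q[2])),
                "n_scores": len(self.r2)}


def _outer_splits(n: int, outer_folds: int, repeats: int, seed: int):
    for rep in range(repeats):
        kf = KFold(n_splits=outer_folds, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(kf.split(np.arange(n))):
            yield rep, fold, tr, te


def nested_cv(X, y, learner: LearnerSpec, outer_folds: int = 5,
              repeats: int = 10, inner_folds: int = 5, seed: int = 0,
              feature_set: str = "", visit_selection: str = "") -> CVResult:
    """Repeated nested cross-validation, fully seeded.

    Hyperparameters are tuned by randomized search only on the inner folds
    of each outer training split; R^2 = 1 - SSE/SST is computed on each
    outer test fold (it may be negative).
    """
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float)
    n = len(ya)
    if n < 2 * outer_folds:
        raise ValueError(f"need at least {2 * outer_folds} samples, have {n}")
    if ya.std(ddof=0) == 0:
        raise ValueError("target has zero variance")
    rows, chosen, signature = [], [], []
    for rep, fold, tr, te in _outer_splits(n, outer_folds, repeats, seed):
        search = RandomizedSearchCV(
            learner.make_estimator(), learner.space,
            n_iter=learner.n_candidates,
            cv=KFold(inner_folds, shuffle=True, random_state=seed + 1000 + rep),
            random_state=seed + 2000 + rep, scoring="r2", n_jobs=1,
            error_score="raise")
        search.fit(Xa[tr], ya[tr])
        pred = search.best_estimator_.predict(Xa[te])
        sse = float(np.sum((ya[te] - pred) ** 2))
        sst = float(np.sum((ya[te] - ya[te].mean()) ** 2))
        rows.append({"repeat": rep, "fold": fold, "r2": 1.0 - sse / sst})
        chosen.append({"repeat": rep, "fold": fold, **search.best_params_})
        signature.append((rep, fold, tuple(te.tolist())))
    return CVResult(scores=pd.DataFrame(rows), learner=learner.kind,
                    feature_set=feature_set, visit_selection=visit_selection,
                    chosen_params=chosen, fold_signature=tuple(signature))


def compare_r2(cv_a: CVResult, cv_b: CVResult) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test on fold-level R^2.

    Both results must come from the same fold structure (same seeds);
    zero differences are dropped per the Wilcoxon convention, and a fully
    tied comparison returns p = 1.
    """
    if cv_a.fold_signature != cv_b.fold_signature:
        raise ValueError("CV results are not paired (different fold splits)")
    diff = cv_a.r2 - cv_b.r2
    if np.all(diff == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class AttributionReport:
    """Per-sample additive attributions (or global importances)."""

    method: str
    ranking: pd.DataFrame               # feature, mean_abs_attribution, rank
    values: np.ndarray | None = None    # (n_samples, n_features) if additive
    baseline: float = np.nan

    def top_feature(self) -> str:
        return self.ranking.iloc[0]["feature"]


def _shapley_exact(model, X: pd.DataFrame, background: np.ndarray
                   ) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values by coalition enumeration.

    The value of coalition S for sample x is the mean prediction with the
    columns in S taken from x and the rest from the background rows.  The
    attributions are exactly additive: they sum to f(x) minus the mean
    background prediction.
    """
    Xa = np.asarray(X, float)
    n, M = Xa.shape
    B = background.shape[0]
    from math import factorial

    v = {}
    for size in range(M + 1):
        for S in itertools.combinations(range(M), size):
            mat = np.repeat(background[None, :, :], n, axis=0)  # (n, B, M)
            for j in S:
                mat[:, :, j] = Xa[:, j][:, None]
            frame = pd.DataFrame(mat.reshape(n * B, M), columns=X.columns)
            v[S] = model.predict(frame).reshape(n, B).mean(axis=1)
    phi = np.zeros((n, M))
    for S in v:
        for j in range(M):
            if j in S:
                continue
            w = factorial(len(S)) * factorial(M - len(S) - 1) / factorial(M)
            phi[:, j] += w * (v[tuple(sorted(S + (j,)))] - v[S])
    return phi, float(v[()].mean())


def attribute(model, X: pd.DataFrame, method: str = "shapley_tree",
              background_size: int = 20, seed: int = 0) -> AttributionReport:
    """Feature attribution for a fitted regressor.

    ``shapley_tree`` computes exact interventional Shapley values by full
    coalition enumeration against a background sample — feasible up to
    15 features; beyond that an error suggests ``permutation``, which
    returns global importances as the mean |prediction change| under
    column permutation.
    """
    feats = list(X.columns)
    rng = np.random.default_rng(seed)
    if method == "shapley_tree":
        if len(feats) > _MAX_SHAPLEY_FEATURES:
            raise ValueError(
                f"{len(feats)} features exceed the exact-Shapley limit "
                f"({_MAX_SHAPLEY_FEATURES}); use method='permutation'")
        Xa = np.asarray(X, float)
        bidx = rng.choice(len(Xa), size=min(background_size, len(Xa)),
                          replace=False)
        phi, baseline = _shapley_exact(model, X, Xa[bidx])
        mean_abs = np.abs(phi).mean(axis=0)
        ranking = (pd.DataFrame({"feature": feats,
                                 "mean_abs_attribution": mean_abs})
                   .sort_values("mean_abs_attribution", ascending=False)
                   .reset_index(drop=True))
        ranking["rank"] = np.arange(1, len(feats) + 1)
        return AttributionReport(method=method, ranking=ranking, values=phi,
                                 baseline=baseline)
    if method == "permutation":
        base_pred = model.predict(X)
        imps = []
        for j, col in enumerate(feats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            imps.append(float(np.abs(model.predict(Xp) - base_pred).mean()))
        ranking = (pd.DataFrame({"feature": feats,
                                 "mean_abs_attribution": imps})
                   .sort_values("mean_abs_attribution", ascending=False)
                   .reset_index(drop=True))
        ranking["rank"] = np.arange(1, len(feats) + 1)
        return AttributionReport(method=method, ranking=ranking)
    raise ValueError(f"unknown attribution method {method!r}; "
                     "use 'shapley_tree' or 'permutation'")
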