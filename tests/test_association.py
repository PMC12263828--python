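"""Feature-set association: designs, LR tests, BY adjustment, scan grid."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gaitprog.association import (AssocOutcomeSpec, FeatureSet,
                                  assemble_design, association_scan,
                                  build_feature_sets, by_adjust,
                                  default_outcome_specs, fit_assoc, lr_test)
from gaitprog.cohort import GaitSchema


class TestFeatureSets:
    def test_lux_task_sets(self):
        sets = build_feature_sets(GaitSchema(),
                                  ["Count", "Tray", "TUG", "Turn"])
        assert [s.name for s in sets] == \
            ["allGait", "Count", "Tray", "TUG", "Turn"]
        assert len(sets[0].columns) == 4 * 7

    def test_erl_task_sets(self):
        sets = build_feature_sets(GaitSchema(), ["TUG", "W2x10", "W4x10"])
        assert [s.name for s in sets] == ["allGait", "TUG", "W2x10", "W4x10"]

    def test_single_counting_rule(self):
        sets = build_feature_sets(GaitSchema(), ["TUG", "Turn"],
                                  include_single=True)
        assert len(sets) == 1 + 2 + 14

    def test_unknown_task(self):
        with pytest.raises(ValueError, match="unknown task"):
            build_feature_sets(GaitSchema(), ["Sprint"])

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="no columns"):
            FeatureSet("empty", ())


def _toy_matched(n=60, seed=0, n_per_patient=1):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for j in range(n_per_patient):
            rows.append({
                "patient_id": f"P{i:03d}",
                "years_since_diagnosis": rng.uniform(0, 8),
                "age_at_diagnosis": rng.normal(60, 8),
                "sex": "M" if rng.random() < 0.6 else "F",
                "axial": rng.normal(6, 3),
                "TUG__gait_speed": rng.normal(1.2, 0.15),
                "TUG__stride_length": rng.normal(1.3, 0.15),
            })
    return pd.DataFrame(rows)


def _toy_fit(matched, seed=1):
    rng = np.random.default_rng(seed)
    pids = pd.unique(matched["patient_id"])
    return SimpleNamespace(
        delta=pd.Series(rng.normal(0, 3, len(pids)), index=pids),
        alpha1=pd.DataFrame({"axial": rng.normal(0, 0.3, len(pids))},
                            index=pids))


class TestAssembleDesign:
    def test_latent_time_family_covariates(self):
        m = _toy_matched()
        fr = assemble_design(m, _toy_fit(m),
                             AssocOutcomeSpec("latent_time", "latent_time"))
        assert fr.attrs["covariates"] == ["age_at_diagnosis", "sex_male"]
        fit = _toy_fit(m)
        np.testing.assert_allclose(
            fr["_response"],
            m["years_since_diagnosis"]
            + fit.delta.loc[m["patient_id"]].to_numpy())

    def test_score_family_uses_latent_time_only(self):
        m = _toy_matched()
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        assert fr.attrs["covariates"] == ["latent_time"]
        np.testing.assert_array_equal(fr["_response"], m["axial"])

    def test_slope_family_maps_alpha1(self):
        m = _toy_matched()
        fit = _toy_fit(m)
        fr = assemble_design(m, fit, AssocOutcomeSpec("slope", "axial"))
        np.testing.assert_allclose(
            fr["_response"], fit.alpha1["axial"].loc[m["patient_id"]])

    def test_unknown_slope_outcome_errors(self):
        m = _toy_matched()
        with pytest.raises(KeyError, match="pigd"):
            assemble_design(m, _toy_fit(m), AssocOutcomeSpec("slope", "pigd"))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            AssocOutcomeSpec("quantile", "axial")


class TestFitAssoc:
    def test_matches_ols_oracle(self):
        """Flag off, one row per patient: closed-form OLS on z-scores."""
        m = _toy_matched(seed=3)
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        feats = ("TUG__gait_speed", "TUG__stride_length")
        fit = fit_assoc(fr, feats, random_intercept=False)
        X = [np.ones(len(fr)), fr["latent_time"].to_numpy()]
        for c in feats:
            v = fr[c].to_numpy()
            X.append((v - v.mean()) / v.std())
        X = np.column_stack(X)
        beta, *_ = np.linalg.lstsq(X, fr["_response"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-6)

    def test_zero_response_gives_zero_coefficients(self):
        m = _toy_matched()
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        fr["_response"] = 0.0
        fit = fit_assoc(fr, ("TUG__gait_speed",), False)
        np.testing.assert_allclose(fit.params, 0.0, atol=1e-10)
        assert np.isfinite(fit.loglik)

    def test_planted_effect_recovered_within_2se(self, rng):
        m = _toy_matched(n=200, seed=5)
        slope_per_sd = 2.0
        z = (m["TUG__gait_speed"] - m["TUG__gait_speed"].mean()) \
            / m["TUG__gait_speed"].std(ddof=0)
        m["axial"] = 6 + slope_per_sd * z + rng.normal(0, 1, len(m))
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        fit = fit_assoc(fr, ("TUG__gait_speed", "TUG__stride_length"), False)
        est, se = fit.params["TUG__gait_speed"], fit.bse["TUG__gait_speed"]
        assert abs(est - slope_per_sd) <= 2 * se and est > 0

    def test_zero_variance_feature_rejected(self):
        m = _toy_matched()
        m["TUG__gait_speed"] = 1.2
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_assoc(fr, ("TUG__gait_speed",), False)

    def test_collinear_columns_named(self):
        m = _toy_matched()
        m["TUG__stride_length"] = 2 * m["TUG__gait_speed"] + 1
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        with pytest.raises(ValueError, match="collinear"):
            fit_assoc(fr, ("TUG__gait_speed", "TUG__stride_length"), False)

    def test_too_few_rows(self):
        m = _toy_matched(n=5)
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        with pytest.raises(ValueError, match=">= 10"):
            fit_assoc(fr, ("TUG__gait_speed",), False)

    def test_mixed_reduces_to_ols_with_null_grouping_structure(self):
        """Random-intercept fit on repeated rows has finite ML likelihood
        and the same fixed-effect signs as OLS."""
        m = _toy_matched(n=40, n_per_patient=3, seed=11)
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        f_mix = fit_assoc(fr, ("TUG__gait_speed",), True)
        f_ols = fit_assoc(fr, ("TUG__gait_speed",), False)
        assert np.isfinite(f_mix.loglik)
        assert f_mix.nobs == f_ols.nobs


class TestLRTest:
    def _fits(self, seed=0, features=("TUG__gait_speed",)):
        m = _toy_matched(seed=seed)
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        full = fit_assoc(fr, features, False)
        null = fit_assoc(fr, (), False)
        return full, null

    def test_identical_models_give_zero_stat(self):
        full, _ = self._fits()
        with pytest.raises(ValueError, match="adds no parameters"):
            lr_test(full, full)
        stat, df, p = lr_test(full, self._fits()[1])
        assert stat >= 0 and df == 1

    def test_df_counts_added_features(self):
        m = _toy_matched()
        fr = assemble_design(m, _toy_fit(m), AssocOutcomeSpec("score", "axial"))
        cols = ("TUG__gait_speed", "TUG__stride_length")
        stat, df, p = lr_test(fit_assoc(fr, cols, False),
                              fit_assoc(fr, (), False))
        assert df == 2

    def test_row_mismatch_rejected(self):
        full, _ = self._fits(seed=0)
        _, null = self._fits(seed=99)
        with pytest.raises(ValueError, match="different rows"):
            lr_test(full, null)

    def test_invariant_to_affine_feature_rescaling(self):
        m = _toy_matched(seed=2)
        fitobj = _toy_fit(m)
        fr1 = assemble_design(m, fitobj, AssocOutcomeSpec("score", "axial"))
        m2 = m.copy()
        m2["TUG__gait_speed"] = 100 * m2["TUG__gait_speed"] - 7
        fr2 = assemble_design(m2, fitobj, AssocOutcomeSpec("score", "axial"))
        s1 = lr_test(fit_assoc(fr1, ("TUG__gait_speed",), False),
                     fit_assoc(fr1, (), False))[0]
        s2 = lr_test(fit_assoc(fr2, ("TUG__gait_speed",), False),
                     fit_assoc(fr2, (), False))[0]
        assert abs(s1 - s2) <= 1e-6


def _by_oracle(p):
    """Independent brute-force BY step-up."""
    p = np.asarray(p, float)
    m = len(p)
    c = sum(1.0 / l for l in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos in range(m):
        j0 = rank_pos + 1
        candidates = [min(1.0, m * c * p[order[k]] / (k + 1))
                      for k in range(rank_pos, m)]
        adj[order[rank_pos]] = min(candidates)
    return adj


class TestBYAdjust:
    def test_single_p_identity(self):
        np.testing.assert_allclose(by_adjust([0.03]), [0.03])

    def test_hand_case(self):
        out = by_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(out, [0.055, 0.055, 0.0733333333],
                                   atol=1e-9)

    def test_matches_bruteforce_and_statsmodels(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            ours = by_adjust(p)
            # agreement with the brute-force oracle to float associativity
            np.testing.assert_allclose(ours, _by_oracle(p), rtol=1e-12,
                                       atol=1e-15)
            np.testing.assert_allclose(
                ours, multipletests(p, method="fdr_by")[1], atol=1e-12)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.all(ours >= bh - 1e-12) and np.all(bh >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            by_adjust([-0.1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20),
           st.integers(min_value=0, max_value=19),
           st.floats(min_value=0.0, max_value=0.5))
    def test_monotone_in_each_raw_p(self, ps, idx, bump):
        """Raising one raw p never lowers any adjusted p."""
        idx = idx % len(ps)
        base = by_adjust(ps)
        raised = list(ps)
        raised[idx] = min(1.0, raised[idx] + bump)
        assert np.all(by_adjust(raised) >= base - 1e-12)


class TestLRCalibration:
    def test_null_type_one_error(self, rng):
        """Empirical LR rejection under the null stays near nominal."""
        n, df_added, reps = 150, 3, 400
        rej = 0
        chi2_crit = stats.chi2.ppf(0.95, df_added)
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            X0 = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
            X1 = np.column_stack([X0, rng.normal(0, 1, (n, df_added))])
            b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
            b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
            ll0 = -n / 2 * np.log(np.sum((y - X0 @ b0) ** 2) / n)
            ll1 = -n / 2 * np.log(np.sum((y - X1 @ b1) ** 2) / n)
            rej += 2 * (ll1 - ll0) > chi2_crit
        assert 0.02 <= rej / reps <= 0.08


def test_scan_grid_shape_and_flags(lux_small):
    """LuxPARK-style scan: 13 outcome rows x 5 feature-set columns."""
    from gaitprog import match_gait_to_clinical
    _, cohort, truth = lux_small
    matched = match_gait_to_clinical(cohort)
    pids = truth.patients["patient_id"]
    fit = SimpleNamespace(
        delta=truth.delta(),
        alpha1=pd.DataFrame(
            {o: truth.patients[f"alpha1_{o}"].to_numpy() for o in
             ("axial", "pigd", "td", "updrs1", "updrs2", "updrs3")},
            index=pids))
    sets = build_feature_sets(GaitSchema(), ["Count", "Tray", "TUG", "Turn"],
                              available=list(matched.columns))
    specs = default_outcome_specs("lux_like")
    assert len(specs) == 13
    scan, coefs = association_scan(matched, fit, specs, sets)
    assert len(scan) == 13 * 5
    assert (scan.loc[scan["failed"] == "", "p_adj"]
            >= scan.loc[scan["failed"] == "", "p_raw"] - 1e-12).all()
    assert set(scan["feature_set"]) == {"allGait", "Count", "Tray", "TUG",
                                        "Turn"}
    # latent time is strongly gait-associated by construction
    lt = scan[(scan["family"] == "latent_time")
              & (scan["feature_set"] == "allGait")]
    assert (lt["p_adj"] < 0.05).all()
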