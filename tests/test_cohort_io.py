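"""Cohort data model: parsing, validation, score construction, matching."""

import numpy as np
import pandas as pd
import pytest

from gaitprog import (Cohort, GaitSchema, compute_axial_score,
                      filter_min_visits, load_clinical, load_gait,
                      match_gait_to_clinical, write_cohort)
from gaitprog.cohort import RowError, SchemaError


def _csv(tmp_path, text, name="clin.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


GOOD = """patient_id,visit_date,years_since_diagnosis,updrs3,hy_stage,med_on,age_at_diagnosis,sex
P1,2020-01-01,1.0,20,1,1,60.5,M
P1,2021-01-01,2.0,24,2,0,60.5,M
P1,2022-01-01,3.0,,2,1,60.5,M
"""


class TestLoadClinical:
    def test_well_formed_file(self, tmp_path):
        cohort = load_clinical(_csv(tmp_path, GOOD))
        assert len(cohort.clinical) == 3
        assert cohort.n_patients() == 1
        assert cohort.clinical["updrs3"].isna().sum() == 1

    def test_out_of_range_hy_stage_names_row_and_bound(self, tmp_path):
        bad = GOOD.replace("P1,2021-01-01,2.0,24,2,", "P1,2021-01-01,2.0,24,6,")
        with pytest.raises(RowError, match=r"row 1.*hy_stage"):
            load_clinical(_csv(tmp_path, bad))

    def test_score_out_of_range_rejected(self, tmp_path):
        bad = GOOD.replace("24", "200")  # above UPDRS III max of 132
        with pytest.raises(RowError, match=r"updrs3=200.*\[0.0, 132.0\]"):
            load_clinical(_csv(tmp_path, bad))

    def test_duplicate_patient_date_named(self, tmp_path):
        bad = GOOD.replace("P1,2021-01-01", "P1,2020-01-01")
        with pytest.raises(RowError, match=r"duplicate.*P1.*2020-01-01"):
            load_clinical(_csv(tmp_path, bad))

    def test_missing_column_is_schema_error(self, tmp_path):
        bad = GOOD.replace("years_since_diagnosis", "bogus")
        with pytest.raises(SchemaError, match="years_since_diagnosis"):
            load_clinical(_csv(tmp_path, bad))

    def test_unparseable_number_lists_row(self, tmp_path):
        bad = GOOD.replace("P1,2021-01-01,2.0", "P1,2021-01-01,oops")
        with pytest.raises(RowError, match="row 1"):
            load_clinical(_csv(tmp_path, bad))

    def test_negative_time_rejected(self, tmp_path):
        bad = GOOD.replace("P1,2021-01-01,2.0", "P1,2021-01-01,-2.0")
        with pytest.raises(RowError, match="years_since_diagnosis"):
            load_clinical(_csv(tmp_path, bad))


def test_roundtrip_bit_identical(tmp_path, lux_small):
    """write_cohort -> load reproduces all finite values exactly."""
    _, cohort, _ = lux_small
    write_cohort(cohort, tmp_path)
    back = load_clinical(tmp_path / "clinical_visits.csv",
                         score_ranges=cohort.score_ranges)
    back = load_gait(tmp_path / "gait_sessions.csv", back)
    for col in cohort.outcome_columns + ["years_since_diagnosis"]:
        np.testing.assert_array_equal(back.clinical[col].to_numpy(),
                                      cohort.clinical[col].to_numpy())
    feat = [c for c in cohort.gait.columns if c not in
            ("patient_id", "visit_date", "task")]
    for col in feat:
        np.testing.assert_array_equal(back.gait[col].to_numpy(),
                                      cohort.gait[col].to_numpy())


class TestAxialScore:
    @pytest.mark.parametrize("items,variant,expected", [
        ({i: 0 for i in (1, 2, 9, 10, 11, 12, 13)}, "mds", 0),
        (dict(zip((1, 2, 9, 10, 11, 12, 13), (2, 1, 0, 3, 1, 2, 1))),
         "mds", 10),
        ({i: 4 for i in (1, 2, 9, 10, 11, 12, 13)}, "original", 24),
        ({i: 4 for i in (1, 2, 9, 10, 11, 12, 13)}, "mds", 28),
    ])
    def test_sums(self, items, variant, expected):
        assert compute_axial_score(items, variant) == expected

    def test_missing_item_named(self):
        items = {i: 1 for i in (1, 2, 9, 10, 12, 13)}  # item 11 absent
        with pytest.raises(ValueError, match="item 11"):
            compute_axial_score(items, "mds")
        # but the original variant does not need item 11
        assert compute_axial_score(items, "original") == 6

    def test_item_out_of_range(self):
        items = {i: 0 for i in (1, 2, 9, 10, 11, 12, 13)}
        items[10] = 5
        with pytest.raises(ValueError, match="item 10"):
            compute_axial_score(items, "mds")

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            compute_axial_score({}, "new")


def _toy_cohort(visit_counts, outcome="updrs3"):
    rows = []
    for i, n in enumerate(visit_counts):
        for j in range(n):
            rows.append({"patient_id": f"P{i}",
                         "visit_date": pd.Timestamp("2020-01-01")
                         + pd.Timedelta(days=365 * j),
                         "years_since_diagnosis": float(j),
                         "age_at_diagnosis": 60.0, "sex": "M",
                         outcome: 10.0 + j})
    return Cohort(clinical=pd.DataFrame(
        rows, columns=["patient_id", "visit_date", "years_since_diagnosis",
                       "age_at_diagnosis", "sex", outcome]))


class TestFilterMinVisits:
    def test_counts(self):
        cohort = _toy_cohort([3, 1, 2])
        out = filter_min_visits(cohort, ["updrs3"], 2)
        assert out.n_patients() == 2
        assert out.meta["filter_report"]["patients_before"] == 3
        assert out.meta["filter_report"]["patients_after"] == 2

    def test_empty_cohort(self):
        cohort = _toy_cohort([])
        out = filter_min_visits(cohort, ["updrs3"], 2)
        assert out.n_patients() == 0

    def test_unknown_outcome(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            filter_min_visits(_toy_cohort([2]), ["nope"])

    def test_randomized_against_tally_oracle(self, rng):
        """Retained set equals an independent per-patient tally."""
        rows = []
        for i in range(100):
            for j in range(rng.integers(1, 6)):
                rows.append({"patient_id": f"P{i:03d}",
                             "visit_date": pd.Timestamp("2020-01-01")
                             + pd.Timedelta(days=int(j) * 200),
                             "years_since_diagnosis": float(j),
                             "age_at_diagnosis": 60.0, "sex": "F",
                             "updrs3": float(rng.integers(0, 50))
                             if rng.random() < 0.8 else np.nan,
                             "axial": float(rng.integers(0, 20))
                             if rng.random() < 0.8 else np.nan})
        cohort = Cohort(clinical=pd.DataFrame(rows))
        out = filter_min_visits(cohort, ["updrs3", "axial"], 2)
        # brute-force oracle: explicit per-patient, per-outcome counting
        expected = set()
        df = cohort.clinical
        for pid in df["patient_id"].unique():
            sub = df[df["patient_id"] == pid]
            if all(sub[o].notna().sum() >= 2 for o in ("updrs3", "axial")):
                expected.add(pid)
        assert set(out.clinical["patient_id"]) == expected

    def test_idempotent_and_monotone(self, lux_small):
        _, cohort, _ = lux_small
        once = filter_min_visits(cohort, ["updrs3"], 3)
        twice = filter_min_visits(once, ["updrs3"], 3)
        assert set(once.patients) == set(twice.patients)
        stricter = filter_min_visits(cohort, ["updrs3"], 5)
        assert set(stricter.patients) <= set(once.patients)


def _gait_df(entries):
    return pd.DataFrame([{"patient_id": p, "visit_date": pd.Timestamp(d),
                          "task": t, "gait_speed": v}
                         for p, d, t, v in entries])


class TestMatching:
    def _cohort(self, clin_dates, gait_entries):
        clin = pd.DataFrame([{"patient_id": "P1",
                              "visit_date": pd.Timestamp(d),
                              "years_since_diagnosis": float(i),
                              "age_at_diagnosis": 60.0, "sex": "M",
                              "updrs3": 20.0 + i}
                             for i, d in enumerate(clin_dates)])
        return Cohort(clinical=clin, gait=_gait_df(gait_entries))

    def test_same_day_matches(self):
        c = self._cohort(["2020-01-01"],
                         [("P1", "2020-01-01", "TUG", 1.1)])
        out = match_gait_to_clinical(c)
        assert len(out) == 1
        assert out.loc[0, "TUG__gait_speed"] == 1.1
        assert out.loc[0, "updrs3"] == 20.0

    def test_tolerance_zero_drops_offset_gait(self):
        c = self._cohort(["2020-01-04"],
                         [("P1", "2020-01-01", "TUG", 1.1)])
        assert len(match_gait_to_clinical(c, tolerance_days=0)) == 0
        assert c.meta["unmatched_gait_dates"] == 1
        assert len(match_gait_to_clinical(c, tolerance_days=3)) == 1

    def test_tie_breaks_to_earlier_visit(self):
        c = self._cohort(["2020-01-01", "2020-01-05"],
                         [("P1", "2020-01-03", "TUG", 1.1)])
        out = match_gait_to_clinical(c, tolerance_days=2)
        assert out.loc[0, "clinical_date"] == pd.Timestamp("2020-01-01")

    def test_random_sessions_against_bruteforce_oracle(self, rng):
        """Matched pairs equal an exhaustive date-difference search."""
        clin_rows, gait_rows = [], []
        for i in range(10):
            dates = sorted(rng.choice(365, size=6, replace=False))
            for j, d in enumerate(dates):
                clin_rows.append({"patient_id": f"P{i}",
                                  "visit_date": pd.Timestamp("2020-01-01")
                                  + pd.Timedelta(days=int(d)),
                                  "years_since_diagnosis": float(j),
                                  "age_at_diagnosis": 60.0, "sex": "M",
                                  "updrs3": 10.0})
            for d in rng.choice(365, size=5, replace=False):
                gait_rows.append(("P%d" % i,
                                  pd.Timestamp("2020-01-01")
                                  + pd.Timedelta(days=int(d)), "TUG",
                                  float(rng.normal(1.2, 0.1))))
        cohort = Cohort(clinical=pd.DataFrame(clin_rows),
                        gait=_gait_df(gait_rows))
        tol = 2
        out = match_gait_to_clinical(cohort, tolerance_days=tol)
        got = {(r["patient_id"], r["gait_date"]): r["clinical_date"]
               for _, r in out.iterrows()}
        clin = cohort.clinical
        expected = {}
        for p, gd, _, _ in gait_rows:
            sub = clin[clin["patient_id"] == p]
            diffs = (sub["visit_date"] - gd).dt.days.abs()
            cand = sub[diffs <= tol]
            if len(cand):
                best = diffs.loc[cand.index].min()
                pick = cand[diffs.loc[cand.index] == best] \
                    .sort_values("visit_date").iloc[0]
                expected[(p, gd)] = pick["visit_date"]
        assert got == expected
        # output size bounded by distinct (patient, gait date) pairs
        assert len(out) <= len(set((p, d) for p, d, _, _ in gait_rows))


class TestGaitSchema:
    def test_duplicate_names_rejected(self):
        from gaitprog.cohort import GaitFeature
        with pytest.raises(SchemaError):
            GaitSchema(features=(GaitFeature("a", "m"), GaitFeature("a", "m")))

    def test_phase_consistency_enforced(self):
        df = pd.DataFrame({"stride_time": [1.0], "stance_time": [0.6],
                           "swing_time": [0.6]})   # 0.6+0.6 != 1.0 by 20%
        with pytest.raises(RowError, match="stride"):
            GaitSchema().validate(df)
        ok = pd.DataFrame({"stride_time": [1.0], "stance_time": [0.62],
                           "swing_time": [0.40]})  # within 5% tolerance
        GaitSchema().validate(ok)

    def test_range_violation(self):
        df = pd.DataFrame({"gait_speed": [-0.5]})
        with pytest.raises(RowError, match="gait_speed"):
            GaitSchema().validate(df)


def test_gait_patient_must_exist_clinically():
    clin = pd.DataFrame([{"patient_id": "P1",
                          "visit_date": pd.Timestamp("2020-01-01"),
                          "years_since_diagnosis": 0.0,
                          "age_at_diagnosis": 60.0, "sex": "M"}])
    gait = _gait_df([("P9", "2020-01-01", "TUG", 1.0)])
    with pytest.raises(RowError, match="P9"):
        Cohort(clinical=clin, gait=gait)
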