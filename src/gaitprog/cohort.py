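"""Cohort data model and strict CSV input/output.

Long-format clinical visit tables and task-specific gait feature sessions
are the two inputs of every analysis in this package.  Clinical visits carry
UPDRS-family scores, Hoehn & Yahr stage, medication state and static
covariates; gait sessions carry one feature vector per (patient, date, task).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed vocabulary of gait tasks: Timed-Up-and-Go, the Turn, manual TUG
#: (Tray), cognitive TUG (Count) and the 2x10m / 4x10m straight walks.
TASKS = ("TUG", "Turn", "Tray", "Count", "W2x10", "W4x10")

#: Valid Hoehn & Yahr stages, half stages included.
HY_STAGES = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)

#: Default score ranges; configuration, not constants, because the MDS
#: revision and the original UPDRS use different item sets and ranges.
DEFAULT_SCORE_RANGES: dict[str, tuple[float, float]] = {
    "updrs1": (0.0, 52.0),
    "updrs2": (0.0, 52.0),
    "updrs3": (0.0, 132.0),
    "axial": (0.0, 28.0),
    "pigd": (0.0, np.inf),
    "td": (0.0, np.inf),
}

CLINICAL_REQUIRED = ("patient_id", "visit_date", "years_since_diagnosis",
                     "age_at_diagnosis", "sex")

#: MDS-UPDRS III items entering the axial score: speech (1), facial
#: expression (2), arising from chair (9), gait (10), freezing of gait (11),
#: postural instability (12), posture (13).  The original UPDRS has no
#: freezing-of-gait item, so that variant drops item 11.
AXIAL_ITEMS = {"mds": (1, 2, 9, 10, 11, 12, 13), "original": (1, 2, 9, 10, 12, 13)}


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A required column is missing or a file is structurally invalid."""


class RowError(CohortError):
    """One or more rows violate typing, range or uniqueness rules."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid rows:\n" + "\n".join(self.problems))


@dataclass(frozen=True)
class GaitFeature:
    name: str
    unit: str
    low: float = -np.inf
    high: float = np.inf


@dataclass
class GaitSchema:
    """Ordered descriptors of the digital gait features a device exports."""

    features: tuple[GaitFeature, ...] = (
        GaitFeature("stride_length", "m", 0.0),
        GaitFeature("gait_speed", "m/s", 0.0),
        GaitFeature("stride_time", "s", 0.0),
        GaitFeature("stance_time", "s", 0.0),
        GaitFeature("swing_time", "s", 0.0),
        GaitFeature("landing_impact", "device units"),
        GaitFeature("max_sensor_lift", "cm", 0.0),
    )
    #: |stance + swing - stride| tolerance as a fraction of stride time.
    phase_tolerance: float = 0.05

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise SchemaError("gait feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def validate(self, df: pd.DataFrame) -> None:
        """Range-check feature columns; enforce gait-phase consistency."""
        problems: list[str] = []
        for f in self.features:
            if f.name not in df.columns:
                continue
            v = df[f.name].astype(float)
            bad = v.notna() & ((v < f.low) | (v > f.high))
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx}: {f.name}={v[idx]} outside [{f.low}, {f.high}]")
        phase = {"stance_time", "swing_time", "stride_time"}
        if phase.issubset(df.columns):
            sub = df[list(phase)].dropna()
            resid = (sub["stance_time"] + sub["swing_time"] - sub["stride_time"]).abs()
            bad = resid > self.phase_tolerance * sub["stride_time"].abs()
            for idx in sub.index[bad]:
                problems.append(
                    f"row {idx}: stance+swing deviates from stride by "
                    f"{resid[idx]:.4g} (> {self.phase_tolerance:.0%} of stride)")
        if problems:
            raise RowError(problems)


@dataclass
class Cohort:
    """A clinical visit table plus (optionally) matched gait sessions.

    ``clinical`` is long-format, one row per visit; ``gait`` one row per
    (patient, date, task).  Every gait patient must exist clinically.
    """

    clinical: pd.DataFrame
    gait: pd.DataFrame | None = None
    label: str = "cohort"
    score_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_RANGES))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gait is not None and len(self.gait):
            missing = set(self.gait["patient_id"]) - set(self.clinical["patient_id"])
            if missing:
                raise RowError(
                    [f"gait patient {p!r} absent from clinical table"
                     for p in sorted(missing)])

    @property
    def outcome_columns(self) -> list[str]:
        return [c for c in self.clinical.columns if c in self.score_ranges]

    @property
    def patients(self) -> list[str]:
        return list(pd.unique(self.clinical["patient_id"]))

    def n_patients(self) -> int:
        return self.clinical["patient_id"].nunique()


def _parse_clinical(df: pd.DataFrame,
                    score_ranges: dict[str, tuple[float, float]]) -> pd.DataFrame:
    problems: list[str] = []
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing required columns: {missing}")

    out = df.copy()
    dates = pd.to_datetime(out["visit_date"], format="ISO8601", errors="coerce")
    for idx in out.index[dates.isna() & out["visit_date"].notna()]:
        problems.append(f"row {idx}: unparseable visit_date "
                        f"{out.loc[idx, 'visit_date']!r}")
    out["visit_date"] = dates

    for col in ("years_since_diagnosis", "age_at_diagnosis"):
        v = pd.to_numeric(out[col], errors="coerce")
        for idx in out.index[v.isna() & out[col].notna()]:
            problems.append(f"row {idx}: unparseable {col} {out.loc[idx, col]!r}")
        out[col] = v
    t = out["years_since_diagnosis"]
    for idx in out.index[t.notna() & ((t < 0) | ~np.isfinite(t))]:
        problems.append(f"row {idx}: years_since_diagnosis={t[idx]} "
                        "must be finite and >= 0")

    for score, (lo, hi) in score_ranges.items():
        if score not in out.columns:
            continue
        v = pd.to_numeric(out[score], errors="coerce")
        for idx in out.index[v.isna() & out[score].notna()
                             & (out[score].astype(str).str.strip() != "")]:
            problems.append(f"row {idx}: unparseable {score} {out.loc[idx, score]!r}")
        out[score] = v
        bad = v.notna() & ((v < lo) | (v > hi))
        for idx in out.index[bad]:
            problems.append(f"row {idx}: {score}={v[idx]} outside [{lo}, {hi}]")

    if "hy_stage" in out.columns:
        v = pd.to_numeric(out["hy_stage"], errors="coerce")
        bad = v.notna() & ~v.isin(HY_STAGES)
        for idx in out.index[bad]:
            problems.append(f"row {idx}: hy_stage={v[idx]} not in {HY_STAGES}")
        out["hy_stage"] = v
    if "med_on" in out.columns:
        v = pd.to_numeric(out["med_on"], errors="coerce")
        bad = v.notna() & ~v.isin([0, 1])
        for idx in out.index[bad]:
            problems.append(f"row {idx}: med_on={out.loc[idx, 'med_on']!r} "
                            "must be 1, 0 or blank")
        out["med_on"] = v
    if "sex" in out.columns:
        sex = out["sex"].astype(str).str.upper().str.strip()
        bad = ~sex.isin(["M", "F"])
        for idx in out.index[bad]:
            problems.append(f"row {idx}: sex={out.loc[idx, 'sex']!r} must be M or F")
        out["sex"] = sex

    dup = out.duplicated(subset=["patient_id", "visit_date"], keep=False)
    if dup.any():
        keys = out.loc[dup, ["patient_id", "visit_date"]].drop_duplicates()
        for _, row in keys.iterrows():
            problems.append("duplicate (patient_id, visit_date) = "
                            f"({row['patient_id']!r}, {row['visit_date'].date()})")
    if problems:
        raise RowError(problems)
    return out


def load_clinical(path, score_ranges: dict | None = None, label: str = "cohort",
                  ) -> Cohort:
    """Read a clinical visit CSV with full validation.

    Rows violating score ranges, the H&Y vocabulary, date/number parsing or
    the per-patient date uniqueness raise :class:`RowError` listing every
    offending row index; a missing required column raises
    :class:`SchemaError`.
    """
    ranges = dict(DEFAULT_SCORE_RANGES) if score_ranges is None else dict(score_ranges)
    df = pd.read_csv(path, float_precision="round_trip")
    clinical = _parse_clinical(df, ranges)
    return Cohort(clinical=clinical, label=label, score_ranges=ranges)


def load_gait(path, cohort: Cohort, schema: GaitSchema | None = None) -> Cohort:
    """Attach a gait session CSV to an already loaded cohort."""
    schema = schema or GaitSchema()
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("patient_id", "visit_date", "task"):
        if col not in df.columns:
            raise SchemaError(f"gait table missing required column: {col}")
    df["visit_date"] = pd.to_datetime(df["visit_date"], format="ISO8601")
    problems = [f"row {idx}: unknown task {t!r}"
                for idx, t in df["task"].items() if t not in TASKS]
    dup = df.duplicated(subset=["patient_id", "visit_date", "task"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["patient_id", "visit_date", "task"]].drop_duplicates()
        problems += ["duplicate (patient_id, visit_date, task) = "
                     f"({r['patient_id']!r}, {r['visit_date'].date()}, {r['task']})"
                     for _, r in keys.iterrows()]
    if problems:
        raise RowError(problems)
    schema.validate(df)
    return Cohort(clinical=cohort.clinical, gait=df, label=cohort.label,
                  score_ranges=cohort.score_ranges, meta=dict(cohort.meta))


def write_cohort(cohort: Cohort, directory) -> dict[str, str]:
    """Write clinical_visits.csv (and gait_sessions.csv) under ``directory``.

    Uses pandas' shortest round-tripping float representation, so a
    write/load cycle reproduces finite values bit-identically.
    """
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    ranges = {k: [None if not np.isfinite(v[0]) else v[0],
                  None if not np.isfinite(v[1]) else v[1]]
              for k, v in cohort.score_ranges.items()}
    p = directory / "score_ranges.json"
    with open(p, "w") as fh:
        json.dump(ranges, fh, indent=1)
    paths["score_ranges"] = str(p)
    clin = cohort.clinical.copy()
    clin["visit_date"] = pd.to_datetime(clin["visit_date"]).dt.strftime("%Y-%m-%d")
    p = directory / "clinical_visits.csv"
    clin.to_csv(p, index=False)
    paths["clinical"] = str(p)
    if cohort.gait is not None:
        gait = cohort.gait.copy()
        gait["visit_date"] = pd.to_datetime(gait["visit_date"]).dt.strftime("%Y-%m-%d")
        p = directory / "gait_sessions.csv"
        gait.to_csv(p, index=False)
        paths["gait"] = str(p)
    return paths


def read_score_ranges(path) -> dict[str, tuple[float, float]]:
    """Read a score-range sidecar written by :func:`write_cohort`."""
    import json

    with open(path) as fh:
        raw = json.load(fh)
    return {k: (-np.inf if lo is None else lo, np.inf if hi is None else hi)
            for k, (lo, hi) in raw.items()}


def compute_axial_score(updrs3_items: dict[int, int], variant: str = "mds") -> int:
    """Sum the axial sub-items of the (MDS-)UPDRS motor exam.

    ``variant="mds"`` sums items 1, 2, 9, 10, 11, 12 and 13 (range 0-28);
    ``variant="original"`` omits freezing of gait (item 11; range 0-24),
    which the original UPDRS does not assess.
    """
    if variant not in AXIAL_ITEMS:
        raise ValueError(f"variant must be 'mds' or 'original', got {variant!r}")
    total = 0
    for item in AXIAL_ITEMS[variant]:
        if item not in updrs3_items:
            raise ValueError(f"missing required UPDRS III item {item} "
                             f"for variant {variant!r}")
        value = updrs3_items[item]
        if value not in (0, 1, 2, 3, 4):
            raise ValueError(f"UPDRS III item {item} = {value!r} not in 0..4")
        total += int(value)
    return total


def filter_min_visits(cohort: Cohort, outcomes: list[str],
                      min_visits: int = 2) -> Cohort:
    """Keep patients with >= ``min_visits`` non-missing visits for EVERY outcome.

    The retained-count report is stored under ``cohort.meta['filter_report']``.
    """
    unknown = [o for o in outcomes if o not in cohort.clinical.columns]
    if unknown:
        raise ValueError(f"unknown outcome name(s): {unknown}")
    clin = cohort.clinical
    if len(clin) == 0:
        keep: set[str] = set()
    else:
        counts = clin.groupby("patient_id")[list(outcomes)].count()
        keep = set(counts.index[(counts >= min_visits).all(axis=1)])
    new_clin = clin[clin["patient_id"].isin(keep)].reset_index(drop=True)
    gait = cohort.gait
    if gait is not None:
        gait = gait[gait["patient_id"].isin(keep)].reset_index(drop=True)
    meta = dict(cohort.meta)
    meta["filter_report"] = {
        "outcomes": list(outcomes), "min_visits": int(min_visits),
        "patients_before": int(clin["patient_id"].nunique()),
        "patients_after": len(keep),
    }
    return Cohort(clinical=new_clin, gait=gait, label=cohort.label,
                  score_ranges=dict(cohort.score_ranges), meta=meta)


def match_gait_to_clinical(cohort: Cohort, tolerance_days: int = 0,
                           schema: GaitSchema | None = None) -> pd.DataFrame:
    """Match each gait assessment date to its nearest clinical visit.

    Returns one wide row per (patient, gait date): clinical covariates and
    outcomes from the matched visit plus ``<task>__<feature>`` columns
    (missing where a task was not performed).  The nearest visit within
    ``tolerance_days`` wins; ties break toward the earlier visit.  Unmatched
    gait dates are dropped; the count is recorded under
    ``cohort.meta['unmatched_gait_dates']``.
    """
    if tolerance_days < 0:
        raise ValueError("tolerance_days must be >= 0")
    if cohort.gait is None or len(cohort.gait) == 0:
        return pd.DataFrame()
    schema = schema or GaitSchema()
    feat_cols = [c for c in cohort.gait.columns if c in schema.names]

    wide = cohort.gait.pivot_table(
        index=["patient_id", "visit_date"], columns="task", values=feat_cols,
        aggfunc="first", observed=True)
    wide.columns = [f"{task}__{feat}" for feat, task in wide.columns]
    wide = wide.sort_index(axis=1).reset_index()
    wide = wide.rename(columns={"visit_date": "gait_date"})

    clin = cohort.clinical
    rows = []
    n_unmatched = 0
    by_patient = {pid: sub.sort_values("visit_date")
                  for pid, sub in clin.groupby("patient_id")}
    for _, grow in wide.iterrows():
        sub = by_patient.get(grow["patient_id"])
        if sub is None:
            n_unmatched += 1
            continue
        diffs = (sub["visit_date"] - grow["gait_date"]).dt.days.to_numpy()
        absd = np.abs(diffs)
        ok = absd <= tolerance_days
        if not ok.any():
            n_unmatched += 1
            continue
        cand = np.flatnonzero(ok)
        best = absd[cand].min()
        tied = cand[absd[cand] == best]
        # ties break toward the earlier clinical visit (sorted ascending)
        pick = sub.iloc[tied[0]]
        merged = pick.to_dict()
        merged.update(grow.to_dict())
        merged["clinical_date"] = pick["visit_date"]
        rows.append(merged)
    cohort.meta["unmatched_gait_dates"] = n_unmatched
    if not rows:
        return pd.DataFrame()
    matched = pd.DataFrame(rows).drop(columns=["visit_date"])
    front = ["patient_id", "gait_date", "clinical_date"]
    cols = front + [c for c in matched.columns if c not in front]
    return matched[cols].reset_index(drop=True)
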