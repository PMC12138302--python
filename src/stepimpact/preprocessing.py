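"""Cleaning, imputation, exclusion and stratification of raw step logs.

The rules implemented here turn raw dual-stream device logs into per-user
daily series aligned to each user's registration date (day 0):

* manual pedometer entries are discarded (only automatically linked data
  are analysed);
* per device stream, daily values below 200 or above 50,000 steps are
  treated as implausible and set missing (strictly below/above — exactly
  200 and exactly 50,000 are retained);
* when both streams survive on a day, the larger value is kept;
* missing days are imputed by the mean of the previous 7 calendar days,
  chronologically, so earlier imputations feed later ones — the series
  starts 35 days before registration precisely so that day -28 has a full
  7-day history;
* users are excluded sequentially (missing sex/birth date, residence outside
  the target prefecture, age outside 20-79 at registration, step data not
  linkable over the window, missingness remaining after imputation) and
  tallied at the first rule that removes them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisWindow",
    "StepSeries",
    "StrataLabel",
    "ExclusionTally",
    "clean_and_merge",
    "impute_series",
    "compute_baseline_mean",
    "assign_strata",
    "select_cohort",
    "align_all_users",
]

VALID_MIN = 200
VALID_MAX = 50_000
AGE_MIN = 20
AGE_MAX = 79

BASELINE_BANDS = [
    (-np.inf, 2000, "<2000"),
    (2000, 4000, "2000-3999"),
    (4000, 6000, "4000-5999"),
    (6000, 8000, "6000-7999"),
    (8000, 10_000, "8000-9999"),
    (10_000, 12_000, "10000-11999"),
    (12_000, np.inf, ">=12000"),
]

SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}


@dataclass(frozen=True)
class AnalysisWindow:
    """Day-offset windows around registration (day 0, never analysed)."""

    post_end: int = 28
    pre_start: int = -28
    pre_end: int = -1
    post_start: int = 1
    series_start: int = -35

    def __post_init__(self):
        if self.post_end not in (28, 56, 84, 112):
            raise ValueError(f"post_end must be one of 28/56/84/112, got {self.post_end}")

    @property
    def pre_offsets(self) -> np.ndarray:
        return np.arange(self.pre_start, self.pre_end + 1)

    @property
    def post_offsets(self) -> np.ndarray:
        return np.arange(self.post_start, self.post_end + 1)

    @property
    def all_offsets(self) -> np.ndarray:
        return np.arange(self.series_start, self.post_end + 1)


@dataclass
class StepSeries:
    """One user's daily steps on the offset grid [-35, +P]; NaN = missing."""

    user_id: str
    registration_date: pd.Timestamp
    offsets: np.ndarray
    steps: np.ndarray
    imputed: np.ndarray

    def value_at(self, offset: int) -> float:
        return float(self.steps[int(offset - self.offsets[0])])

    def window_values(self, start: int, end: int) -> np.ndarray:
        i0 = int(start - self.offsets[0])
        return self.steps[i0 : i0 + (end - start) + 1]

    def window_imputed(self, start: int, end: int) -> np.ndarray:
        i0 = int(start - self.offsets[0])
        return self.imputed[i0 : i0 + (end - start) + 1]


@dataclass(frozen=True)
class StrataLabel:
    sex: str
    age_band: str
    season: str
    fiscal_year: int
    baseline_band: str


@dataclass
class ExclusionTally:
    """Sequential exclusion counts in flow-diagram order."""

    total: int = 0
    missing_sex_or_birth: int = 0
    outside_prefecture: int = 0
    age_out_of_range: int = 0
    not_linkable: int = 0
    missing_after_imputation: int = 0
    remaining: int = 0

    @property
    def excluded(self) -> int:
        return (
            self.missing_sex_or_birth
            + self.outside_prefecture
            + self.age_out_of_range
            + self.not_linkable
            + self.missing_after_imputation
        )

    def check(self) -> None:
        if self.total != self.excluded + self.remaining:
            raise AssertionError("exclusion tally does not conserve the cohort size")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_registered", self.total),
            ("excluded_missing_sex_or_birth", self.missing_sex_or_birth),
            ("excluded_outside_prefecture", self.outside_prefecture),
            ("excluded_age_out_of_range", self.age_out_of_range),
            ("excluded_step_data_not_linkable", self.not_linkable),
            ("excluded_missing_after_imputation", self.missing_after_imputation),
            ("analyzed", self.remaining),
        ]
        return pd.DataFrame(rows, columns=["stage", "n"])


def clean_and_merge(
    records: pd.DataFrame,
    registration_date,
    window: AnalysisWindow | None = None,
) -> StepSeries:
    """Validity-filter each device stream, then merge streams by max.

    Filtering precedes the merge so an implausible reading on one device
    cannot mask a valid reading on the other. Manual entries are dropped
    before anything else. Duplicate (user, date, source) rows are a data
    integrity error.
    """
    window = window or AnalysisWindow()
    reg = pd.Timestamp(registration_date)
    auto = records[records["source"] != "manual"]
    if auto.duplicated(subset=["user_id", "date", "source"]).any():
        raise ValueError("duplicate (user, date, source) rows in step log")
    user_id = str(records["user_id"].iloc[0]) if len(records) else ""
    offsets = window.all_offsets
    steps = np.full(offsets.shape, np.nan)
    if len(auto):
        auto = auto.copy()
        auto["offset"] = (pd.to_datetime(auto["date"]) - reg).dt.days
        vals = auto["steps"].astype(float)
        valid = (vals >= VALID_MIN) & (vals <= VALID_MAX)
        auto = auto[valid & auto["offset"].between(window.series_start, window.post_end)]
        merged = auto.groupby("offset")["steps"].max()
        idx = merged.index.to_numpy() - window.series_start
        steps[idx] = merged.to_numpy(dtype=float)
    return StepSeries(
        user_id=user_id,
        registration_date=reg,
        offsets=offsets,
        steps=steps,
        imputed=np.zeros(offsets.shape, dtype=bool),
    )


def impute_series(series: StepSeries, window: AnalysisWindow | None = None) -> StepSeries:
    """Fill missing days with the mean of the previous 7 days, chronologically.

    Previously imputed values participate in later means; a day stays missing
    only when all 7 predecessors are missing. Values observed in the log are
    never altered. Offsets before ``pre_start + (-7)``-coverage (the 35-day
    run-in) are never imputed themselves.
    """
    window = window or AnalysisWindow()
    if series.offsets[0] > window.series_start or series.offsets[-1] < window.post_end:
        raise ValueError(
            f"series for {series.user_id} does not cover "
            f"[{window.series_start}, {window.post_end}]"
        )
    steps = series.steps.copy()
    imputed = series.imputed.copy()
    start = int(window.pre_start - series.offsets[0])
    end = int(window.post_end - series.offsets[0])
    for i in range(start, end + 1):
        if np.isnan(steps[i]):
            prev = steps[i - 7 : i]
            if np.any(~np.isnan(prev)):
                steps[i] = np.nanmean(prev)
                imputed[i] = True
    return replace(series, steps=steps, imputed=imputed)


def compute_baseline_mean(
    series: StepSeries,
    window: AnalysisWindow | None = None,
    include_imputed: bool = True,
) -> float:
    """Mean steps/day over the pre-registration window (-28..-1).

    With ``include_imputed=False`` the mean is taken over observed days only
    (the no-imputation variant reported alongside the imputed one).
    """
    window = window or AnalysisWindow()
    vals = series.window_values(window.pre_start, window.pre_end)
    if not include_imputed:
        vals = np.where(series.window_imputed(window.pre_start, window.pre_end), np.nan, vals)
    if np.all(np.isnan(vals)):
        raise ValueError(f"no usable pre-period days for user {series.user_id}")
    return float(np.nanmean(vals))


def _age_at(registration: pd.Timestamp, birth: pd.Timestamp) -> int:
    """Completed years at registration."""
    age = registration.year - birth.year
    if (registration.month, registration.day) < (birth.month, birth.day):
        age -= 1
    return age


def fiscal_year(date: pd.Timestamp) -> int:
    """Japanese fiscal year: April 1 through March 31, labelled by its start."""
    return date.year if date.month >= 4 else date.year - 1


def season_of(date: pd.Timestamp) -> str:
    return SEASONS[date.month]


def baseline_band(baseline_mean: float) -> str:
    for lo, hi, label in BASELINE_BANDS:
        if lo <= baseline_mean < hi:
            return label
    raise ValueError(f"baseline mean {baseline_mean} not bandable")


def assign_strata(profile: pd.Series, baseline_mean: float) -> StrataLabel:
    """Map one user to the stratification axes used in the effect tables."""
    reg = pd.Timestamp(profile["registration_date"])
    birth = pd.Timestamp(profile["birth_date"])
    age = _age_at(reg, birth)
    return StrataLabel(
        sex=str(profile["sex"]),
        age_band=f"{age // 10 * 10}-{age // 10 * 10 + 9}",
        season=season_of(reg),
        fiscal_year=fiscal_year(reg),
        baseline_band=baseline_band(baseline_mean),
    )


def select_cohort(
    profiles: pd.DataFrame,
    series_by_user: dict[str, StepSeries],
    window: AnalysisWindow | None = None,
    prefecture: str = "Osaka",
) -> tuple[pd.DataFrame, dict[str, StepSeries], ExclusionTally]:
    """Apply the sequential exclusion cascade and return the analysis set.

    Each user is counted at the first rule that excludes them. Imputation is
    applied here (rule 5 concerns missingness *after* imputation). The
    returned frame carries per-user baseline means, strata labels and a
    ``complete_data`` flag (no imputed values in the analysis window).
    """
    window = window or AnalysisWindow()
    tally = ExclusionTally(total=len(profiles))
    rows = []
    kept: dict[str, StepSeries] = {}
    for _, prof in profiles.iterrows():
        uid = prof["user_id"]
        if pd.isna(prof["sex"]) or pd.isna(prof["birth_date"]):
            tally.missing_sex_or_birth += 1
            continue
        if prof["prefecture"] != prefecture:
            tally.outside_prefecture += 1
            continue
        age = _age_at(pd.Timestamp(prof["registration_date"]), pd.Timestamp(prof["birth_date"]))
        if age < AGE_MIN or age > AGE_MAX:
            tally.age_out_of_range += 1
            continue
        series = series_by_user.get(uid)
        if series is None or np.all(np.isnan(series.steps)):
            tally.not_linkable += 1
            continue
        series = impute_series(series, window)
        analysed = series.window_values(window.pre_start, window.post_end)
        if np.any(np.isnan(analysed)):
            tally.missing_after_imputation += 1
            continue
        base = compute_baseline_mean(series, window)
        label = assign_strata(prof, base)
        rows.append(
            {
                "user_id": uid,
                "sex": label.sex,
                "age_band": label.age_band,
                "season": label.season,
                "fiscal_year": label.fiscal_year,
                "baseline_band": label.baseline_band,
                "baseline_mean": base,
                "complete_data": not series.window_imputed(
                    window.pre_start, window.post_end
                ).any(),
            }
        )
        kept[uid] = series
    tally.remaining = len(rows)
    tally.check()
    cols = [
        "user_id", "sex", "age_band", "season", "fiscal_year",
        "baseline_band", "baseline_mean", "complete_data",
    ]
    return pd.DataFrame(rows, columns=cols), kept, tally


def align_all_users(
    steps: pd.DataFrame,
    profiles: pd.DataFrame,
    window: AnalysisWindow | None = None,
) -> dict[str, StepSeries]:
    """Run clean_and_merge for every profiled user present in the log."""
    window = window or AnalysisWindow()
    out: dict[str, StepSeries] = {}
    steps = steps.copy()
    steps["date"] = pd.to_datetime(steps["date"])
    grouped = dict(tuple(steps.groupby("user_id")))
    for _, prof in profiles.iterrows():
        uid = prof["user_id"]
        if uid in grouped:
            out[uid] = clean_and_merge(grouped[uid], prof["registration_date"], window)
    return out


def series_to_frame(series_by_user: dict[str, StepSeries]) -> pd.DataFrame:
    """Long-format export: user_id, day_offset, steps, imputed."""
    frames = []
    for uid, s in series_by_user.items():
        frames.append(
            pd.DataFrame(
                {
                    "user_id": uid,
                    "day_offset": s.offsets,
                    "steps": s.steps,
                    "imputed": s.imputed,
                    "registration_date": s.registration_date,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_series(frame: pd.DataFrame) -> dict[str, StepSeries]:
    """Inverse of :func:`series_to_frame`."""
    out = {}
    for uid, g in frame.groupby("user_id"):
        g = g.sort_values("day_offset")
        out[str(uid)] = StepSeries(
            user_id=str(uid),
            registration_date=pd.Timestamp(g["registration_date"].iloc[0]),
            offsets=g["day_offset"].to_numpy(dtype=int),
            steps=g["steps"].to_numpy(dtype=float),
            imputed=g["imputed"].to_numpy(dtype=bool),
        )
    return out
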