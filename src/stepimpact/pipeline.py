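"""End-to-end study orchestration.

``run_study`` simulates (or ingests) a cohort, applies the cleaning and
exclusion rules per follow-up horizon, fits one counterfactual model per
user, aggregates effects overall and by stratum, runs the pre/post paired
t-test, and assembles report tables mirroring the shapes of a cohort
paper's flow diagram, baseline table and effect tables. Everything is
deterministic given the config seed; per-user fit seeds are spawned from it
so results do not depend on the worker count.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from . import __version__
from .bsts import BstsSpec
from .impact import CohortImpact, EmptyStratumError, UserImpact, aggregate_cohort
from .model import CausalImpactModel
from .preprocessing import (
    AnalysisWindow,
    StepSeries,
    align_all_users,
    select_cohort,
)
from .synthetic import (
    DemographyParams,
    EffectScenario,
    generate_profiles,
    generate_step_logs,
    generate_weather,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "PairedTResult",
    "paired_t_test",
    "run_study",
    "write_tables",
    "fit_cohort",
    "effect_table",
]

STRATA_AXES = ("sex", "age_band", "season", "fiscal_year", "baseline_band")


@dataclass
class StudyConfig:
    """Study definition: data source, horizons, strata, sampler settings."""

    scenario: EffectScenario | None = None
    demography: DemographyParams | None = None
    n_users: int = 300
    input_dir: str | Path | None = None
    horizons: tuple[int, ...] = (28,)
    strata_axes: tuple[str, ...] = STRATA_AXES
    complete_only: bool = False
    prefecture: str = "Osaka"
    bsts: BstsSpec = field(default_factory=BstsSpec)
    out_dir: str | Path | None = None
    seed: int = 0
    jobs: int = 1

    def __post_init__(self) -> None:
        self.horizons = tuple(sorted(set(self.horizons)))
        if 28 not in self.horizons:
            raise ValueError("the 28-day horizon is always analysed")
        bad = set(self.horizons) - {28, 56, 84, 112}
        if bad:
            raise ValueError(f"unsupported horizons: {sorted(bad)}")
        unknown = set(self.strata_axes) - set(STRATA_AXES)
        if unknown:
            raise ValueError(f"unknown strata axes: {sorted(unknown)}")


@dataclass
class PairedTResult:
    t: float
    p: float
    mean_difference: float
    n: int


def paired_t_test(pre_means, post_means) -> PairedTResult:
    """Classical paired t on per-user (post - pre) means, two-sided."""
    pre = np.asarray(pre_means, dtype=float)
    post = np.asarray(post_means, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post vectors must have equal length")
    if pre.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences: t undefined")
    res = stats.ttest_rel(post, pre)
    return PairedTResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean_difference=float(diff.mean()),
        n=int(pre.size),
    )


@dataclass
class StudyReport:
    baseline_table: pd.DataFrame
    prepost_table: pd.DataFrame
    effect_tables: dict[int, pd.DataFrame]
    tally_tables: dict[int, pd.DataFrame]
    per_user_tables: dict[int, pd.DataFrame]
    overall: dict[int, CohortImpact]
    manifest: dict


def _spawned_seeds(seed: int, n: int, label: int = 0) -> list[int]:
    ss = np.random.SeedSequence([seed, label])
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _fit_one(series: StepSeries, weather: pd.DataFrame, window: AnalysisWindow,
             spec: BstsSpec, seed: int):
    model = CausalImpactModel.from_series(series, weather, window, spec)
    try:
        return model.fit(seed=seed), None
    except Exception as exc:  # noqa: BLE001 - failures are tallied, not fatal
        return None, f"{series.user_id}: {exc}"


def fit_cohort(
    series_by_user: dict[str, StepSeries],
    weather: pd.DataFrame | None,
    window: AnalysisWindow,
    spec: BstsSpec,
    seed: int,
    jobs: int = 1,
) -> tuple[dict[str, UserImpact], pd.DataFrame, list[str]]:
    """Fit one counterfactual model per user; returns impacts + a summary table.

    Per-user seeds are spawned deterministically from ``seed`` in user-id
    order, so the result is identical for any worker count.
    """
    uids = sorted(series_by_user)
    seeds = _spawned_seeds(seed, len(uids), label=window.post_end)
    tasks = (
        delayed(_fit_one)(series_by_user[u], weather, window, spec, s)
        for u, s in zip(uids, seeds)
    )
    results = Parallel(n_jobs=jobs)(tasks) if jobs != 1 else [
        _fit_one(series_by_user[u], weather, window, spec, s)
        for u, s in zip(uids, seeds)
    ]
    impacts: dict[str, UserImpact] = {}
    failures: list[str] = []
    rows = []
    for uid, (res, err) in zip(uids, results):
        if err is not None:
            failures.append(err)
            continue
        impacts[uid] = res.impact
        lo_a, hi_a = res.average_effect_ci
        lo_c, hi_c = res.cumulative_effect_ci
        rows.append(
            {
                "user_id": uid,
                "average_effect": res.average_effect,
                "average_lo": lo_a,
                "average_hi": hi_a,
                "cumulative_effect": res.cumulative_effect,
                "cumulative_lo": lo_c,
                "cumulative_hi": hi_c,
            }
        )
    cols = ["user_id", "average_effect", "average_lo", "average_hi",
            "cumulative_effect", "cumulative_lo", "cumulative_hi"]
    return impacts, pd.DataFrame(rows, columns=cols), failures


def effect_table(
    cohort: pd.DataFrame,
    impacts: dict[str, UserImpact],
    strata_axes: tuple[str, ...] = STRATA_AXES,
) -> pd.DataFrame:
    """Stratified effect table (overall row first, then one row per level)."""
    rows = []

    def _append(axis: str, level, uids) -> None:
        label = f"{axis}={level}"
        selected = [impacts[u] for u in uids if u in impacts]
        if not selected:
            rows.append(
                {
                    "stratum": label, "n": 0,
                    "average_effect": None, "average_lo": None, "average_hi": None,
                    "cumulative_effect": None, "cumulative_lo": None, "cumulative_hi": None,
                }
            )
            return
        rows.append(aggregate_cohort(selected).row(label))

    overall = [impacts[u] for u in cohort["user_id"] if u in impacts]
    if not overall:
        raise EmptyStratumError("no fitted users in cohort")
    rows.append(aggregate_cohort(overall).row("all"))
    for axis in strata_axes:
        for level in sorted(cohort[axis].unique(), key=str):
            uids = cohort.loc[cohort[axis] == level, "user_id"]
            _append(axis, level, uids)
    return pd.DataFrame(rows)


def _baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table-1-shaped counts and proportions of the analysis set."""
    n = len(cohort)
    rows = [("all", "all", n, 1.0)]
    for axis in ("sex", "age_band", "fiscal_year", "season", "baseline_band"):
        for level in sorted(cohort[axis].unique(), key=str):
            k = int((cohort[axis] == level).sum())
            rows.append((axis, str(level), k, k / n if n else np.nan))
    df = pd.DataFrame(rows, columns=["characteristic", "level", "n", "proportion"])
    med = cohort["baseline_mean"].median() if n else np.nan
    df.loc[len(df)] = ("baseline_steps_median", "all", n, med)
    return df


def _prepost_table(cohort: pd.DataFrame, series_by_user: dict[str, StepSeries],
                   window: AnalysisWindow) -> pd.DataFrame:
    """Pre/post 4-week means and paired t results, overall and by sex."""
    w28 = AnalysisWindow(post_end=28)
    rows = []
    groups = [("all", cohort)] + [
        (f"sex={s}", cohort[cohort["sex"] == s]) for s in sorted(cohort["sex"].unique())
    ]
    for label, sub in groups:
        pre, post = [], []
        for uid in sub["user_id"]:
            s = series_by_user[uid]
            pre.append(float(np.nanmean(s.window_values(w28.pre_start, w28.pre_end))))
            post.append(float(np.nanmean(s.window_values(w28.post_start, w28.post_end))))
        try:
            t = paired_t_test(pre, post)
            rows.append(
                {
                    "group": label, "n": t.n,
                    "pre_mean": float(np.mean(pre)), "post_mean": float(np.mean(post)),
                    "mean_difference": t.mean_difference, "t": t.t, "p": t.p,
                }
            )
        except ValueError:
            rows.append(
                {
                    "group": label, "n": len(pre),
                    "pre_mean": float(np.mean(pre)) if pre else np.nan,
                    "post_mean": float(np.mean(post)) if post else np.nan,
                    "mean_difference": np.nan, "t": np.nan, "p": np.nan,
                }
            )
    return pd.DataFrame(rows)


def _load_or_simulate(config: StudyConfig):
    if config.input_dir is not None:
        d = Path(config.input_dir)
        steps = pd.read_csv(d / "steps.csv", parse_dates=["date"])
        users = pd.read_csv(d / "users.csv", parse_dates=["birth_date", "registration_date"])
        weather = pd.read_csv(d / "weather.csv", parse_dates=["date"])
        return steps, users, weather
    scenario = config.scenario or EffectScenario()
    max_h = max(config.horizons)
    seeds = _spawned_seeds(config.seed, 3, label=999)
    scenario = dataclasses.replace(scenario, post_days=max_h, seed=seeds[0])
    users = generate_profiles(config.n_users, config.demography, seed=seeds[1])
    lo = users["registration_date"].min() - pd.Timedelta(days=36)
    hi = users["registration_date"].max() + pd.Timedelta(days=max_h + 1)
    weather = generate_weather(lo.date(), (hi - lo).days + 1, seed=seeds[2])
    steps = generate_step_logs(users, weather, scenario)
    return steps, users, weather


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline and return all report tables."""
    steps, users, weather = _load_or_simulate(config)
    effect_tables, tally_tables, per_user_tables, overall = {}, {}, {}, {}
    baseline = prepost = None
    all_failures: list[str] = []
    for horizon in config.horizons:
        window = AnalysisWindow(post_end=horizon)
        aligned = align_all_users(steps, users, window)
        cohort, kept, tally = select_cohort(users, aligned, window, config.prefecture)
        if config.complete_only:
            cohort = cohort[cohort["complete_data"]].reset_index(drop=True)
            kept = {u: kept[u] for u in cohort["user_id"]}
        tally_tables[horizon] = tally.to_frame()
        impacts, per_user, failures = fit_cohort(
            kept, weather, window, config.bsts, config.seed, config.jobs
        )
        all_failures.extend(failures)
        cohort_fitted = cohort[cohort["user_id"].isin(impacts)].reset_index(drop=True)
        per_user_tables[horizon] = per_user
        effect_tables[horizon] = effect_table(cohort_fitted, impacts, config.strata_axes)
        overall[horizon] = aggregate_cohort(
            [impacts[u] for u in cohort_fitted["user_id"]], with_curve=True
        )
        if horizon == 28:
            baseline = _baseline_table(cohort_fitted)
            prepost = _prepost_table(cohort_fitted, kept, window)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "horizons": list(config.horizons),
        "n_users_input": int(len(users)),
        "complete_only": config.complete_only,
        "bsts": dataclasses.asdict(config.bsts),
        "scenario": (
            dataclasses.asdict(config.scenario) if config.scenario is not None else None
        ),
        "input_dir": str(config.input_dir) if config.input_dir else None,
        "fit_failures": all_failures,
    }
    return StudyReport(
        baseline_table=baseline,
        prepost_table=prepost,
        effect_tables=effect_tables,
        tally_tables=tally_tables,
        per_user_tables=per_user_tables,
        overall=overall,
        manifest=manifest,
    )


def write_tables(report: StudyReport, directory: str | Path) -> dict[str, Path]:
    """Write every report table as headered CSV plus a JSON run manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = directory / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        paths[name] = p

    if report.baseline_table is not None:
        _write("baseline_characteristics", report.baseline_table)
    if report.prepost_table is not None:
        _write("prepost_paired_t", report.prepost_table)
    for h, df in report.effect_tables.items():
        _write(f"effects_h{h}", df)
    for h, df in report.tally_tables.items():
        _write(f"exclusion_tally_h{h}", df)
    for h, df in report.per_user_tables.items():
        _write(f"per_user_effects_h{h}", df)
    mpath = directory / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = mpath
    return paths
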