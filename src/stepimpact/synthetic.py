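"""Synthetic mHealth step-count cohorts with a known registration effect.

Every downstream stage of the pipeline (cleaning, imputation, exclusion,
per-user counterfactual modelling, cohort aggregation) is exercised against
cohorts generated here, because the real app cohort is proprietary. The
generator emulates the statistical structure the analysis assumes: per-user
baseline heterogeneity, a weekday/weekend cycle, a linear weather term, a
post-registration level shift, and the data pathologies the cleaning rules
target (implausible values, missing days, duplicate device streams, users
whose device never linked).

All tables are plain pandas DataFrames with ISO-8601 dates; ``write_tables``
emits the three CSV files (steps, users, weather) that the preprocessing
module reads back.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClimateParams",
    "DemographyParams",
    "EffectScenario",
    "generate_weather",
    "generate_profiles",
    "generate_step_logs",
    "write_tables",
    "load_scenario",
]

_SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
    "winter": (12, 1, 2),
}


def _check_simplex(name: str, weights: dict) -> None:
    total = float(sum(weights.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions must sum to 1, got {total!r}")


@dataclass
class ClimateParams:
    """Annual-sinusoid climate for a temperate, monsoon-influenced city.

    Defaults approximate Osaka: mean ~17 degC with a ~11 degC seasonal swing
    peaking in early August (day-of-year ``temp_peak_doy``).
    """

    temp_mean: float = 17.0
    temp_amplitude: float = 11.0
    temp_peak_doy: int = 218
    temp_noise_sd: float = 2.0
    wet_day_prob: float = 0.33
    precip_mean_mm: float = 9.0
    sunshine_mean_h: float = 6.5
    sunshine_sd_h: float = 3.0
    wind_mean_ms: float = 2.8
    wind_sd_ms: float = 1.0


@dataclass
class DemographyParams:
    """Cohort demography for a prefecture-scale Japanese app cohort.

    Defaults: 38.5% men, age ~ N(51.6, 13.2) truncated to 20-79,
    registrations concentrated in spring and fiscal year 2020."""

    sex_props: dict = field(
        default_factory=lambda: {"male": 0.385, "female": 0.615}
    )
    age_mean: float = 51.6
    age_sd: float = 13.2
    age_min: int = 20
    age_max: int = 79
    fiscal_year_weights: dict = field(
        default_factory=lambda: {2020: 0.427, 2021: 0.160, 2022: 0.231, 2023: 0.182}
    )
    season_weights: dict = field(
        default_factory=lambda: {
            "spring": 0.476,
            "summer": 0.165,
            "fall": 0.206,
            "winter": 0.153,
        }
    )
    prefecture: str = "Osaka"
    # contamination rates, all probabilities
    missing_sex_rate: float = 0.0
    missing_birth_rate: float = 0.0
    foreign_residence_rate: float = 0.0
    age_out_of_range_rate: float = 0.0


@dataclass
class EffectScenario:
    """Ground truth for one simulated cohort.

    ``true_effect`` is the steps/day level shift switched on from the day
    after registration; ``effect_sd`` adds per-user heterogeneity around it.
    ``effect_mode`` is ``constant`` or ``decaying`` (halving every
    ``effect_half_life_days`` after registration), the latter emulating the
    attenuation seen over longer follow-up horizons.
    """

    true_effect: float = 360.0
    effect_sd: float = 0.0
    effect_mode: str = "constant"
    effect_half_life_days: float = 56.0
    weekend_offset: float = -800.0
    weather_coefficients: dict = field(
        default_factory=lambda: {
            "temp_c": 15.0,
            "precip_mm": -20.0,
            "sunshine_h": 40.0,
            "wind_ms": -30.0,
        }
    )
    baseline_mean: float = 5900.0
    baseline_sd: float = 4100.0
    noise_sd: float = 1500.0
    missing_rate: float = 0.0
    invalid_rate: float = 0.0
    unlinked_rate: float = 0.0
    manual_rate: float = 0.0
    stream_disagreement_sd: float = 300.0
    post_days: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "invalid_rate", "unlinked_rate", "manual_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("baseline_sd and noise_sd must be nonnegative")
        if self.effect_mode not in ("constant", "decaying"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")


def generate_weather(
    start_date: dt.date,
    n_days: int,
    climate: ClimateParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a contiguous daily weather table.

    Temperature follows an annual sinusoid plus Gaussian noise; precipitation
    is a wet-day Bernoulli times an exponential amount; sunshine is truncated
    to [0, 24] h and reduced on wet days; wind is a truncated Gaussian.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    climate = climate or ClimateParams()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    temp = (
        climate.temp_mean
        + climate.temp_amplitude
        * np.cos(2 * np.pi * (doy - climate.temp_peak_doy) / 365.25)
        + rng.normal(0.0, climate.temp_noise_sd, n_days)
    )
    wet = rng.random(n_days) < climate.wet_day_prob
    precip = np.where(wet, rng.exponential(climate.precip_mean_mm, n_days), 0.0)
    sunshine = rng.normal(climate.sunshine_mean_h, climate.sunshine_sd_h, n_days)
    sunshine = np.clip(sunshine - 3.0 * wet, 0.0, 24.0)
    wind = np.clip(rng.normal(climate.wind_mean_ms, climate.wind_sd_ms, n_days), 0.0, None)
    return pd.DataFrame(
        {
            "date": dates,
            "temp_c": temp,
            "precip_mm": precip,
            "sunshine_h": sunshine,
            "wind_ms": wind,
        }
    )


def _draw_registration_dates(n: int, demo: DemographyParams, rng) -> list[dt.date]:
    fys = np.array(sorted(demo.fiscal_year_weights))
    fy_p = np.array([demo.fiscal_year_weights[f] for f in fys], dtype=float)
    seasons = list(demo.season_weights)
    season_p = np.array([demo.season_weights[s] for s in seasons], dtype=float)
    chosen_fy = rng.choice(fys, size=n, p=fy_p)
    chosen_season = rng.choice(len(seasons), size=n, p=season_p)
    out = []
    for fy, si in zip(chosen_fy, chosen_season):
        month = int(rng.choice(_SEASON_MONTHS[seasons[si]]))
        # fiscal year runs April..March: Jan-Mar belong to the next calendar year
        year = int(fy) if month >= 4 else int(fy) + 1
        last = (dt.date(year, month % 12 + 1, 1) - dt.timedelta(days=1)).day
        out.append(dt.date(year, month, int(rng.integers(1, last + 1))))
    return out


def generate_profiles(
    n_users: int,
    demography: DemographyParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate user profiles (sex, birth date, residence, registration date).

    Contamination rates inject the record defects the exclusion cascade
    screens for: missing sex or birth date, residence outside the target
    prefecture, and ages outside [age_min, age_max] at registration.
    """
    if n_users < 1:
        raise ValueError(f"n_users must be >= 1, got {n_users}")
    demo = demography or DemographyParams()
    _check_simplex("sex", demo.sex_props)
    _check_simplex("fiscal_year", demo.fiscal_year_weights)
    _check_simplex("season", demo.season_weights)
    rng = np.random.default_rng(seed)

    sexes = rng.choice(
        list(demo.sex_props), size=n_users, p=list(demo.sex_props.values())
    ).astype(object)
    reg_dates = _draw_registration_dates(n_users, demo, rng)
    ages = np.clip(
        rng.normal(demo.age_mean, demo.age_sd, n_users), demo.age_min, demo.age_max
    )
    out_of_range = rng.random(n_users) < demo.age_out_of_range_rate
    ages = np.where(
        out_of_range,
        np.where(rng.random(n_users) < 0.5, demo.age_min - 2, demo.age_max + 3),
        ages,
    )
    birth_dates: list[dt.date | None] = []
    for age, reg in zip(ages, reg_dates):
        # completed-years age at registration; offset avoids boundary flicker
        days = int(age * 365.25 + rng.integers(30, 330))
        birth_dates.append(reg - dt.timedelta(days=days))
    prefecture = np.where(
        rng.random(n_users) < demo.foreign_residence_rate, "Other", demo.prefecture
    ).astype(object)
    sexes[rng.random(n_users) < demo.missing_sex_rate] = None
    miss_birth = rng.random(n_users) < demo.missing_birth_rate
    birth = [None if m else b for m, b in zip(miss_birth, birth_dates)]
    return pd.DataFrame(
        {
            "user_id": [f"u{i:06d}" for i in range(n_users)],
            "sex": sexes,
            "birth_date": pd.to_datetime(birth),
            "prefecture": prefecture,
            "registration_date": pd.to_datetime(reg_dates),
        }
    )


def true_daily_steps(
    offsets: np.ndarray,
    dates: pd.DatetimeIndex,
    weather: pd.DataFrame,
    baseline: float,
    user_effect: float,
    scenario: EffectScenario,
) -> np.ndarray:
    """Noise-free expected steps for one user (the generator's ground truth)."""
    w = weather.set_index("date").loc[dates]
    linear = np.zeros(len(dates))
    for key, coef in scenario.weather_coefficients.items():
        linear += coef * w[key].to_numpy()
    weekend = dates.dayofweek >= 5
    effect = np.where(offsets > 0, user_effect, 0.0)
    if scenario.effect_mode == "decaying":
        decay = 0.5 ** (np.maximum(offsets - 1, 0) / scenario.effect_half_life_days)
        effect = effect * decay
    return baseline + scenario.weekend_offset * weekend + linear + effect


def generate_step_logs(
    profiles: pd.DataFrame,
    weather: pd.DataFrame,
    scenario: EffectScenario,
) -> pd.DataFrame:
    """Simulate the raw dual-stream step log for every profiled user.

    Per user and day, a true step count is drawn (baseline + weekend shift +
    weather term + post-registration effect + noise, floored at 0, rounded),
    then emitted on two device streams: one carries the true value, the other
    the true value minus a nonnegative perturbation, so the larger-value merge
    rule recovers the truth whenever both survive validity filtering.
    Invalid values (<200 or >50,000) and whole missing days are injected at
    the configured rates; ``unlinked_rate`` users emit no records at all.
    """
    rng = np.random.default_rng(scenario.seed)
    wmin, wmax = weather["date"].min(), weather["date"].max()
    records: dict[str, list] = {"user_id": [], "date": [], "source": [], "steps": []}
    for row in profiles.itertuples(index=False):
        t0 = row.registration_date
        lo = t0 - pd.Timedelta(days=35)
        hi = t0 + pd.Timedelta(days=scenario.post_days)
        if lo < wmin or hi > wmax:
            raise ValueError(
                f"weather table does not cover [{lo.date()}, {hi.date()}] "
                f"required by user {row.user_id}"
            )
        if rng.random() < scenario.unlinked_rate:
            continue
        n = 35 + scenario.post_days + 1
        dates = pd.date_range(lo, hi, freq="D")
        offsets = np.arange(-35, scenario.post_days + 1)
        if scenario.baseline_sd > 0:
            # moment-matched lognormal: step data are right-skewed
            m, s = scenario.baseline_mean, scenario.baseline_sd
            sig2 = np.log1p(s * s / (m * m))
            baseline = rng.lognormal(np.log(m) - sig2 / 2, np.sqrt(sig2))
        else:
            baseline = scenario.baseline_mean
        user_effect = scenario.true_effect + (
            rng.normal(0.0, scenario.effect_sd) if scenario.effect_sd > 0 else 0.0
        )
        truth = true_daily_steps(offsets, dates, weather, baseline, user_effect, scenario)
        noisy = truth + (
            rng.normal(0.0, scenario.noise_sd, n) if scenario.noise_sd > 0 else 0.0
        )
        primary = np.round(np.maximum(noisy, 0.0))
        secondary = np.maximum(
            primary - np.round(np.abs(rng.normal(0, scenario.stream_disagreement_sd, n))),
            0.0,
        )
        invalid = rng.random(n) < scenario.invalid_rate
        bad_vals = np.where(
            rng.random(n) < 0.5, rng.integers(0, 200, n), rng.integers(50_001, 90_000, n)
        ).astype(float)
        primary = np.where(invalid, bad_vals, primary)
        secondary = np.where(invalid, bad_vals, secondary)
        missing = rng.random(n) < scenario.missing_rate
        keep = ~missing
        for src, vals in (("stream_a", primary), ("stream_b", secondary)):
            records["user_id"].extend([row.user_id] * int(keep.sum()))
            records["date"].extend(dates[keep])
            records["source"].extend([src] * int(keep.sum()))
            records["steps"].extend(vals[keep].astype(int))
        manual = rng.random(n) < scenario.manual_rate
        if manual.any():
            records["user_id"].extend([row.user_id] * int(manual.sum()))
            records["date"].extend(dates[manual])
            records["source"].extend(["manual"] * int(manual.sum()))
            records["steps"].extend(
                rng.integers(500, 20_000, int(manual.sum())).tolist()
            )
    return pd.DataFrame(records)


def write_tables(
    steps: pd.DataFrame,
    users: pd.DataFrame,
    weather: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the three cohort tables as headered CSV with ISO-8601 dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, datecols in (
        ("steps", steps, ["date"]),
        ("users", users, ["birth_date", "registration_date"]),
        ("weather", weather, ["date"]),
    ):
        out = df.copy()
        for c in datecols:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


def load_scenario(path: str | Path) -> EffectScenario:
    """Read an EffectScenario from a YAML mapping; the seed must be explicit."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("scenario config must set an explicit seed")
    return EffectScenario(**raw)


def scenario_to_yaml(scenario: EffectScenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(scenario), fh, sort_keys=False)
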