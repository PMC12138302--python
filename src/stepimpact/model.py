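"""Per-user causal-impact model with a statsmodels-style fit/results API.

`CausalImpactModel` holds one user's aligned daily series and weather
covariates; `.fit()` runs the BSTS Gibbs sampler on the pre-registration
window, forecasts the counterfactual post-registration trajectory, and
returns a `CausalImpactResults` carrying the effect estimates, their
credible intervals and a `summary()` table. Plotting of the observed vs
counterfactual trajectories hangs off the results object.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import bsts, impact
from .preprocessing import AnalysisWindow, StepSeries

WEATHER_COLUMNS = ["temp_c", "precip_mm", "sunshine_h", "wind_ms"]

__all__ = ["CausalImpactModel", "CausalImpactResults", "WEATHER_COLUMNS"]


class CausalImpactModel:
    """Counterfactual effect model for a single user.

    Parameters
    ----------
    y : array-like
        Daily step counts on the offset grid ``window.pre_start ..
        window.post_end`` (day 0 included in the grid but never used).
    covariates : ndarray or None
        Daily covariate matrix on the same grid (one row per offset).
    window : AnalysisWindow
        Pre/post windows around registration.
    spec : BstsSpec
        Sampler configuration; ``spec.seed`` controls all randomness.
    """

    def __init__(self, y, covariates=None, window: AnalysisWindow | None = None,
                 spec: bsts.BstsSpec | None = None, user_id: str = ""):
        self.window = window or AnalysisWindow()
        self.spec = spec or bsts.BstsSpec()
        self.user_id = user_id
        y = np.asarray(y, dtype=float)
        n_expected = self.window.post_end - self.window.pre_start + 1
        if y.shape[0] != n_expected:
            raise ValueError(
                f"series has {y.shape[0]} days; expected {n_expected} "
                f"({self.window.pre_start}..{self.window.post_end})"
            )
        self.offsets = np.arange(self.window.pre_start, self.window.post_end + 1)
        self.y = y
        if covariates is not None:
            covariates = np.asarray(covariates, dtype=float)
            if covariates.shape[0] != n_expected:
                raise ValueError("covariates must align with the series grid")
        self.covariates = covariates

    @classmethod
    def from_series(cls, series: StepSeries, weather: pd.DataFrame | None = None,
                    window: AnalysisWindow | None = None,
                    spec: bsts.BstsSpec | None = None) -> "CausalImpactModel":
        """Build from a preprocessed StepSeries and the daily weather table."""
        window = window or AnalysisWindow()
        y = series.window_values(window.pre_start, window.post_end)
        cov = None
        if weather is not None:
            w = weather.copy()
            w["date"] = pd.to_datetime(w["date"])
            dates = series.registration_date + pd.to_timedelta(
                np.arange(window.pre_start, window.post_end + 1), unit="D"
            )
            cov = w.set_index("date").loc[dates, WEATHER_COLUMNS].to_numpy(dtype=float)
        return cls(y, cov, window, spec, user_id=series.user_id)

    def _split(self):
        w = self.window
        pre_idx = (self.offsets >= w.pre_start) & (self.offsets <= w.pre_end)
        post_idx = (self.offsets >= w.post_start) & (self.offsets <= w.post_end)
        return pre_idx, post_idx

    def fit(self, seed: int | None = None) -> "CausalImpactResults":
        """Sample the posterior on the pre-window and forecast the post-window."""
        spec = self.spec if seed is None else replace(self.spec, seed=seed)
        pre_idx, post_idx = self._split()
        y_pre = self.y[pre_idx]
        y_post = self.y[post_idx]
        X_pre = self.covariates[pre_idx] if self.covariates is not None else None
        X_post = self.covariates[post_idx] if self.covariates is not None else None
        draws = bsts.sample_posterior(y_pre, X_pre, spec)
        horizon = int(post_idx.sum())
        forecast = bsts.predict_counterfactual(
            draws, X_post, horizon, gap_days=self.window.post_start - self.window.pre_end - 1
        )
        ui = impact.user_impact(
            self.user_id, y_post, forecast.trajectories,
            offsets=self.offsets[post_idx],
        )
        return CausalImpactResults(self, draws, forecast, ui, y_post)


class CausalImpactResults:
    """Posterior draws, counterfactual forecast and effect estimates."""

    def __init__(self, model: CausalImpactModel, posterior: bsts.PosteriorDraws,
                 forecast: bsts.CounterfactualForecast, user_impact_: impact.UserImpact,
                 y_post: np.ndarray):
        self.model = model
        self.posterior = posterior
        self.forecast = forecast
        self.impact = user_impact_
        self.y_post = y_post

    # -- scalar effect estimates ------------------------------------------
    @property
    def average_effect(self) -> float:
        return float(self.impact.average.median)

    @property
    def average_effect_ci(self) -> tuple[float, float]:
        return float(self.impact.average.lower), float(self.impact.average.upper)

    @property
    def cumulative_effect(self) -> float:
        return float(self.impact.cumulative.median[-1])

    @property
    def cumulative_effect_ci(self) -> tuple[float, float]:
        return (
            float(self.impact.cumulative.lower[-1]),
            float(self.impact.cumulative.upper[-1]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-day observed, counterfactual and pointwise-impact summary."""
        q = self.forecast.quantiles
        pi = self.impact.pointwise.to_frame(self.impact.offsets)
        return pd.DataFrame(
            {
                "day_offset": q["day_offset"],
                "y": self.y_post,
                "yhat_median": q["yhat_median"],
                "yhat_lo": q["yhat_lo"],
                "yhat_hi": q["yhat_hi"],
                "pi_median": pi["median"],
                "pi_lo": pi["lower"],
                "pi_hi": pi["upper"],
            }
        )

    def summary(self) -> str:
        lo_a, hi_a = self.average_effect_ci
        lo_c, hi_c = self.cumulative_effect_ci
        sigma = self.posterior.sigma_obs
        lines = [
            "Causal impact of registration (posterior summary)",
            "=" * 52,
            f"user:                   {self.model.user_id or '<unnamed>'}",
            f"pre-period days:        {self.model.window.pre_end - self.model.window.pre_start + 1}",
            f"post-period days:       {self.impact.horizon}",
            f"posterior draws:        {self.posterior.n_kept}",
            "",
            f"average effect          {self.average_effect:10.1f} steps/day"
            f"   95% CrI [{lo_a:.1f}, {hi_a:.1f}]",
            f"cumulative effect       {self.cumulative_effect:10.1f} steps"
            f"     95% CrI [{lo_c:.1f}, {hi_c:.1f}]",
            f"observation noise SD    {np.median(sigma):10.1f} steps/day",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs counterfactual with the 95% band (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        df = self.to_frame()
        pre_idx, _ = self.model._split()
        ax.plot(self.model.offsets[pre_idx], self.model.y[pre_idx], "k-", label="observed (pre)")
        ax.plot(df["day_offset"], df["y"], "k-", label="observed (post)")
        ax.plot(df["day_offset"], df["yhat_median"], "b--", label="counterfactual")
        ax.fill_between(df["day_offset"], df["yhat_lo"], df["yhat_hi"], alpha=0.2)
        ax.axvline(0, color="green", lw=1)
        ax.set_xlabel("days since registration")
        ax.set_ylabel("steps/day")
        ax.legend(loc="best", fontsize=8)
        return ax
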