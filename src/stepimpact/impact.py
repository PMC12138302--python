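"""Pointwise, cumulative and average intervention effects, per user and cohort.

For one user, the pointwise impact on post day t is PI_t = y_t - yhat_t,
computed per posterior draw of the counterfactual yhat; the cumulative impact
is the running sum of PI and the average impact its mean over the post
window (so cumulative at the horizon equals horizon x average, draw by
draw). Summaries are posterior medians with 2.5/97.5 percentile bands,
always taken over per-draw functionals (quantiles of sums, never sums of
quantiles).

Across users the cohort effect is the arithmetic mean of per-user point
estimates (posterior medians by default), with a normal-approximation 95%
CI from the across-user standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImpactSummary",
    "UserImpact",
    "CohortImpact",
    "EmptyStratumError",
    "pointwise_impact",
    "cumulative_impact",
    "average_impact",
    "user_impact",
    "aggregate_cohort",
]

_Q = (2.5, 50.0, 97.5)


class EmptyStratumError(ValueError):
    """Raised when a cohort aggregate is requested for zero users."""


@dataclass
class ImpactSummary:
    """Per-draw impact draws plus their pointwise posterior summary."""

    draws: np.ndarray  # (n_draws,) or (n_draws, horizon)

    @property
    def median(self):
        return np.percentile(self.draws, 50.0, axis=0)

    @property
    def lower(self):
        return np.percentile(self.draws, 2.5, axis=0)

    @property
    def upper(self):
        return np.percentile(self.draws, 97.5, axis=0)

    def to_frame(self, offsets: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day_offset": offsets,
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def pointwise_impact(y_post: np.ndarray, counterfactual_draws: np.ndarray) -> ImpactSummary:
    """PI draws: observed minus counterfactual, per post day and draw."""
    y_post = np.asarray(y_post, dtype=float)
    cf = np.asarray(counterfactual_draws, dtype=float)
    if cf.ndim != 2 or cf.shape[1] != y_post.shape[0]:
        raise ValueError(
            f"counterfactual draws have horizon {cf.shape[-1]}, "
            f"observed post series has {y_post.shape[0]}"
        )
    if np.any(np.isnan(y_post)):
        raise ValueError("y_post must have no missing values")
    return ImpactSummary(y_post[None, :] - cf)


def cumulative_impact(pi: ImpactSummary) -> ImpactSummary:
    """Running sum of PI within each draw."""
    return ImpactSummary(np.cumsum(pi.draws, axis=1))


def average_impact(pi: ImpactSummary) -> ImpactSummary:
    """Mean PI over the post window within each draw."""
    return ImpactSummary(pi.draws.mean(axis=1))


@dataclass
class UserImpact:
    """One user's effect estimates over a post window."""

    user_id: str
    offsets: np.ndarray
    pointwise: ImpactSummary
    cumulative: ImpactSummary
    average: ImpactSummary

    @property
    def horizon(self) -> int:
        return len(self.offsets)

    def point_estimate(self, which: str = "average", estimator: str = "median") -> float:
        """Scalar per-user estimate used for cohort averaging."""
        if which == "average":
            draws = self.average.draws
        elif which == "cumulative":
            draws = self.cumulative.draws[:, -1]
        else:
            raise ValueError(f"unknown impact kind {which!r}")
        return float(np.median(draws) if estimator == "median" else np.mean(draws))


def user_impact(user_id: str, y_post: np.ndarray, counterfactual_draws: np.ndarray,
                offsets: np.ndarray | None = None) -> UserImpact:
    pi = pointwise_impact(y_post, counterfactual_draws)
    if offsets is None:
        offsets = np.arange(1, len(y_post) + 1)
    return UserImpact(
        user_id=user_id,
        offsets=np.asarray(offsets),
        pointwise=pi,
        cumulative=cumulative_impact(pi),
        average=average_impact(pi),
    )


@dataclass
class CohortImpact:
    """Across-user mean effects with normal-approximation 95% CIs."""

    n: int
    mean_average: float
    ci_average: tuple[float, float] | None
    mean_cumulative: float
    ci_cumulative: tuple[float, float] | None
    daily_curve: pd.DataFrame | None = None
    single_user: bool = False

    def row(self, label: str) -> dict:
        return {
            "stratum": label,
            "n": self.n,
            "average_effect": self.mean_average,
            "average_lo": None if self.ci_average is None else self.ci_average[0],
            "average_hi": None if self.ci_average is None else self.ci_average[1],
            "cumulative_effect": self.mean_cumulative,
            "cumulative_lo": None if self.ci_cumulative is None else self.ci_cumulative[0],
            "cumulative_hi": None if self.ci_cumulative is None else self.ci_cumulative[1],
        }


def _mean_ci(values: np.ndarray) -> tuple[float, tuple[float, float] | None]:
    mean = float(values.mean())
    if values.size < 2:
        return mean, None
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    return mean, (mean - 1.96 * se, mean + 1.96 * se)


def aggregate_cohort(
    user_impacts: list[UserImpact],
    estimator: str = "median",
    with_curve: bool = False,
) -> CohortImpact:
    """Cohort mean of per-user effects with across-user 95% CIs.

    The per-user summary entering the mean is that user's posterior median
    (or mean, via ``estimator``) of the average and terminal-cumulative
    impact; across-user sampling variation supplies the CI.
    """
    if not user_impacts:
        raise EmptyStratumError("no users in stratum")
    avg = np.array([u.point_estimate("average", estimator) for u in user_impacts])
    cum = np.array([u.point_estimate("cumulative", estimator) for u in user_impacts])
    mean_avg, ci_avg = _mean_ci(avg)
    mean_cum, ci_cum = _mean_ci(cum)
    curve = None
    if with_curve:
        horizon = user_impacts[0].horizon
        daily = np.vstack([u.pointwise.median for u in user_impacts if u.horizon == horizon])
        mean = daily.mean(axis=0)
        if daily.shape[0] >= 2:
            half = 1.96 * daily.std(axis=0, ddof=1) / np.sqrt(daily.shape[0])
        else:
            half = np.zeros(horizon)
        curve = pd.DataFrame(
            {
                "day_offset": user_impacts[0].offsets,
                "mean_pi": mean,
                "lower": mean - half,
                "upper": mean + half,
            }
        )
    return CohortImpact(
        n=len(user_impacts),
        mean_average=mean_avg,
        ci_average=ci_avg,
        mean_cumulative=mean_cum,
        ci_cumulative=ci_cum,
        daily_curve=curve,
        single_user=len(user_impacts) == 1,
    )
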