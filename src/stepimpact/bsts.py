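"""Bayesian structural time series engine for counterfactual forecasting.

The model is the classic causal-impact workhorse: a local linear trend,
a sum-to-zero weekly seasonal component, and a static linear regression on
weather covariates, observed through Gaussian noise::

    y_t     = mu_t + gamma_t + x_t' beta + eps_t,      eps_t ~ N(0, sigma_eps^2)
    mu_t+1  = mu_t + delta_t + eta_mu,                 eta_mu ~ N(0, sigma_mu^2)
    delta_t+1 = delta_t + eta_delta
    gamma_t+1 = -(gamma_t + ... + gamma_t-S+2) + eta_gamma

Fitting is exact-likelihood Bayesian: a Gibbs sampler alternates a
forward-filter backward-sample draw of the state path with conjugate
inverse-gamma draws of the four variances and a conjugate Gaussian (or
spike-and-slab) draw of the regression coefficients. Sampling happens on a
standardized scale (y and covariates centred/scaled by pre-period moments);
results are reported back on the original scale. The counterfactual forecast
propagates each posterior draw through the transition equation past the
intervention and adds observation noise, giving posterior-predictive
pointwise intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kalman import kalman_filter, ffbs

__all__ = [
    "VariancePrior",
    "BstsSpec",
    "StateSpaceModel",
    "BstsParams",
    "FilterResult",
    "PosteriorDraws",
    "CounterfactualForecast",
    "build_state_space",
    "kalman_loglik",
    "sample_posterior",
    "predict_counterfactual",
]

DIFFUSE_VARIANCE = 1e6  # approximate-diffuse prior on the standardized scale


@dataclass(frozen=True)
class VariancePrior:
    """Inverse-gamma prior as (observations-equivalent weight, variance guess).

    The guess is expressed as a fraction of Var(standardized y) = 1, i.e. it
    is directly the prior point for the variance on the sampling scale.
    Maps to IG(shape = weight/2, rate = weight * guess / 2).
    """

    weight: float
    guess: float


@dataclass
class BstsSpec:
    """Sampler configuration.

    State-noise priors are tight and small (guess sd 1% of the data sd,
    32 observations of weight) so the trend and seasonal components stay
    smooth on a 28-day pre-period; the observation-noise prior is weakly
    informative so the residual variance is learned from the data.
    """

    seasonal_period: int = 7
    n_draws: int = 1000
    n_burn: int = 100
    obs_prior: VariancePrior = field(default_factory=lambda: VariancePrior(0.01, 0.5))
    level_prior: VariancePrior = field(default_factory=lambda: VariancePrior(32.0, 1e-4))
    slope_prior: VariancePrior = field(default_factory=lambda: VariancePrior(32.0, 1e-4))
    seasonal_prior: VariancePrior = field(default_factory=lambda: VariancePrior(32.0, 1e-4))
    regression_mode: str = "gaussian"
    slab_sd: float = 1.0
    spike_sd: float = 0.01
    prior_inclusion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonal_period < 2:
            raise ValueError("seasonal_period must be >= 2")
        if not self.n_draws > self.n_burn >= 0:
            raise ValueError("need n_draws > n_burn >= 0")
        if self.regression_mode not in ("gaussian", "spike_slab"):
            raise ValueError(f"unknown regression_mode {self.regression_mode!r}")

    @property
    def n_kept(self) -> int:
        return self.n_draws - self.n_burn


@dataclass
class StateSpaceModel:
    """Time-invariant system matrices; state = (mu, delta, gamma block)."""

    Z: np.ndarray          # (m,) output vector selecting mu + gamma
    T: np.ndarray          # (m, m) transition
    R: np.ndarray          # (m, 3) selection for (level, slope, seasonal) noise
    seasonal_period: int
    n_covariates: int

    @property
    def state_dim(self) -> int:
        return self.Z.shape[0]

    def rqr(self, sigma2_level: float, sigma2_slope: float, sigma2_seasonal: float) -> np.ndarray:
        return self.R @ np.diag([sigma2_level, sigma2_slope, sigma2_seasonal]) @ self.R.T


@dataclass
class BstsParams:
    """A fully specified parameter point for filtering."""

    sigma2_obs: float
    sigma2_level: float
    sigma2_slope: float
    sigma2_seasonal: float
    beta: np.ndarray
    a0: np.ndarray
    P0: np.ndarray


@dataclass
class FilterResult:
    loglik: float
    filtered_mean: np.ndarray      # (n, m) a_{t|t}
    filtered_cov: np.ndarray       # (n, m, m)
    predicted_mean: np.ndarray     # (n, m) a_{t|t-1}
    predicted_cov: np.ndarray
    model: StateSpaceModel

    def one_step_forecasts(self, covariates=None, beta=None) -> np.ndarray:
        """E[y_t | y_1..t-1] on the filtering scale."""
        f = self.predicted_mean @ self.model.Z
        if covariates is not None and beta is not None and len(beta):
            f = f + np.asarray(covariates, dtype=float) @ beta
        return f


def build_state_space(spec: BstsSpec, n_covariates: int = 0) -> StateSpaceModel:
    """Assemble Z, T, R for trend + S-period sum-to-zero seasonality.

    The state is (mu, delta, gamma_t, gamma_{t-1}, ..., gamma_{t-S+2}):
    dimension 2 + (S - 1).
    """
    if n_covariates < 0:
        raise ValueError("n_covariates must be >= 0")
    S = spec.seasonal_period
    m = 2 + (S - 1)
    Z = np.zeros(m)
    Z[0] = 1.0  # level
    Z[2] = 1.0  # current seasonal state
    T = np.zeros((m, m))
    T[0, 0] = 1.0
    T[0, 1] = 1.0
    T[1, 1] = 1.0
    T[2, 2 : 2 + S - 1] = -1.0          # gamma_{t+1} = -(sum of previous S-1)
    for j in range(S - 2):
        T[3 + j, 2 + j] = 1.0           # shift the seasonal memory
    R = np.zeros((m, 3))
    R[0, 0] = 1.0
    R[1, 1] = 1.0
    R[2, 2] = 1.0
    return StateSpaceModel(Z=Z, T=T, R=R, seasonal_period=S, n_covariates=n_covariates)


def _prepare_observations(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    if np.any(np.isinf(y)):
        raise ValueError("observations must be finite or NaN (missing)")
    return np.where(mask, y, 0.0), mask


def kalman_loglik(
    y: np.ndarray,
    covariates: np.ndarray | None,
    model: StateSpaceModel,
    params: BstsParams,
) -> tuple[float, FilterResult]:
    """Exact Gaussian log-likelihood and filtered moments at a parameter point.

    Missing entries of ``y`` (NaN) contribute a prediction step but no
    update and no likelihood term.
    """
    y = np.asarray(y, dtype=float)
    if covariates is not None and len(np.atleast_1d(params.beta)):
        X = np.asarray(covariates, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
        y = y - X @ params.beta
    for v in (params.sigma2_obs, params.sigma2_level, params.sigma2_slope, params.sigma2_seasonal):
        if not np.isfinite(v) or v < 0:
            raise ValueError("variances must be finite and nonnegative")
    y_filled, mask = _prepare_observations(y)
    rqr = model.rqr(params.sigma2_level, params.sigma2_slope, params.sigma2_seasonal)
    ll, a_filt, P_filt, a_pred, P_pred = kalman_filter(
        y_filled, mask, model.Z, model.T, rqr,
        params.sigma2_obs, np.asarray(params.a0, dtype=float),
        np.asarray(params.P0, dtype=float),
    )
    return float(ll), FilterResult(float(ll), a_filt, P_filt, a_pred, P_pred, model)


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws, stored on the standardized scale.

    ``sigma2`` columns are (obs, level, slope, seasonal); ``states`` has
    shape (n_kept, n_pre, state_dim). ``y_mean``/``y_sd`` and
    ``x_mean``/``x_sd`` hold the standardization constants needed to map
    back to steps/day.
    """

    spec: BstsSpec
    model: StateSpaceModel
    sigma2: np.ndarray
    beta: np.ndarray
    inclusion: np.ndarray
    states: np.ndarray
    y_mean: float
    y_sd: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    prediction_seed: int

    @property
    def n_kept(self) -> int:
        return self.sigma2.shape[0]

    @property
    def sigma_obs(self) -> np.ndarray:
        """Observation-noise SD draws in steps/day."""
        return np.sqrt(self.sigma2[:, 0]) * self.y_sd


def _inverse_gamma(rng, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def sample_posterior(
    y_pre: np.ndarray,
    covariates_pre: np.ndarray | None,
    spec: BstsSpec,
) -> PosteriorDraws:
    """Gibbs sampler over states, variances and regression coefficients.

    ``y_pre`` is the pre-intervention series (NaN allowed for missing days),
    ``covariates_pre`` an optional (n, k) matrix aligned with it. The chain
    runs ``spec.n_draws`` iterations and retains the last
    ``n_draws - n_burn``. Reproducible given ``spec.seed``.
    """
    y_pre = np.asarray(y_pre, dtype=float)
    n = y_pre.shape[0]
    if n < 2 * spec.seasonal_period:
        raise ValueError(
            f"pre-period has {n} days; need at least {2 * spec.seasonal_period} "
            f"(twice the seasonal period)"
        )
    X_raw = None
    k = 0
    if covariates_pre is not None:
        X_raw = np.asarray(covariates_pre, dtype=float)
        if X_raw.ndim == 1:
            X_raw = X_raw[:, None]
        if X_raw.shape[0] != n:
            raise ValueError("covariates_pre must align with y_pre")
        k = X_raw.shape[1]

    obs_mask = ~np.isnan(y_pre)
    # centring constant is the rounded mean: any location is equivalent under
    # the diffuse level prior, and rounding makes integer-valued series
    # exactly invariant to integer shifts (counts shifted by a constant give
    # bit-identical chains)
    y_mean = float(np.round(np.nanmean(y_pre)))
    y_sd = float(np.nanstd(y_pre - y_mean))
    if y_sd == 0.0:
        y_sd = 1.0
    y_std = (y_pre - y_mean) / y_sd

    if k:
        x_mean = X_raw.mean(axis=0)
        x_sd = X_raw.std(axis=0)
        x_sd[x_sd == 0.0] = 1.0
        X = (X_raw - x_mean) / x_sd
    else:
        x_mean = np.zeros(0)
        x_sd = np.zeros(0)
        X = np.zeros((n, 0))

    model = build_state_space(spec, k)
    m = model.state_dim
    a0 = np.zeros(m)
    P0 = DIFFUSE_VARIANCE * np.eye(m)

    ss = np.random.SeedSequence(spec.seed)
    gibbs_ss, pred_ss = ss.spawn(2)
    rng = np.random.default_rng(gibbs_ss)
    prediction_seed = int(pred_ss.generate_state(1)[0] % (2**31))

    priors = (spec.obs_prior, spec.level_prior, spec.slope_prior, spec.seasonal_prior)
    sig2 = np.array([p.guess for p in priors])
    beta = np.zeros(k)
    incl = np.ones(k, dtype=bool)
    n_obs = int(obs_mask.sum())
    Xo = X[obs_mask]

    kept = spec.n_kept
    out_sig2 = np.empty((kept, 4))
    out_beta = np.empty((kept, k))
    out_incl = np.empty((kept, k), dtype=bool)
    out_states = np.empty((kept, n, m))

    y_filled = np.where(obs_mask, y_std, 0.0)
    Sm1 = spec.seasonal_period - 1
    for it in range(spec.n_draws):
        y_adj = y_filled - (X @ beta if k else 0.0)
        rqr = model.rqr(sig2[1], sig2[2], sig2[3])
        _, a_filt, P_filt, a_pred, P_pred = kalman_filter(
            y_adj, obs_mask, model.Z, model.T, rqr, sig2[0], a0, P0
        )
        alpha = ffbs(a_filt, P_filt, a_pred, P_pred, model.T, rng.standard_normal((n, m)))

        # conjugate variance updates from the sampled disturbances
        e_level = alpha[1:, 0] - alpha[:-1, 0] - alpha[:-1, 1]
        e_slope = alpha[1:, 1] - alpha[:-1, 1]
        e_seas = alpha[1:, 2] + alpha[:-1, 2 : 2 + Sm1].sum(axis=1)
        for idx, (prior, e) in enumerate(
            zip(priors[1:], (e_level, e_slope, e_seas)), start=1
        ):
            sig2[idx] = _inverse_gamma(
                rng,
                0.5 * (prior.weight + e.size),
                0.5 * (prior.weight * prior.guess + float(e @ e)),
            )
        zalpha = alpha[:, 0] + alpha[:, 2]
        resid = (y_std - zalpha - (X @ beta if k else 0.0))[obs_mask]
        sig2[0] = _inverse_gamma(
            rng,
            0.5 * (spec.obs_prior.weight + n_obs),
            0.5 * (spec.obs_prior.weight * spec.obs_prior.guess + float(resid @ resid)),
        )

        if k:
            target = (y_std - zalpha)[obs_mask]
            if spec.regression_mode == "spike_slab":
                prior_var = np.where(incl, spec.slab_sd**2, spec.spike_sd**2)
            else:
                prior_var = np.full(k, spec.slab_sd**2)
            A = Xo.T @ Xo / sig2[0] + np.diag(1.0 / prior_var)
            b = Xo.T @ target / sig2[0]
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(k))
            if spec.regression_mode == "spike_slab":
                log_slab = -0.5 * (beta / spec.slab_sd) ** 2 - np.log(spec.slab_sd)
                log_spike = -0.5 * (beta / spec.spike_sd) ** 2 - np.log(spec.spike_sd)
                p = spec.prior_inclusion
                odds = np.exp(np.clip(log_slab - log_spike, -500, 500)) * p / (1 - p)
                incl = rng.random(k) < odds / (1.0 + odds)

        if it >= spec.n_burn:
            j = it - spec.n_burn
            out_sig2[j] = sig2
            out_beta[j] = beta
            out_incl[j] = incl
            out_states[j] = alpha

    return PosteriorDraws(
        spec=spec,
        model=model,
        sigma2=out_sig2,
        beta=out_beta,
        inclusion=out_incl,
        states=out_states,
        y_mean=y_mean,
        y_sd=y_sd,
        x_mean=x_mean,
        x_sd=x_sd,
        prediction_seed=prediction_seed,
    )


@dataclass
class CounterfactualForecast:
    """Posterior-predictive counterfactual over the post window."""

    trajectories: np.ndarray  # (n_kept, horizon) in steps/day
    offsets: np.ndarray       # post-window day offsets (1..horizon by default)

    @property
    def quantiles(self) -> pd.DataFrame:
        lo, med, hi = np.percentile(self.trajectories, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {"day_offset": self.offsets, "yhat_lo": lo, "yhat_median": med, "yhat_hi": hi}
        )


def predict_counterfactual(
    draws: PosteriorDraws,
    covariates_post: np.ndarray | None,
    horizon: int,
    gap_days: int = 1,
) -> CounterfactualForecast:
    """Forecast the no-intervention trajectory over the post window.

    Each retained draw's final pre-period state is propagated through the
    transition equation with that draw's state noise; ``gap_days`` silent
    transition steps bridge the skipped registration day (offset 0), which
    is used for neither training nor inference. Observation noise is added,
    so the intervals are posterior predictive.
    """
    k = draws.model.n_covariates
    if k:
        if covariates_post is None:
            raise ValueError("covariates_post required: model has a regression term")
        Xp = np.asarray(covariates_post, dtype=float)
        if Xp.ndim == 1:
            Xp = Xp[:, None]
        if Xp.shape[0] < horizon:
            raise ValueError(
                f"covariates_post covers {Xp.shape[0]} days; horizon is {horizon}"
            )
        Xp = (Xp[:horizon] - draws.x_mean) / draws.x_sd
    rng = np.random.default_rng(draws.prediction_seed)
    nk = draws.n_kept
    T, R, Z = draws.model.T, draws.model.R, draws.model.Z
    state = draws.states[:, -1, :].copy()          # (nk, m)
    noise_sd = np.sqrt(draws.sigma2[:, 1:4])       # (nk, 3)
    obs_sd = np.sqrt(draws.sigma2[:, 0])
    yhat = np.empty((nk, horizon))
    for step in range(gap_days + horizon):
        eta = rng.standard_normal((nk, 3)) * noise_sd
        state = state @ T.T + eta @ R.T
        if step >= gap_days:
            j = step - gap_days
            y = state @ Z + rng.standard_normal(nk) * obs_sd
            if k:
                y = y + Xp[j] @ draws.beta.T
            yhat[:, j] = y
    yhat = draws.y_mean + draws.y_sd * yhat
    return CounterfactualForecast(
        trajectories=yhat,
        offsets=np.arange(gap_days, gap_days + horizon),
    )
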