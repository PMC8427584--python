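"""Bayesian regression of individual heterozygosity on collection year with
spatially autocorrelated residuals.

The model
---------
Individual heterozygosity is treated as one draw from a multivariate normal
whose mean is linear in collection year and whose covariance decays with
pairwise geographic distance through a powered-exponential kernel:

    H ~ MVN(mu, Sigma),   mu_i = M + beta * T_i,
    Sigma_ij = alpha0 * exp(-alpha1 * D_ij^alpha2)

with M the global intercept (heterozygosity units), beta the per-year effect,
alpha0 the sill (residual variance), alpha1 the decay rate and alpha2 in
(0, 2) the shape exponent.  This is a linear regression with a Gaussian-
process residual on geographic distance — a phenomenological model of
temporal diversity loss, not an explicit demographic one.

To help the sampler, responses and predictors are rescaled before fitting
(heterozygosity by its maximum, year to [0, 1] over its span, distance by its
maximum) and all posterior draws are back-transformed to the original units.
Priors are standard normal on the scaled intercept and slope, standard normal
truncated to positives (half-normal) on alpha0 and alpha1, and uniform(0, 2)
on alpha2.  Significance of the temporal effect is read off the equal-tailed
95% credible interval of beta excluding zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import HetRecord, SampleMeta
from .geo import geo_distance_matrix
from .mcmc import adaptive_metropolis, rhat_ess

logger = logging.getLogger(__name__)

PARAM_NAMES = ["M", "beta", "alpha0", "alpha1", "alpha2"]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the spatial decay regression (original units)."""

    M: float
    beta: float
    alpha0: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 (sill) must be positive")
        if self.alpha1 <= 0:
            raise ValueError("alpha1 (decay rate) must be positive")
        if not 0.0 < self.alpha2 < 2.0:
            raise ValueError("alpha2 (shape) must lie in (0, 2)")

    def to_array(self) -> np.ndarray:
        return np.array([self.M, self.beta, self.alpha0, self.alpha1, self.alpha2])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "DecayParams":
        return cls(*map(float, x))


@dataclass
class DecayData:
    """Aligned vectors for the regression: H, T, coordinates and distances."""

    sample_ids: list[str]
    H: np.ndarray
    T: np.ndarray
    coords: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.H = np.asarray(self.H, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if n < 3:
            raise ValueError("need at least 3 samples")
        if self.H.shape != (n,) or self.T.shape != (n,):
            raise ValueError("H and T must be length-n vectors")
        if self.D.shape != (n, n):
            raise ValueError("D must be n x n")
        if not np.allclose(self.D, self.D.T) or np.any(np.diag(self.D) != 0):
            raise ValueError("D must be symmetric with zero diagonal")
        if np.any(self.D < 0):
            raise ValueError("distances must be non-negative")
        if np.any((self.H < 0) | (self.H > 1)):
            raise ValueError("heterozygosity must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class ScalingRecord:
    """Constants used to rescale the data, kept for back-transformation."""

    h_max: float
    t_min: float
    t_max: float
    d_max: float

    def __post_init__(self) -> None:
        if self.h_max <= 0:
            raise ValueError("max heterozygosity must be positive")
        if self.t_max <= self.t_min:
            raise ValueError("year span is degenerate; the slope is unidentifiable")
        if self.d_max <= 0:
            raise ValueError("max distance must be positive")

    @property
    def t_span(self) -> float:
        return self.t_max - self.t_min


def build_decay_data(
    het: Sequence[HetRecord] | np.ndarray,
    meta: Sequence[SampleMeta],
    metric: str = "great_circle_km",
) -> DecayData:
    """Assemble a :class:`DecayData` from heterozygosity records and metadata."""
    by_id = {m.sample_id: m for m in meta}
    if isinstance(het, np.ndarray) or (
        len(het) > 0 and not isinstance(het[0], HetRecord)
    ):
        H = np.asarray(het, dtype=float)
        if H.shape != (len(meta),):
            raise ValueError("heterozygosity vector length must match metadata")
        ids = [m.sample_id for m in meta]
        ordered = list(meta)
    else:
        ids = [r.sample_id for r in het]
        absent = [s for s in ids if s not in by_id]
        if absent:
            raise ValueError(f"samples missing from metadata: {absent}")
        H = np.array([r.heterozygosity for r in het])
        ordered = [by_id[s] for s in ids]
    coords = np.array([[m.longitude, m.latitude] for m in ordered])
    T = np.array([m.year for m in ordered], dtype=float)
    D = geo_distance_matrix(coords, metric=metric)
    return DecayData(sample_ids=ids, H=H, T=T, coords=coords, D=D)


def scale_inputs(data: DecayData) -> tuple[DecayData, ScalingRecord]:
    """Rescale H by its max, T to [0, 1] over its span, D by its max."""
    scaling = ScalingRecord(
        h_max=float(np.max(data.H)),
        t_min=float(np.min(data.T)),
        t_max=float(np.max(data.T)),
        d_max=float(np.max(data.D)),
    )
    scaled = DecayData(
        sample_ids=data.sample_ids,
        H=data.H / scaling.h_max,
        T=(data.T - scaling.t_min) / scaling.t_span,
        coords=data.coords,
        D=data.D / scaling.d_max,
    )
    return scaled, scaling


def powered_exp_cov(
    D: np.ndarray,
    alpha0: float,
    alpha1: float,
    alpha2: float,
    jitter: float | None = None,
) -> np.ndarray:
    """Powered-exponential covariance alpha0 * exp(-alpha1 * D^alpha2).

    A small diagonal jitter (default ``1e-10 * alpha0``) keeps the Cholesky
    factorization stable; the model itself has no nugget, so the diagonal is
    the sill up to that jitter.
    """
    if alpha0 <= 0 or alpha1 <= 0 or not 0 < alpha2 < 2:
        raise ValueError("invalid covariance parameters")
    if jitter is None:
        jitter = 1e-10 * alpha0
    S = alpha0 * np.exp(-alpha1 * np.power(D, alpha2))
    S[np.diag_indices_from(S)] = alpha0 + jitter
    return S


def mvn_logpdf(y: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """MVN log-density via Cholesky factorization."""
    n = y.size
    try:
        c, low = cho_factor(cov, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance not positive definite; increase the jitter"
        ) from exc
    resid = y - mu
    alpha = cho_solve((c, low), resid, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + resid @ alpha))


def log_likelihood(
    data: DecayData, params: DecayParams, jitter_rel: float = 1e-10
) -> float:
    """MVN log-likelihood of H given the regression mean and spatial kernel."""
    mu = params.M + params.beta * data.T
    cov = powered_exp_cov(
        data.D, params.alpha0, params.alpha1, params.alpha2,
        jitter=jitter_rel * params.alpha0,
    )
    return mvn_logpdf(data.H, mu, cov)


def log_prior(params: DecayParams | np.ndarray) -> float:
    """Log prior: N(0,1) on M and beta, half-normal on alpha0/alpha1,
    uniform(0,2) on alpha2.  Returns -inf outside the support."""
    if isinstance(params, DecayParams):
        M, beta, a0, a1, a2 = params.to_array()
    else:
        M, beta, a0, a1, a2 = params
    if a0 <= 0 or a1 <= 0 or not 0.0 < a2 < 2.0:
        return -np.inf
    lp = -0.5 * (M**2 + beta**2) - 2 * _HALF_LOG_2PI
    # half-normal: standard normal restricted to positives (up to log 2)
    lp += -0.5 * (a0**2 + a1**2) - 2 * _HALF_LOG_2PI
    lp += -np.log(2.0)  # uniform(0, 2) density for alpha2
    return float(lp)


@dataclass
class FitConfig:
    """MCMC configuration mirroring the study defaults: 4 chains of 1e4
    iterations, the first half as warm-up, thinning every 20 retained
    iterations."""

    n_chains: int = 4
    n_iterations: int = 10_000
    thin: int = 20
    warmup_fraction: float = 0.5
    seed: int | None = None
    jitter_rel: float = 1e-10
    target_accept: float = 0.3
    compute_diagnostics: bool = True
    rhat_warn: float = 1.01
    ess_warn: float = 200.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must lie in (0, 1)")


@dataclass
class PosteriorSamples:
    """Thinned post-warmup draws on both scales plus diagnostics."""

    draws_scaled: np.ndarray  # (n_chains, n_draws, 5)
    draws: np.ndarray  # back-transformed, same shape
    param_names: list[str]
    scaling: ScalingRecord
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    accept_rates: list[float] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self, scaled: bool = False) -> np.ndarray:
        d = self.draws_scaled if scaled else self.draws
        return d.reshape(-1, d.shape[-1])

    def to_frame(self, scaled: bool = False) -> pd.DataFrame:
        d = self.draws_scaled if scaled else self.draws
        n_chains, n_draws, _ = d.shape
        frames = []
        for c in range(n_chains):
            df = pd.DataFrame(d[c], columns=self.param_names)
            df.insert(0, "iteration", np.arange(n_draws))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


class _ScaledPosterior:
    """Log posterior on the scaled data, cached for repeated evaluation."""

    def __init__(self, data: DecayData, jitter_rel: float = 1e-10) -> None:
        self.H = data.H
        self.T = data.T
        self.D = data.D
        self.n = data.n
        self.jitter_rel = jitter_rel

    def __call__(self, theta: np.ndarray) -> float:
        M, beta, a0, a1, a2 = theta
        if a0 <= 0 or a1 <= 0 or not 0.0 < a2 < 2.0:
            return -np.inf
        lp = log_prior(theta)
        cov = a0 * np.exp(-a1 * np.power(self.D, a2))
        cov[np.diag_indices_from(cov)] = a0 * (1.0 + self.jitter_rel)
        mu = M + beta * self.T
        try:
            ll = mvn_logpdf(self.H, mu, cov)
        except np.linalg.LinAlgError:
            return -np.inf
        return lp + ll


class _UnconstrainedPosterior:
    """Log posterior in the sampling parameterization.

    alpha0 and alpha1 are sampled on the log scale (their posterior ridge is
    far closer to Gaussian there), with the log-scale Jacobian included; the
    stored draws are mapped back to the natural scale.
    """

    def __init__(self, log_post: "_ScaledPosterior") -> None:
        self.log_post = log_post

    @staticmethod
    def to_natural(x: np.ndarray) -> np.ndarray:
        out = np.array(x, dtype=float, copy=True)
        out[..., 2] = np.exp(x[..., 2])
        out[..., 3] = np.exp(x[..., 3])
        return out

    @staticmethod
    def from_natural(theta: np.ndarray) -> np.ndarray:
        out = np.array(theta, dtype=float, copy=True)
        out[..., 2] = np.log(theta[..., 2])
        out[..., 3] = np.log(theta[..., 3])
        return out

    def __call__(self, x: np.ndarray) -> float:
        if not np.all(np.isfinite(x)) or abs(x[2]) > 500 or abs(x[3]) > 500:
            return -np.inf
        lp = self.log_post(self.to_natural(x))
        if not np.isfinite(lp):
            return -np.inf
        return lp + x[2] + x[3]  # Jacobian of the log transforms


def _initial_points(
    data: DecayData, n_chains: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Data-informed starting points in the sampling parameterization:
    OLS line plus jitter, residual variance for the sill."""
    X = np.column_stack([np.ones(data.n), data.T])
    coef, *_ = np.linalg.lstsq(X, data.H, rcond=None)
    resid = data.H - X @ coef
    s2 = max(float(np.var(resid)), 1e-6)
    points = np.empty((n_chains, 5))
    for c in range(n_chains):
        points[c] = [
            coef[0] + 0.05 * rng.standard_normal(),
            coef[1] + 0.05 * rng.standard_normal(),
            np.log(s2) + 0.3 * rng.standard_normal(),
            0.5 * rng.standard_normal(),
            rng.uniform(0.5, 1.5),
        ]
    scales = np.array([0.05, 0.05, 0.4, 0.6, 0.2])
    return points, scales


def sample_posterior(
    scaled_data: DecayData,
    config: FitConfig | None = None,
    scaling: ScalingRecord | None = None,
) -> PosteriorSamples:
    """Draw from the posterior on the scaled data.

    Any correct MCMC kernel satisfies the sampling contract; here an adaptive
    random-walk Metropolis kernel is used (adaptation frozen after warm-up).
    Thinning applies to post-warmup iterations only.  When ``scaling`` is
    given, a back-transformed copy of the draws (original units) is attached.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    log_post = _UnconstrainedPosterior(_ScaledPosterior(scaled_data, config.jitter_rel))
    n_warm = int(round(config.n_iterations * config.warmup_fraction))
    starts, scales = _initial_points(scaled_data, config.n_chains, rng)

    chains = []
    accept_rates = []
    seeds = rng.spawn(config.n_chains)
    for c in range(config.n_chains):
        x0 = starts[c]
        for _ in range(50):
            if np.isfinite(log_post(x0)):
                break
            x0 = starts[c] + 0.1 * rng.standard_normal(5)
        else:
            raise RuntimeError("could not find a finite starting point")
        draws, acc = adaptive_metropolis(
            log_post, x0, config.n_iterations, n_warm, seeds[c],
            init_scales=scales, target_accept=config.target_accept,
        )
        chains.append(log_post.to_natural(draws[:: config.thin]))
        accept_rates.append(acc)
    draws_scaled = np.stack(chains)  # (n_chains, n_draws, 5)

    if scaling is not None:
        draws_orig = back_transform_params(draws_scaled, scaling)
    else:
        draws_orig = draws_scaled.copy()
        scaling = ScalingRecord(h_max=1.0, t_min=0.0, t_max=1.0, d_max=1.0)

    ps = PosteriorSamples(
        draws_scaled=draws_scaled,
        draws=draws_orig,
        param_names=list(PARAM_NAMES),
        scaling=scaling,
        accept_rates=accept_rates,
    )
    if config.compute_diagnostics:
        rhat, ess = rhat_ess(draws_scaled, PARAM_NAMES)
        ps.rhat, ps.ess = rhat, ess
        bad_rhat = {k: v for k, v in rhat.items() if v > config.rhat_warn}
        bad_ess = {k: v for k, v in ess.items() if v < config.ess_warn}
        if bad_rhat:
            warnings.warn(f"Rhat above {config.rhat_warn}: {bad_rhat}", stacklevel=2)
        if bad_ess:
            warnings.warn(f"ESS below {config.ess_warn:g}: {bad_ess}", stacklevel=2)
    return ps


def back_transform_params(
    draws: np.ndarray, scaling: ScalingRecord
) -> np.ndarray:
    """Map draws from the scaled fitting scale to original units.

    beta = beta' * h_max / (t_max - t_min); M = M' * h_max - beta * t_min;
    alpha0 = alpha0' * h_max^2; alpha1 = alpha1' / d_max^alpha2; alpha2
    unchanged.
    """
    draws = np.asarray(draws, dtype=float)
    out = draws.copy()
    beta = draws[..., 1] * scaling.h_max / scaling.t_span
    out[..., 0] = draws[..., 0] * scaling.h_max - beta * scaling.t_min
    out[..., 1] = beta
    out[..., 2] = draws[..., 2] * scaling.h_max**2
    out[..., 3] = draws[..., 3] / scaling.d_max ** draws[..., 4]
    return out


def forward_scale_params(params: DecayParams, scaling: ScalingRecord) -> DecayParams:
    """Exact inverse of :func:`back_transform_params` for a single point."""
    beta_s = params.beta * scaling.t_span / scaling.h_max
    M_s = (params.M + params.beta * scaling.t_min) / scaling.h_max
    return DecayParams(
        M=M_s,
        beta=beta_s,
        alpha0=params.alpha0 / scaling.h_max**2,
        alpha1=params.alpha1 * scaling.d_max**params.alpha2,
        alpha2=params.alpha2,
    )


@dataclass
class FitSummary:
    """Posterior summaries on the original scale."""

    table: pd.DataFrame  # index: parameter; columns: mean, median, ci_low, ci_high
    beta_significant: bool
    percent_decline_mean: float
    percent_decline_ci: tuple[float, float]
    percent_decline_point: float
    t_start: float
    t_end: float

    def __repr__(self) -> str:
        return (
            f"FitSummary(beta_significant={self.beta_significant}, "
            f"percent_decline={self.percent_decline_mean:.1f}% "
            f"over {self.t_start:.0f}-{self.t_end:.0f})\n{self.table}"
        )


def percent_decline(
    M: float | np.ndarray,
    beta: float | np.ndarray,
    t_start: float,
    t_end: float,
) -> float | np.ndarray:
    """Model-predicted percent reduction of the mean line over [t_start, t_end].

    100 * (1 - (M + beta*t_end) / (M + beta*t_start)); positive slopes yield
    negative values (an increase), unclamped.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    baseline = M + np.asarray(beta) * t_start
    if np.any(baseline <= 0):
        raise ValueError("predicted baseline heterozygosity is non-positive")
    final = M + np.asarray(beta) * t_end
    out = 100.0 * (1.0 - final / baseline)
    return float(out) if np.ndim(out) == 0 else out


def percent_decline_params(params: DecayParams, t_start: float, t_end: float) -> float:
    return float(percent_decline(params.M, params.beta, t_start, t_end))


def summarize_fit(samples: PosteriorSamples, min_draws: int = 100) -> FitSummary:
    """Equal-tailed 95% intervals, posterior mean/median, significance of
    beta, and the per-draw percent decline over the sampled year span."""
    flat = samples.flat(scaled=False)
    if flat.shape[0] < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, have {flat.shape[0]}")
    mean = flat.mean(axis=0)
    median = np.median(flat, axis=0)
    lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
    table = pd.DataFrame(
        {"mean": mean, "median": median, "ci_low": lo, "ci_high": hi},
        index=samples.param_names,
    )
    beta_lo, beta_hi = table.loc["beta", ["ci_low", "ci_high"]]
    beta_significant = bool(beta_hi < 0 or beta_lo > 0)

    t0, t1 = samples.scaling.t_min, samples.scaling.t_max
    M_d, beta_d = flat[:, 0], flat[:, 1]
    baseline = M_d + beta_d * t0
    ok = baseline > 0
    if not np.all(ok):
        logger.warning(
            "percent decline: %d of %d draws have non-positive baseline; excluded",
            int((~ok).sum()), flat.shape[0],
        )
    pd_draws = 100.0 * (1.0 - (M_d[ok] + beta_d[ok] * t1) / baseline[ok])
    # plug-in decline at the posterior means; stabler than the per-draw mean
    # when the baseline approaches zero (the ratio blows up draw-wise)
    point = float(percent_decline(float(mean[0]), float(mean[1]), t0, t1))
    return FitSummary(
        table=table,
        beta_significant=beta_significant,
        percent_decline_mean=float(pd_draws.mean()),
        percent_decline_ci=(
            float(np.quantile(pd_draws, 0.025)),
            float(np.quantile(pd_draws, 0.975)),
        ),
        percent_decline_point=point,
        t_start=t0,
        t_end=t1,
    )


def map_line_given_kernel(
    scaled_data: DecayData,
    alpha0: float,
    alpha1: float,
    alpha2: float,
    jitter_rel: float = 1e-10,
) -> tuple[float, float]:
    """MAP of (M', beta') with the covariance parameters held fixed.

    With Sigma fixed the posterior in the line coefficients is Gaussian, so
    the MAP solves the penalised generalised-least-squares normal equations
    (X' Sigma^-1 X + I) b = X' Sigma^-1 H (the identity is the N(0,1) prior
    precision).  As alpha0 -> 0 the prior term vanishes relative to the
    likelihood and the MAP tends to the least-squares line under the
    correlation kernel.
    """
    X = np.column_stack([np.ones(scaled_data.n), scaled_data.T])
    cov = powered_exp_cov(scaled_data.D, alpha0, alpha1, alpha2,
                          jitter=jitter_rel * alpha0)
    c, low = cho_factor(cov, lower=True)
    SinvX = cho_solve((c, low), X)
    Sinvy = cho_solve((c, low), scaled_data.H)
    A = X.T @ SinvX + np.eye(2)
    b = X.T @ Sinvy
    M, beta = np.linalg.solve(A, b)
    return float(M), float(beta)


class SpatialDecayModel(RegressorMixin, BaseEstimator):
    """sklearn-style estimator for the spatial heterozygosity-decay regression.

    Parameters
    ----------
    n_chains, n_iterations, thin, warmup_fraction : MCMC configuration
        Defaults mirror the study design: 4 chains of 10,000 iterations,
        first half discarded as warm-up, every 20th retained iteration kept.
    seed : int or None
        Seed for the sampler; fixed seed gives bit-identical draws.
    metric : {"great_circle_km", "euclidean_degrees"}
        Distance metric for the spatial kernel.
    year_cutoff : float or None
        When set, samples collected after this year are dropped before the
        fit (the robustness refit on the pre-cutoff subset).

    Attributes
    ----------
    posterior_ : PosteriorSamples
    summary_ : FitSummary
    params_ : DecayParams  (posterior means, original units)
    scaling_ : ScalingRecord
    n_retained_ : int
    """

    def __init__(
        self,
        n_chains: int = 4,
        n_iterations: int = 10_000,
        thin: int = 20,
        warmup_fraction: float = 0.5,
        seed: int | None = None,
        metric: str = "great_circle_km",
        jitter_rel: float = 1e-10,
        year_cutoff: float | None = None,
        compute_diagnostics: bool = True,
    ) -> None:
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.thin = thin
        self.warmup_fraction = warmup_fraction
        self.seed = seed
        self.metric = metric
        self.jitter_rel = jitter_rel
        self.year_cutoff = year_cutoff
        self.compute_diagnostics = compute_diagnostics

    def _as_xyz(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            try:
                lon = X["longitude"].to_numpy(dtype=float)
                lat = X["latitude"].to_numpy(dtype=float)
                year = X["year"].to_numpy(dtype=float)
            except KeyError as exc:
                raise ValueError(
                    "X must have columns longitude, latitude, year"
                ) from exc
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 3:
                raise ValueError("X must be (n, 3): longitude, latitude, year")
            lon, lat, year = X[:, 0], X[:, 1], X[:, 2]
        return lon, lat, year

    def _config(self) -> FitConfig:
        return FitConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            thin=self.thin,
            warmup_fraction=self.warmup_fraction,
            seed=self.seed,
            jitter_rel=self.jitter_rel,
            compute_diagnostics=self.compute_diagnostics,
        )

    def fit(self, X, y) -> "SpatialDecayModel":
        lon, lat, year = self._as_xyz(X)
        H = np.asarray(y, dtype=float)
        if H.shape != year.shape:
            raise ValueError("y must be a heterozygosity vector matching X")
        if self.year_cutoff is not None:
            keep = year <= self.year_cutoff
            if keep.sum() < 3:
                raise ValueError("fewer than 3 samples at or before year_cutoff")
            lon, lat, year, H = lon[keep], lat[keep], year[keep], H[keep]
        ids = [f"s{i}" for i in range(len(H))]
        coords = np.column_stack([lon, lat])
        data = DecayData(
            sample_ids=ids, H=H, T=year, coords=coords,
            D=geo_distance_matrix(coords, metric=self.metric),
        )
        scaled, scaling = scale_inputs(data)
        self.posterior_ = sample_posterior(scaled, self._config(), scaling)
        self.summary_ = summarize_fit(self.posterior_)
        flat = self.posterior_.flat()
        self.params_ = DecayParams.from_array(
            np.concatenate([flat[:, :4].mean(axis=0), [np.median(flat[:, 4])]])
        )
        self.scaling_ = scaling
        self.n_retained_ = len(H)
        self.n_features_in_ = 3
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean regression line evaluated at the years in X."""
        if not hasattr(self, "params_"):
            raise AttributeError("model is not fitted")
        _, _, year = self._as_xyz(X)
        return self.params_.M + self.params_.beta * year


def refit_subset_by_year(
    het: Sequence[HetRecord] | np.ndarray,
    meta: Sequence[SampleMeta],
    year_cutoff: float,
    config: FitConfig | None = None,
    metric: str = "great_circle_km",
) -> tuple[FitSummary, int]:
    """Drop samples collected after ``year_cutoff``, rescale and refit.

    Returns the fit summary and the number of retained samples.
    """
    config = config or FitConfig()
    data = build_decay_data(het, meta, metric=metric)
    keep = np.flatnonzero(data.T <= year_cutoff)
    if keep.size < 3:
        raise ValueError("fewer than 3 samples at or before the cutoff")
    sub = DecayData(
        sample_ids=[data.sample_ids[i] for i in keep],
        H=data.H[keep],
        T=data.T[keep],
        coords=data.coords[keep],
        D=data.D[np.ix_(keep, keep)],
    )
    scaled, scaling = scale_inputs(sub)
    ps = sample_posterior(scaled, config, scaling)
    return summarize_fit(ps), int(keep.size)
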