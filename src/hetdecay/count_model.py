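"""Poisson-regression robustness check for the heterozygosity decline.

Instead of modelling the heterozygosity *ratio* as Gaussian, the count of
heterozygous calls in each individual is modelled as Poisson with a log link
and the number of genotyped positions as exposure offset:

    n_het_i ~ Poisson(lambda_i),
    log lambda_i = log n_genotyped_i + m + b * T'_i + u_i,

where u is a latent spatial field, u ~ MVN(0, alpha0 * exp(-alpha1 D'^alpha2)).
This accommodates the heteroscedasticity of a ratio with varying denominators
and respects the [0, 1] support that the Gaussian model ignores.  The latent
field is parameterised non-centred (u = L z with z standard normal) for
sampler robustness.  Priors match the Gaussian model: N(0,1) on m and b,
half-normal on alpha0 and alpha1, uniform(0,2) on alpha2.  Outputs are the
appendix-variant check: what matters is sign/significance concordance of b
with the Gaussian model's beta, not numerical equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .genotypes import HetRecord
from .geo import geo_distance_matrix
from .mcmc import rhat_ess
from .model import FitConfig, ScalingRecord, powered_exp_cov

COUNT_PARAM_NAMES = ["m", "b", "alpha0", "alpha1", "alpha2"]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def poisson_log_likelihood(
    n_het: np.ndarray,
    n_genotyped: np.ndarray,
    T_scaled: np.ndarray,
    m: float,
    b: float,
    u: np.ndarray | float = 0.0,
) -> float:
    """Poisson log-likelihood with log-exposure offset.

    log lambda_i = log(n_genotyped_i) + m + b*T'_i + u_i.
    """
    y = np.asarray(n_het, dtype=float)
    e = np.asarray(n_genotyped, dtype=float)
    if np.any(e <= 0):
        raise ValueError("all exposures must be positive")
    if np.any(y > e):
        raise ValueError("n_het cannot exceed n_genotyped")
    log_lam = np.log(e) + m + b * np.asarray(T_scaled, dtype=float) + u
    if not np.all(np.isfinite(log_lam)):
        raise ValueError("non-finite Poisson rate")
    return float(np.sum(y * log_lam - np.exp(log_lam) - gammaln(y + 1.0)))


def poisson_map_line(
    n_het: np.ndarray,
    n_genotyped: np.ndarray,
    T_scaled: np.ndarray,
    prior_precision: float = 0.0,
) -> tuple[float, float]:
    """Mode of (m, b) with the latent field switched off (u = 0).

    With ``prior_precision=0`` this is plain maximum likelihood — ordinary
    Poisson regression with offset, the alpha0 -> 0 limit of the model —
    solved by Newton iteration (IRLS).
    """
    y = np.asarray(n_het, dtype=float)
    off = np.log(np.asarray(n_genotyped, dtype=float))
    X = np.column_stack([np.ones_like(y), np.asarray(T_scaled, dtype=float)])
    beta = np.array([np.log(max(y.sum(), 1.0)) - np.log(np.exp(off).sum()), 0.0])
    for _ in range(100):
        eta = off + X @ beta
        lam = np.exp(eta)
        grad = X.T @ (y - lam) - prior_precision * beta
        hess = X.T @ (lam[:, None] * X) + prior_precision * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return float(beta[0]), float(beta[1])


@dataclass
class CountPosterior:
    """Draws over (m, b, alpha0', alpha1', alpha2) plus diagnostics."""

    draws_scaled: np.ndarray  # (n_chains, n_draws, 5), scaled year/distance
    draws: np.ndarray  # b per-year, alpha1 per-distance-unit
    param_names: list[str]
    scaling: ScalingRecord
    rhat: dict
    ess: dict

    def flat(self, scaled: bool = False) -> np.ndarray:
        d = self.draws_scaled if scaled else self.draws
        return d.reshape(-1, d.shape[-1])

    @property
    def prob_b_negative(self) -> float:
        return float((self.flat()[:, 1] < 0).mean())


def _count_back_transform(draws: np.ndarray, scaling: ScalingRecord) -> np.ndarray:
    """b per scaled year -> per calendar year; alpha1 to original distances.

    m is a log-rate intercept at the earliest sampling year (T' = 0), and
    alpha0 lives on the log-rate scale; both are left as is.
    """
    out = draws.copy()
    out[..., 1] = draws[..., 1] / scaling.t_span
    out[..., 3] = draws[..., 3] / scaling.d_max ** draws[..., 4]
    return out


def sample_posterior_counts(
    n_het: np.ndarray,
    n_genotyped: np.ndarray,
    T: np.ndarray,
    D: np.ndarray,
    config: FitConfig | None = None,
) -> CountPosterior:
    """MCMC over (m, b, alpha's, z) with u = chol(Sigma(alpha)) z.

    Metropolis-within-Gibbs: a joint adaptive random-walk update of the five
    hyperparameters (which implicitly moves u through the non-centred map)
    alternating with single-site random-walk sweeps over z.  Adaptation of
    all proposal scales stops at the end of warm-up.
    """
    config = config or FitConfig()
    y = np.asarray(n_het, dtype=float)
    e = np.asarray(n_genotyped, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(e <= 0) or np.any(y > e):
        raise ValueError("need 0 <= n_het <= n_genotyped with positive exposure")
    n = y.size

    scaling = ScalingRecord(
        h_max=1.0, t_min=float(T.min()), t_max=float(T.max()),
        d_max=float(np.max(D)),
    )
    Ts = (T - scaling.t_min) / scaling.t_span
    Ds = D / scaling.d_max
    log_e = np.log(e)
    lgy = gammaln(y + 1.0).sum()

    def chol_of(theta: np.ndarray) -> np.ndarray | None:
        a0, a1, a2 = theta[2:]
        if a0 <= 0 or a1 <= 0 or not 0.0 < a2 < 2.0:
            return None
        try:
            return np.linalg.cholesky(powered_exp_cov(Ds, a0, a1, a2))
        except np.linalg.LinAlgError:
            return None

    def loglik(theta: np.ndarray, u: np.ndarray) -> float:
        log_lam = log_e + theta[0] + theta[1] * Ts + u
        return float(y @ log_lam - np.exp(log_lam).sum() - lgy)

    def logprior_theta(theta: np.ndarray) -> float:
        m, b, a0, a1, a2 = theta
        if a0 <= 0 or a1 <= 0 or not 0.0 < a2 < 2.0:
            return -np.inf
        return float(-0.5 * (m**2 + b**2 + a0**2 + a1**2) - np.log(2.0)
                     - 4 * _HALF_LOG_2PI)

    rng = np.random.default_rng(config.seed)
    n_warm = int(round(config.n_iterations * config.warmup_fraction))
    n_keep = config.n_iterations - n_warm
    seeds = rng.spawn(config.n_chains)

    # crude data-informed start for (m, b): ML line on the raw counts
    m0, b0 = poisson_map_line(y, e, Ts)

    chains = []
    for c in range(config.n_chains):
        crng = seeds[c]
        theta = np.array([
            m0 + 0.1 * crng.standard_normal(),
            b0 + 0.1 * crng.standard_normal(),
            np.exp(crng.normal(-1.5, 0.3)),
            np.exp(0.5 * crng.standard_normal()),
            crng.uniform(0.5, 1.5),
        ])
        L = chol_of(theta)
        z = 0.1 * crng.standard_normal(n)
        u = L @ z
        lp_theta = logprior_theta(theta) + loglik(theta, u)

        # adaptive joint RW state for theta
        cov = np.diag(np.array([0.05, 0.05, 0.2, 0.3, 0.1]) ** 2)
        cholp = np.linalg.cholesky(cov)
        log_step = 0.0
        run_mean = theta.copy()
        run_m2 = np.zeros((5, 5))
        z_scale = np.full(n, 0.5)

        kept = np.empty((n_keep, 5))
        for t in range(config.n_iterations):
            # -- joint update of the hyperparameters (u moves with L(alpha) z)
            prop = theta + np.exp(log_step) * cholp @ crng.standard_normal(5)
            Lp = chol_of(prop)
            if Lp is not None:
                up = Lp @ z
                lp_prop = logprior_theta(prop) + loglik(prop, up)
                acc = np.log(crng.random()) < lp_prop - lp_theta
            else:
                acc = False
            if acc:
                theta, L, u, lp_theta = prop, Lp, up, lp_prop
            if t < n_warm:
                log_step += ((1.0 if acc else 0.0) - 0.25) / (1.0 + 0.02 * t) ** 0.6
                delta = theta - run_mean
                run_mean += delta / (t + 1)
                run_m2 += np.outer(delta, theta - run_mean)
                if t >= 100 and (t + 1) % 50 == 0:
                    emp = (2.38**2 / 5) * run_m2 / t + 1e-9 * np.eye(5)
                    try:
                        cholp = np.linalg.cholesky(emp)
                    except np.linalg.LinAlgError:
                        pass

            # -- single-site non-centred sweep over z
            log_lam = log_e + theta[0] + theta[1] * Ts + u
            lam = np.exp(log_lam)
            eps = z_scale * crng.standard_normal(n)
            uniforms = crng.random(n)
            for i in range(n):
                du = L[:, i] * eps[i]
                d_ll = y @ du - (lam * np.expm1(du)).sum()
                d_lp = -0.5 * ((z[i] + eps[i]) ** 2 - z[i] ** 2)
                acc_i = np.log(uniforms[i]) < d_ll + d_lp
                if acc_i:
                    z[i] += eps[i]
                    u = u + du
                    log_lam = log_lam + du
                    lam = np.exp(log_lam)
                if t < n_warm:
                    z_scale[i] *= np.exp(
                        ((1.0 if acc_i else 0.0) - 0.44) / (1.0 + 0.02 * t) ** 0.6
                    )
            lp_theta = logprior_theta(theta) + loglik(theta, u)

            if t >= n_warm:
                kept[t - n_warm] = theta
        chains.append(kept[:: config.thin])

    draws_scaled = np.stack(chains)
    draws = _count_back_transform(draws_scaled, scaling)
    if config.compute_diagnostics:
        rhat, ess = rhat_ess(draws_scaled, COUNT_PARAM_NAMES)
    else:
        rhat, ess = {}, {}
    post = CountPosterior(
        draws_scaled=draws_scaled,
        draws=draws,
        param_names=list(COUNT_PARAM_NAMES),
        scaling=scaling,
        rhat=rhat,
        ess=ess,
    )
    bad = {k: v for k, v in rhat.items() if v > 1.05}
    if bad:
        warnings.warn(f"count model Rhat above 1.05: {bad}", stacklevel=2)
    return post


class PoissonDecayModel(BaseEstimator):
    """sklearn-style estimator for the spatial Poisson count regression.

    ``fit(X, y)`` takes X with columns (longitude, latitude, year) and y of
    shape (n, 2) holding (n_het, n_genotyped) per sample — counts and
    exposures, not ratios.
    """

    def __init__(
        self,
        n_chains: int = 4,
        n_iterations: int = 4000,
        thin: int = 5,
        warmup_fraction: float = 0.5,
        seed: int | None = None,
        metric: str = "great_circle_km",
    ) -> None:
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.thin = thin
        self.warmup_fraction = warmup_fraction
        self.seed = seed
        self.metric = metric

    def fit(self, X, y) -> "PoissonDecayModel":
        if isinstance(X, pd.DataFrame):
            lon = X["longitude"].to_numpy(float)
            lat = X["latitude"].to_numpy(float)
            year = X["year"].to_numpy(float)
        else:
            X = np.asarray(X, dtype=float)
            lon, lat, year = X[:, 0], X[:, 1], X[:, 2]
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2): n_het, n_genotyped")
        D = geo_distance_matrix(np.column_stack([lon, lat]), metric=self.metric)
        config = FitConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            thin=self.thin,
            warmup_fraction=self.warmup_fraction,
            seed=self.seed,
        )
        self.posterior_ = sample_posterior_counts(y[:, 0], y[:, 1], year, D, config)
        flat = self.posterior_.flat()
        lo, hi = np.quantile(flat[:, 1], [0.025, 0.975])
        self.b_mean_ = float(flat[:, 1].mean())
        self.b_ci_ = (float(lo), float(hi))
        self.b_significant_ = bool(hi < 0 or lo > 0)
        self.prob_b_negative_ = self.posterior_.prob_b_negative
        return self


def het_records_to_counts(records: list[HetRecord]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([r.n_het for r in records], dtype=float)
    e = np.array([r.n_genotyped for r in records], dtype=float)
    return y, e
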