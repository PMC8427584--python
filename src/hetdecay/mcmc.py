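"""Adaptive random-walk Metropolis machinery.

A Haario-style adaptive Metropolis kernel: during warm-up the proposal
covariance is taken from the running empirical covariance of the chain
(scaled by 2.38^2/d) and the global step size is tuned toward a target
acceptance rate; after warm-up the proposal is frozen so the retained draws
come from a fixed, valid Metropolis kernel.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["adaptive_metropolis", "rhat_ess"]


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    init_scales: np.ndarray | None = None,
    target_accept: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Run one chain; return post-warmup draws and their acceptance rate.

    Parameters
    ----------
    log_post : callable
        Log posterior density (may return -inf outside the support).
    x0 : array
        Starting point with finite log posterior.
    n_iter, n_warmup : int
        Total iterations and warm-up iterations (adaptation happens only in
        warm-up; warm-up draws are discarded).
    init_scales : array, optional
        Initial per-coordinate proposal standard deviations.
    """
    x = np.array(x0, dtype=float)
    d = x.size
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")

    if init_scales is None:
        init_scales = np.maximum(np.abs(x) * 0.1, 1e-3)
    cov = np.diag(np.asarray(init_scales, dtype=float) ** 2)
    chol = np.linalg.cholesky(cov)
    log_step = 0.0

    run_mean = x.copy()
    run_m2 = np.zeros((d, d))

    keep = np.empty((n_iter - n_warmup, d))
    n_accept_post = 0

    for t in range(n_iter):
        step = np.exp(log_step)
        prop = x + step * chol @ rng.standard_normal(d)
        lp_prop = log_post(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop

        if t < n_warmup:
            # Robbins-Monro step-size tuning toward the target acceptance rate
            acc = 1.0 if accept else 0.0
            log_step += (acc - target_accept) / (1.0 + 0.02 * t) ** 0.6
            # running covariance of the chain history
            delta = x - run_mean
            run_mean += delta / (t + 1)
            run_m2 += np.outer(delta, x - run_mean)
            if t >= max(50, 2 * d) and (t + 1) % 50 == 0:
                emp = run_m2 / t
                emp = (2.38**2 / d) * emp + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(emp)
                except np.linalg.LinAlgError:
                    pass
        else:
            keep[t - n_warmup] = x
            n_accept_post += bool(accept)

    accept_rate = n_accept_post / max(1, n_iter - n_warmup)
    return keep, accept_rate


def rhat_ess(draws: np.ndarray, param_names: list[str]) -> tuple[dict, dict]:
    """Split-Rhat and bulk ESS per parameter via arviz.

    ``draws`` has shape (n_chains, n_draws, n_params).
    """
    import arviz as az

    data = {name: draws[:, :, j] for j, name in enumerate(param_names)}
    ds = az.convert_to_dataset(data)
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    return (
        {name: float(rhat[name].values) for name in param_names},
        {name: float(ess[name].values) for name in param_names},
    )
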