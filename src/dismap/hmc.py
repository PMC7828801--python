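"""A compact Hamiltonian Monte Carlo sampler vectorised across chains.

Static-trajectory HMC with jittered leapfrog length, dual-averaging step-size
adaptation (Nesterov/Hoffman–Gelman schedule) and diagonal mass-matrix
estimation from a warmup window.  The target supplies a batched
``logp_grad(q)`` for positions of shape ``(n_chains, dim)``; gradients are
analytic, so no autodiff stack is needed.  This is the sampling backend for
the hierarchical Poisson log-linear models; the model layer checks
convergence (split-Rhat) on the retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.random import default_rng

LogpGrad = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class HmcResult:
    draws: np.ndarray            # (n_chains, n_draws, dim)
    accept_rate: np.ndarray      # per chain
    step_size: np.ndarray        # per chain, post-adaptation
    divergences: int
    inv_mass: np.ndarray         # (n_chains, dim)


def _leapfrog(q, p, eps, inv_mass, logp_grad, n_steps):
    _, grad = logp_grad(q)
    p = p + 0.5 * eps[:, None] * grad
    for step in range(n_steps):
        q = q + eps[:, None] * (inv_mass * p)
        logp, grad = logp_grad(q)
        if step < n_steps - 1:
            p = p + eps[:, None] * grad
    p = p + 0.5 * eps[:, None] * grad
    return q, p, logp


def sample(
    logp_grad: LogpGrad,
    q0: np.ndarray,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int | None = None,
    max_leapfrog: int = 24,
    target_accept: float = 0.85,
    init_step: float | None = None,
) -> HmcResult:
    """Run HMC from per-chain initial positions ``q0`` of shape (C, D).

    Warmup schedule: dual averaging of the step size throughout; positions
    from the middle window (30%–80% of warmup) feed a diagonal mass-matrix
    estimate, after which dual averaging restarts.  A proposal whose energy
    error exceeds 1000 counts as divergent and is rejected.
    """
    rng = default_rng(seed)
    q = np.array(q0, dtype=float)
    n_chains, dim = q.shape
    inv_mass = np.ones((n_chains, dim))

    eps = np.full(n_chains, init_step if init_step is not None else 0.1 / dim**0.25)
    mu = np.log(10.0 * eps)
    log_eps_bar = np.log(eps)
    h_bar = np.zeros(n_chains)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    logp, _ = logp_grad(q)
    if not np.all(np.isfinite(logp)):
        raise ValueError("non-finite log density at the initial position")

    window_lo, window_hi = int(0.3 * n_warmup), int(0.8 * n_warmup)
    window: list[np.ndarray] = []
    draws = np.empty((n_chains, n_draws, dim))
    accepts = np.zeros(n_chains)
    divergences = 0

    total = n_warmup + n_draws
    # silence overflow from occasional unstable proposals; they are rejected
    old_err = np.seterr(over="ignore", invalid="ignore", under="ignore")
    for it in range(total):
        warm = it < n_warmup
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        p = rng.standard_normal((n_chains, dim)) / np.sqrt(inv_mass)
        h0 = -logp + 0.5 * ((p * p) * inv_mass).sum(axis=1)
        q_new, p_new, logp_new = _leapfrog(q, p, eps, inv_mass, logp_grad, n_steps)
        h1 = -logp_new + 0.5 * ((p_new * p_new) * inv_mass).sum(axis=1)
        delta = h0 - h1
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        divergent = delta < -1000.0
        divergences += int(np.sum(divergent & ~warm))
        alpha = np.minimum(1.0, np.exp(np.minimum(delta, 0.0)))
        alpha = np.where(divergent, 0.0, alpha)
        accept = rng.uniform(size=n_chains) < alpha
        q = np.where(accept[:, None], q_new, q)
        logp = np.where(accept, logp_new, logp)

        if warm:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (target_accept - alpha) / (
                da_iter + t0
            )
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if window_lo <= it < window_hi:
                window.append(q.copy())
            if it == window_hi - 1 and len(window) >= 10:
                arr = np.stack(window, axis=1)  # (C, W, D)
                var = arr.var(axis=1, ddof=1)
                w_n = arr.shape[1]
                inv_mass = (w_n / (w_n + 5.0)) * var + 1e-3 * (5.0 / (w_n + 5.0))
                # restart step-size adaptation around the current average
                eps = np.exp(log_eps_bar)
                mu = np.log(10.0 * eps)
                h_bar = np.zeros(n_chains)
                da_iter = 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            draws[:, it - n_warmup, :] = q
            accepts += accept

    np.seterr(**old_err)
    return HmcResult(
        draws=draws,
        accept_rate=accepts / n_draws,
        step_size=eps,
        divergences=divergences,
        inv_mass=inv_mass,
    )
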