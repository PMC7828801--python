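"""Descriptive Bayesian models: conjugate beta-binomial gender shares and
robust Student-t hierarchical pooling of subarea SMRs.

The beta-binomial model treats the yearly male share of deaths as
``y ~ Binomial(π, n)`` with conjugate prior ``π ~ Beta(1, 3)``; posterior
inference is closed form.  The pooling model judges whether the mean SMRs
of the subareas differ: for each value s² on a 100-point scale grid, the
subarea-year mean SMRs follow a Student-t(ν = 10) likelihood with location
θ_s and scale σ, with ``θ_s ~ N(1, 1)`` and ``σ² ~ Scaled-Inv-χ²(10, s²)``.
The two-parameter posterior is computed by grid quadrature (deterministic),
and subareas are called "not significantly different" when their 95%
intervals for θ_s overlap at every grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import special, stats


@dataclass
class BetaBinomialResult:
    a: float
    b: float
    mean: float
    ci_low: float
    ci_high: float
    prob_gt_half: float


def beta_binomial_update(
    y: int, n: int, a0: float = 1.0, b0: float = 3.0
) -> BetaBinomialResult:
    """Conjugate update ``Beta(a0 + y, b0 + n − y)`` with summaries.

    Returns the posterior shapes, mean, central 95% interval and
    ``P(π > 0.5)`` via the regularised incomplete beta function.
    """
    if not (0 <= y <= n):
        raise ValueError("require 0 <= y <= n")
    a, b = a0 + y, b0 + n - y
    lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    return BetaBinomialResult(
        a=a,
        b=b,
        mean=a / (a + b),
        ci_low=float(lo),
        ci_high=float(hi),
        prob_gt_half=float(1.0 - special.betainc(a, b, 0.5)),
    )


def gender_trend_pp(
    yearly_counts: pd.DataFrame,
    a0: float = 1.0,
    b0: float = 3.0,
    n_draws: int = 100_000,
    seed: int | None = None,
    band: tuple[float, float] = (0.05, 0.95),
) -> tuple[pd.DataFrame, bool]:
    """Pairwise posterior probabilities that the male death share differs by year.

    ``yearly_counts`` has columns ``year``, ``y`` (male deaths) and ``n``
    (total deaths).  For each ordered year pair, ``P(π_t > π_u)`` is estimated
    from independent Monte-Carlo draws of the two conjugate posteriors.  The
    verdict is "no trend" (True) when every pairwise probability lies inside
    the ``band``.
    """
    if len(yearly_counts) < 2:
        raise ValueError("need at least two years")
    rng = default_rng(seed)
    draws = {}
    for r in yearly_counts.itertuples(index=False):
        post = beta_binomial_update(r.y, r.n, a0, b0)
        draws[int(r.year)] = rng.beta(post.a, post.b, size=n_draws)
    years = sorted(draws)
    rows = []
    no_trend = True
    for t in years:
        for u in years:
            if t >= u:
                continue
            pp = float(np.mean(draws[t] > draws[u]))
            rows.append((t, u, pp))
            if not (band[0] < pp < band[1]):
                no_trend = False
    table = pd.DataFrame(rows, columns=["year_t", "year_u", "pp_t_gt_u"])
    return table, no_trend


# ---------------------------------------------------------------------------
# robust hierarchical pooling
# ---------------------------------------------------------------------------


def _scaled_inv_chi2_logpdf(sigma2: np.ndarray, nu: float, s2: float) -> np.ndarray:
    """log density of Scaled-Inv-χ²(ν, s²) = Inv-Gamma(ν/2, ν·s²/2)."""
    a = nu / 2.0
    b = nu * s2 / 2.0
    return a * np.log(b) - special.gammaln(a) - (a + 1.0) * np.log(sigma2) - b / sigma2


@dataclass
class PoolingResult:
    """Posterior summaries of the pooled mean per subarea and grid scale."""

    table: pd.DataFrame          # subarea, scale, theta_median, theta_lo, theta_hi, sigma2_median
    scale_grid: np.ndarray
    overlap: bool                # True: 95% intervals overlap at every grid point


def _quantile_from_grid(grid: np.ndarray, pmf: np.ndarray, qs) -> np.ndarray:
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    return np.interp(qs, cdf, grid)


def robust_pool_subareas(
    smr_delta: pd.DataFrame,
    nu: int = 10,
    scale_grid: np.ndarray | None = None,
    prior_mean: float = 1.0,
    prior_sd: float = 1.0,
    n_theta: int = 241,
    n_sigma: int = 161,
) -> PoolingResult:
    """Robust pooling of subarea-year mean SMRs on a grid of prior scales.

    ``smr_delta`` has columns ``subarea``, ``year``, ``smr`` (the unweighted
    mean of area SMRs in the subarea-year).  For every scale s² in
    ``scale_grid`` (default: 100 equally spaced values in [0.1, 1.5]) the
    posterior of (θ_s, σ²) under the Student-t(ν) likelihood is evaluated by
    quadrature and θ_s is summarised by its median and central 95% interval.
    """
    if scale_grid is None:
        scale_grid = np.linspace(0.1, 1.5, 100)
    scale_grid = np.asarray(scale_grid, dtype=float)
    groups = {
        str(sub): g["smr"].to_numpy(dtype=float)
        for sub, g in smr_delta.groupby("subarea")
    }
    n_obs_total = sum(len(v) for v in groups.values())
    if n_obs_total < 2:
        raise ValueError("need at least two subarea-year SMR means")

    all_x = np.concatenate(list(groups.values()))
    spread = max(float(all_x.std()), 0.05)
    t_lo = min(prior_mean, all_x.min()) - max(6 * spread, 1.5)
    t_hi = max(prior_mean, all_x.max()) + max(6 * spread, 1.5)
    theta = np.linspace(t_lo, t_hi, n_theta)
    # σ² grid wide enough for every prior scale and for the data spread
    lam = np.linspace(np.log(2e-3), np.log(30.0), n_sigma)  # log σ²
    sigma2 = np.exp(lam)
    sigma = np.sqrt(sigma2)

    rows = []
    for sub, x in sorted(groups.items()):
        # log-likelihood grid, shared across prior scales
        zs = (x[None, None, :] - theta[:, None, None]) / sigma[None, :, None]
        loglik = (
            stats.t.logpdf(zs, df=nu).sum(axis=2) - len(x) * np.log(sigma)[None, :]
        )
        log_prior_theta = stats.norm.logpdf(theta, prior_mean, prior_sd)
        for s2 in scale_grid:
            log_prior_lam = _scaled_inv_chi2_logpdf(sigma2, nu, s2) + lam  # + Jacobian
            logpost = loglik + log_prior_theta[:, None] + log_prior_lam[None, :]
            logpost -= logpost.max()
            post = np.exp(logpost)
            theta_marg = post.sum(axis=1)
            lam_marg = post.sum(axis=0)
            lo, med, hi = _quantile_from_grid(theta, theta_marg, [0.025, 0.5, 0.975])
            s2_med = float(_quantile_from_grid(sigma2, lam_marg, [0.5])[0])
            rows.append((sub, float(s2), float(med), float(lo), float(hi), s2_med))
    table = pd.DataFrame(
        rows,
        columns=["subarea", "scale", "theta_median", "theta_lo", "theta_hi", "sigma2_median"],
    )
    overlap = True
    for s2, g in table.groupby("scale"):
        if g["theta_lo"].max() > g["theta_hi"].min():
            overlap = False
            break
    return PoolingResult(table=table, scale_grid=scale_grid, overlap=overlap)


def subarea_mean_smr(smr: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of area SMRs per subarea-year.

    ``smr`` needs columns ``area_id``, ``year``, ``smr``; ``areas`` maps
    ``area_id`` to ``subarea``.
    """
    m = smr.merge(areas[["area_id", "subarea"]], on="area_id")
    return (
        m.groupby(["subarea", "year"], as_index=False)["smr"]
        .mean()
        .sort_values(["subarea", "year"], ignore_index=True)
    )
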