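"""WAIC and PSIS-LOO from per-observation log-likelihood draws, and
pairwise model comparison with Bonferroni-corrected normal tests.

Both criteria are reported on the deviance scale (−2 · elpd, lower is
better).  WAIC uses the variance-based effective-parameter count,
``p_waic = Σ_i Var_d(ll_di)`` with the n−1 sample variance; its standard
error comes from the spread of the pointwise elpd contributions,
``SE = 2·sqrt(n · Var_i(elpd_i))``.  LOO is Pareto-smoothed importance
sampling (PSIS); observations with Pareto shape k > 0.7 are flagged.
Pairwise differences use the pointwise elpd contributions, so the SE of a
difference accounts for the shared observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


@dataclass
class InformationCriteria:
    kind: str                    # "waic" or "loo"
    value: float                 # deviance scale, -2 * elpd
    se: float
    elpd: float
    p_eff: float
    elpd_i: np.ndarray           # pointwise elpd, (n_obs,)
    n_obs: int
    n_draws: int
    pareto_k: np.ndarray | None = None

    @property
    def n_bad_k(self) -> int:
        if self.pareto_k is None:
            return 0
        return int(np.sum(self.pareto_k > 0.7))


def _as_matrix(loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 3:  # (chains, draws, obs)
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("loglik must be (draws, obs) or (chains, draws, obs)")
    if ll.shape[0] < 2:
        raise ValueError("need at least two posterior draws")
    if ll.shape[1] < 1:
        raise ValueError("need at least one observation")
    return ll


def compute_waic(loglik: np.ndarray) -> InformationCriteria:
    """Widely applicable information criterion from log-likelihood draws."""
    ll = _as_matrix(loglik)
    S, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    elpd = float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    return InformationCriteria(
        kind="waic",
        value=-2.0 * elpd,
        se=se,
        elpd=elpd,
        p_eff=float(p_i.sum()),
        elpd_i=elpd_i,
        n_obs=n,
        n_draws=S,
    )


def compute_loo(loglik: np.ndarray, reff: float = 1.0) -> InformationCriteria:
    """Pareto-smoothed importance-sampling LOO (PSIS-LOO).

    The raw importance ratios are 1/p(y_i | θ_d); their log weights are
    smoothed with arviz's PSIS routine, and elpd_i is the smoothed
    self-normalised importance-sampling estimate of log p(y_i | y_−i).
    """
    ll = _as_matrix(loglik)
    from arviz.stats import psislw

    S, n = ll.shape
    lw, k = psislw(-ll.T, reff=reff)  # (n_obs, S), normalised log weights
    elpd_i = logsumexp(lw + ll.T, axis=1)
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    elpd = float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    return InformationCriteria(
        kind="loo",
        value=-2.0 * elpd,
        se=se,
        elpd=elpd,
        p_eff=float((lppd_i - elpd_i).sum()),
        elpd_i=np.asarray(elpd_i),
        n_obs=n,
        n_draws=S,
        pareto_k=np.asarray(k, dtype=float),
    )


@dataclass
class ComparisonTable:
    models: pd.DataFrame         # per-model criterion, SE, p_eff
    pairs: pd.DataFrame          # pairwise difference, SE, z, p, Bonferroni p
    best: str
    criterion: str


def compare_models(criteria: dict[str, InformationCriteria]) -> ComparisonTable:
    """Pairwise comparison of models fit to the identical observations.

    Differences are on the deviance scale; the SE of each difference is
    computed from the pointwise elpd contributions, the two-sided normal p
    is Bonferroni-corrected over the number of pairs, and the best model is
    the one with the lowest criterion.
    """
    names = list(criteria)
    if len(names) < 1:
        raise ValueError("no models to compare")
    n_obs = {criteria[m].n_obs for m in names}
    if len(n_obs) != 1:
        raise ValueError("models were fit to different observation sets")
    kinds = {criteria[m].kind for m in names}
    if len(kinds) != 1:
        raise ValueError("cannot mix WAIC and LOO in one comparison")
    kind = kinds.pop()
    n = n_obs.pop()

    models = pd.DataFrame(
        [
            (m, criteria[m].value, criteria[m].se, criteria[m].p_eff)
            for m in names
        ],
        columns=["model", kind, "se", "p_eff"],
    )
    rows = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            di = criteria[a].elpd_i - criteria[b].elpd_i
            diff = -2.0 * float(di.sum())  # criterion(a) - criterion(b)
            se = 2.0 * float(np.sqrt(n * di.var(ddof=1))) if n > 1 else 0.0
            if se > 0:
                z = diff / se
                p = 2.0 * float(stats.norm.sf(abs(z)))
            else:
                z, p = 0.0, 1.0
            if a == b:
                diff, se, z, p = 0.0, 0.0, 0.0, 1.0
            rows.append((a, b, diff, se, z, p, min(1.0, p * max(n_pairs, 1))))
    pairs = pd.DataFrame(
        rows, columns=["model_a", "model_b", "diff", "se_diff", "z", "p", "p_bonferroni"]
    )
    best = models.sort_values(kind, kind="stable").iloc[0]["model"]
    return ComparisonTable(models=models, pairs=pairs, best=str(best), criterion=kind)
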