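"""Tests for WAIC, PSIS-LOO and pairwise model comparison.

The exact-refit oracle is a conjugate Gamma–Poisson model: with
``y_i ~ Poisson(λ)`` and ``λ ~ Gamma(a0, b0)`` the leave-one-out predictive
is negative-binomial in closed form, so PSIS-LOO from posterior draws can be
checked against exact leave-one-out refits.
"""

import math

import numpy as np
import pytest
from scipy import special, stats

from dismap.selection import compare_models, compute_loo, compute_waic


def _gamma_poisson_loglik(y, n_draws=4000, a0=2.0, b0=1.0, seed=0):
    """Posterior draws and the (draws, obs) log-likelihood matrix."""
    rng = np.random.default_rng(seed)
    a, b = a0 + y.sum(), b0 + len(y)
    lam = rng.gamma(a, 1.0 / b, size=n_draws)
    return stats.poisson.logpmf(y[None, :], lam[:, None])


def _exact_loo_elpd(y, a0=2.0, b0=1.0):
    """Σ_i log p(y_i | y_−i) from conjugate leave-one-out refits."""
    total = 0.0
    n = len(y)
    for i in range(n):
        a = a0 + y.sum() - y[i]
        b = b0 + n - 1
        total += (
            special.gammaln(a + y[i])
            - special.gammaln(a)
            - special.gammaln(y[i] + 1)
            + a * math.log(b / (b + 1))
            - y[i] * math.log(b + 1)
        )
    return total


class TestWaic:
    def test_hand_computed_two_draw_case(self):
        ll = np.array([[math.log(0.5)], [math.log(0.25)]])
        res = compute_waic(ll)
        assert res.value == pytest.approx(2.4421, abs=1e-4)
        assert res.p_eff == pytest.approx(0.5 * math.log(2.0) ** 2, abs=1e-9)

    def test_degenerate_posterior(self):
        ll = np.tile(np.array([[-1.0, -2.0, -0.5]]), (10, 1))
        res = compute_waic(ll)
        assert res.p_eff == 0.0
        assert res.value == pytest.approx(-2 * ll[0].sum())

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            compute_waic(np.array([[-1.0, -2.0]]))

    def test_additive_over_independent_blocks(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-2, 0.4, size=(500, 30))
        total = compute_waic(ll).value
        parts = compute_waic(ll[:, :12]).value + compute_waic(ll[:, 12:]).value
        assert total == pytest.approx(parts, abs=1e-9)

    def test_accepts_chain_shaped_input(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-2, 0.3, size=(4, 200, 10))
        assert compute_waic(ll).value == pytest.approx(
            compute_waic(ll.reshape(-1, 10)).value
        )


class TestLoo:
    def test_degenerate_posterior_equals_waic(self):
        ll = np.tile(np.array([[-1.0, -2.0, -0.5]]), (10, 1))
        assert compute_loo(ll).value == pytest.approx(compute_waic(ll).value)

    def test_psis_matches_exact_refits_at_n20(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(4.0, size=20)
        ll = _gamma_poisson_loglik(y, seed=4)
        res = compute_loo(ll)
        assert abs(res.elpd - _exact_loo_elpd(y)) < 0.5

    def test_well_specified_model_has_good_pareto_k(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(4.0, size=20)
        res = compute_loo(_gamma_poisson_loglik(y, seed=6))
        assert res.pareto_k.shape == (20,)
        assert (res.pareto_k < 0.7).all()

    def test_waic_loo_asymptotic_agreement(self):
        rng = np.random.default_rng(7)
        y = rng.poisson(6.0, size=50)
        ll = _gamma_poisson_loglik(y, seed=8)
        w, l = compute_waic(ll), compute_loo(ll)
        assert abs(w.value - l.value) <= 2 * (w.se + l.se)


class TestComparison:
    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, size=15)
        a = compute_waic(_gamma_poisson_loglik(y, seed=1))
        tab = compare_models({"A": a, "A2": a})
        row = tab.pairs.iloc[0]
        assert row["diff"] == 0.0 and row["se_diff"] == 0.0

    def test_antisymmetric_differences(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(3.0, size=15)
        a = compute_waic(_gamma_poisson_loglik(y, seed=2))
        b = compute_waic(_gamma_poisson_loglik(y, n_draws=3000, seed=3))
        d_ab = compare_models({"A": a, "B": b}).pairs.iloc[0]["diff"]
        d_ba = compare_models({"B": b, "A": a}).pairs.iloc[0]["diff"]
        assert d_ab == pytest.approx(-d_ba)

    def test_mismatched_observations_rejected(self):
        rng = np.random.default_rng(2)
        a = compute_waic(rng.normal(-2, 0.3, size=(200, 10)))
        b = compute_waic(rng.normal(-2, 0.3, size=(200, 12)))
        with pytest.raises(ValueError):
            compare_models({"A": a, "B": b})

    def test_refits_of_same_model_are_not_significant(self):
        """Two independent draw sets from one posterior: Bonferroni p > 0.05
        in at least 18 of 20 replicates.

        The refitted model has independent per-observation parameters
        (saturated Poisson means), so the Monte-Carlo error of the pointwise
        elpd values is independent across observations and the comparison's
        normal test is calibrated under the null.
        """

        def saturated_loglik(y, seed, n_draws=4000, a0=2.0, b0=1.0):
            rng = np.random.default_rng(seed)
            lam = rng.gamma(a0 + y[None, :], 1.0 / (b0 + 1), size=(n_draws, len(y)))
            return stats.poisson.logpmf(y[None, :], lam)

        rng = np.random.default_rng(3)
        ok = 0
        for r in range(20):
            y = rng.poisson(5.0, size=100)
            a = compute_loo(saturated_loglik(y, seed=100 + r))
            b = compute_loo(saturated_loglik(y, seed=5200 + r))
            p = compare_models({"A": a, "B": b}).pairs.iloc[0]["p_bonferroni"]
            ok += p > 0.05
        assert ok >= 18

    def test_best_model_has_lowest_criterion(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(3.0, size=15)
        ll = _gamma_poisson_loglik(y, seed=5)
        a = compute_waic(ll)
        b = compute_waic(ll - 0.5)  # uniformly worse fit
        assert compare_models({"good": a, "bad": b}).best == "good"
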