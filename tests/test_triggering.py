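"""Step probabilities, backward recursion, and the scaled triggering rate."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrtrigger import (
    ChainStepProbabilities,
    ScaledParameters,
    solve_equilibrium,
    step_probabilities,
    triggering_probabilities,
    triggering_rate,
    w_of_alpha,
)


def make_params(**overrides) -> ScaledParameters:
    base = dict(m_T=10, x_T=50, r_T=10, alpha=2.5, delta=300, nu=0.5,
                kappa=5, gamma_off=0.5, gamma_kin=0.5, gamma_R=0.3, n=100)
    base.update(overrides)
    return ScaledParameters(**base)


class TestStepProbabilities:
    def test_no_cd8_gives_single_lane(self):
        p = make_params()
        s = step_probabilities(p, 0.0)
        assert s.Pb0 == 0.0
        assert s.Pa0 == pytest.approx(p.n / (p.n + p.alpha), rel=1e-15)

    def test_zero_delta_never_switches_back(self):
        s = step_probabilities(make_params(delta=0.0), 3.0)
        assert s.Pb_star == 0.0

    def test_hand_evaluated_reference_point(self):
        # alpha=2.5, nu*x=1, n=100, gamma_R=0.3, gamma_off=0.5, delta=300:
        # unbound lane total = 2.5 + 100 + 1 = 103.5;
        # bound lane total = 0.5*2.5 + 100/0.3 + 300 = 634.58333...
        p = make_params(nu=0.5)
        s = step_probabilities(p, x=2.0)  # nu * x = 1
        assert s.Pa0 == pytest.approx(100.0 / 103.5, rel=1e-14)
        assert s.Pb0 == pytest.approx(1.0 / 103.5, rel=1e-14)
        total_star = 1.25 + 100.0 / 0.3 + 300.0
        assert s.Pa_star == pytest.approx((100.0 / 0.3) / total_star, rel=1e-14)
        assert s.Pb_star == pytest.approx(300.0 / total_star, rel=1e-14)

    def test_probabilities_sum_below_one(self):
        s = step_probabilities(make_params(), 10.0)
        assert 0.0 < s.Pa0 + s.Pb0 < 1.0
        assert 0.0 < s.Pa_star + s.Pb_star < 1.0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            step_probabilities(make_params(), -1.0)


class TestTriggeringProbabilities:
    def test_single_step_without_switching(self):
        s = ChainStepProbabilities(Pa0=0.7, Pa_star=0.9, Pb0=0.0, Pb_star=0.0)
        P00, P0s, _, _ = triggering_probabilities(s, 1)
        assert P00 == pytest.approx(0.7, abs=1e-15)
        assert P0s == pytest.approx(0.9, abs=1e-15)

    @pytest.mark.parametrize("n,alpha", [(1, 2.5), (10, 0.3), (100, 2.5), (1000, 5.0)])
    def test_classical_proofreading_closed_form(self, n, alpha):
        # with no CD8 association the unbound lane is the McKeithan chain
        p = make_params(n=n, alpha=alpha)
        s = step_probabilities(p, 0.0)
        P00, _, _, _ = triggering_probabilities(s, n)
        assert P00 == pytest.approx((n / (n + alpha)) ** n, abs=1e-14)

    def test_exponential_limit_of_long_chains(self):
        # P00 -> exp(-alpha) as n -> infinity at fixed alpha
        p = make_params(n=10**4, alpha=2.0)
        s = step_probabilities(p, 0.0)
        P00, _, _, _ = triggering_probabilities(s, p.n)
        assert abs(P00 - math.exp(-2.0)) < 1e-3

    def test_boundary_condition_and_monotone_chain(self):
        p = make_params()
        s = step_probabilities(p, 5.0)
        _, _, chain0, chain_star = triggering_probabilities(s, p.n)
        assert chain0[-1] == 1.0 and chain_star[-1] == 1.0
        assert np.all(np.diff(chain0) >= -1e-15)
        assert np.all(np.diff(chain_star) >= -1e-15)
        assert np.all((chain0 >= 0) & (chain0 <= 1))
        assert np.all((chain_star >= 0) & (chain_star <= 1))

    def test_degenerate_switching_rejected(self):
        s = ChainStepProbabilities(Pa0=0.0, Pa_star=0.0, Pb0=1.0, Pb_star=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            triggering_probabilities(s, 5)

    @given(alpha_lo=st.floats(0.1, 5.0), bump=st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_success_probability_decreases_with_off_rate(self, alpha_lo, bump):
        p = make_params()
        eq = solve_equilibrium(p)
        lo = triggering_probabilities(
            step_probabilities(p.replace(alpha=alpha_lo), eq.x), p.n)[0]
        hi = triggering_probabilities(
            step_probabilities(p.replace(alpha=alpha_lo + bump), eq.x), p.n)[0]
        assert hi < lo


class TestTriggeringRate:
    def test_no_receptors_no_triggering(self):
        res = triggering_rate(make_params(r_T=0.0))
        assert res.w == 0.0
        assert res.equilibrium.eps == 0.0 and res.equilibrium.zeta == 0.0

    def test_vanishing_off_rate_vanishing_rate(self):
        # w = alpha * (...) with the bracket bounded by 1
        res = triggering_rate(make_params(alpha=1e-12))
        assert res.w < 1e-11
        assert res.P00 > 0.99

    def test_rate_positive_with_receptors(self):
        res = triggering_rate(make_params())
        assert res.w > 0.0
        assert 0.0 < res.P00 <= 1.0 and 0.0 < res.P0_star <= 1.0

    def test_composition_is_consistent(self):
        p = make_params()
        res = triggering_rate(p)
        eq = res.equilibrium
        expected = p.alpha * (eq.eps * res.P00 + eq.zeta * p.gamma_off * res.P0_star)
        assert res.w == pytest.approx(expected, rel=1e-14)


class TestVectorisedW:
    def test_matches_scalar_path(self):
        p = make_params()
        alphas = np.array([0.3, 1.0, 2.5, 10.0, 40.0])
        wv = w_of_alpha(p, alphas)
        for a, w in zip(alphas, wv):
            assert w == pytest.approx(triggering_rate(p.replace(alpha=a)).w,
                                      rel=1e-12)

    def test_sensitivity_dips_at_intermediate_cd8(self):
        # the hallmark nonmonotonicity: w(x_T) has an interior minimum
        p = make_params(alpha=2.5)
        grid = np.linspace(1.0, 200.0, 100)
        w = np.array([triggering_rate(p.replace(x_T=float(v))).w for v in grid])
        k = int(np.argmin(w))
        assert 0 < k < len(grid) - 1
        assert w[k] < w[0] and w[k] < w[-1]
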