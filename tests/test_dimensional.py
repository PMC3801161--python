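"""Dimensional layer: scaling bridge, bound densities, mutant scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from tcrtrigger import (
    HLA_A2_MUTANTS,
    DimensionalKinetics,
    MutantScenario,
    ScaledParameters,
    apply_mutant,
    bound_densities,
    mutant_scenarios,
    solve_equilibrium,
    to_scaled,
    triggering_rate,
    triggering_rate_forms,
)
from tcrtrigger.dimensional import densities_affinity_form, densities_gamma_form


def random_kinetics(rng: np.random.Generator) -> DimensionalKinetics:
    """Random detailed-balanced kinetics with CD8-enhancing modulation."""
    Lambda1 = rng.uniform(1e-12, 1e-10)
    gamma_on = rng.uniform(1.0, 2.0)
    gamma_off = rng.uniform(0.3, 1.0)
    lambda_m1 = rng.uniform(0.05, 2.0)
    T_R = rng.uniform(5.0, 15.0)
    return DimensionalKinetics.consistent(
        Lambda1=Lambda1,
        Lambda2=rng.uniform(1e-12, 1e-10),
        Lambda3=rng.uniform(1e-12, 1e-10),
        Lambda4=gamma_on * Lambda1,
        lambda_m1=lambda_m1,
        lambda_m3=rng.uniform(0.05, 2.0),
        lambda_m4=gamma_off * lambda_m1,
        M_T=rng.uniform(1e9, 1e11),
        X_T=rng.uniform(0.0, 1e12),
        R_T=rng.uniform(1e9, 1e11),
        T_R=T_R,
        T_R_star=T_R * rng.uniform(0.2, 1.0),
    )


class TestKineticsConstruction:
    def test_detailed_balance_enforced(self, rng):
        kin = random_kinetics(rng)
        assert kin.K1 * kin.K2 == pytest.approx(kin.K3 * kin.K4, rel=1e-12)

    def test_inconsistent_rates_rejected(self, rng):
        kin = random_kinetics(rng)
        data = kin.model_dump()
        data["lambda_m2"] = kin.lambda_m2 * 1.7
        with pytest.raises(ValueError, match="detailed balance"):
            DimensionalKinetics(**data)

    def test_faster_phosphorylation_with_cd8_required(self, rng):
        kin = random_kinetics(rng)
        data = kin.model_dump()
        data["T_R_star"] = data["T_R"] * 2.0
        with pytest.raises(ValueError, match="T_R_star"):
            DimensionalKinetics(**data)


class TestToScaled:
    def test_equal_dissociation_constants_give_unit_kappa(self, rng):
        kin = random_kinetics(rng)
        data = kin.model_dump()
        # force K3 = K1 by setting lambda_m3 = K1 * Lambda3, rebalancing m2
        data.pop("lambda_m2")
        data["lambda_m3"] = kin.K1 * data["Lambda3"]
        kin2 = DimensionalKinetics.consistent(**data)
        assert to_scaled(kin2).kappa == pytest.approx(1.0, rel=1e-12)

    def test_dwell_time_at_threshold_gives_unit_alpha(self, rng):
        kin = random_kinetics(rng)
        data = kin.model_dump()
        data.pop("lambda_m2")
        lm1 = 1.0 / data["T_R"]
        data["lambda_m4"] = data["lambda_m4"] / data["lambda_m1"] * lm1
        data["lambda_m1"] = lm1
        kin2 = DimensionalKinetics.consistent(**data)
        assert to_scaled(kin2).alpha == pytest.approx(1.0, rel=1e-12)

    def test_scaled_set_is_thermodynamically_consistent(self, rng):
        p = to_scaled(random_kinetics(rng))
        assert p.delta / p.nu == pytest.approx(p.gamma_kin, rel=1e-10)

    def test_occupancies_round_trip(self, rng):
        # scaled fractions times M_T must equal the dimensional densities
        for _ in range(25):
            kin = random_kinetics(rng)
            p = to_scaled(kin)
            eq = solve_equilibrium(p)
            bd = bound_densities(kin)
            assert bd.M_R == pytest.approx(kin.M_T * eq.eps, rel=1e-10)
            assert bd.M_X == pytest.approx(kin.M_T * eq.frac_MX, rel=1e-10)
            assert bd.M_XR == pytest.approx(kin.M_T * eq.zeta, rel=1e-10)

    def test_scaled_w_matches_dimensional_W(self, rng):
        # w = W / (K1 m_T lambda)
        for _ in range(10):
            kin = random_kinetics(rng)
            p = to_scaled(kin)
            w = triggering_rate(p).w
            _, W = triggering_rate_forms(kin)
            assert w == pytest.approx(W * kin.T_R / kin.M_T, rel=1e-10)


class TestBoundDensities:
    def test_no_cd8_no_ternary_complexes(self, rng):
        kin = random_kinetics(rng)
        kin = DimensionalKinetics(**{**kin.model_dump(), "X_T": 0.0})
        bd = bound_densities(kin)
        assert bd.M_X == 0.0 and bd.M_XR == 0.0

    def test_no_tcr_no_triggering(self, rng):
        kin = random_kinetics(rng)
        kin = DimensionalKinetics(**{**kin.model_dump(), "R_T": 0.0})
        bd = bound_densities(kin)
        assert bd.M_R == 0.0 and bd.M_XR == 0.0 and bd.W == 0.0

    def test_conservation_laws(self, rng):
        for _ in range(25):
            kin = random_kinetics(rng)
            bd = bound_densities(kin)
            assert bd.M + bd.M_R + bd.M_X + bd.M_XR == pytest.approx(
                kin.M_T, rel=1e-10)
            assert bd.X + bd.M_X + bd.M_XR == pytest.approx(kin.X_T, rel=1e-10)
            assert bd.R + bd.M_R + bd.M_XR == pytest.approx(kin.R_T, rel=1e-10)

    def test_detailed_balance_at_equilibrium(self, rng):
        for _ in range(10):
            kin = random_kinetics(rng)
            bd = bound_densities(kin)
            # each elementary reaction individually balanced
            assert kin.Lambda1 * bd.R * bd.M == pytest.approx(
                kin.lambda_m1 * bd.M_R, rel=1e-9)
            assert kin.Lambda2 * bd.X * bd.M_R == pytest.approx(
                kin.lambda_m2 * bd.M_XR, rel=1e-9)
            assert kin.Lambda3 * bd.X * bd.M == pytest.approx(
                kin.lambda_m3 * bd.M_X, rel=1e-9)
            assert kin.Lambda4 * bd.R * bd.M_X == pytest.approx(
                kin.lambda_m4 * bd.M_XR, rel=1e-9)

    def test_affinity_and_gamma_forms_agree(self, rng):
        for _ in range(25):
            kin = random_kinetics(rng)
            bd = bound_densities(kin)
            a = densities_affinity_form(kin, bd.X, bd.R)
            g = densities_gamma_form(kin, bd.X, bd.R)
            for ai, gi in zip(a, g):
                assert ai == pytest.approx(gi, rel=1e-12)

    def test_association_and_dissociation_W_forms_agree(self, rng):
        for _ in range(10):
            kin = random_kinetics(rng)
            W_assoc, W_dissoc = triggering_rate_forms(kin)
            assert W_assoc == pytest.approx(W_dissoc, rel=1e-10)


class TestMutants:
    def test_builtin_table(self):
        assert HLA_A2_MUTANTS["A245V"] == 498.0
        assert HLA_A2_MUTANTS["wild-type"] == 137.1
        assert HLA_A2_MUTANTS["Q115E"] == 97.94
        assert HLA_A2_MUTANTS["A2/a3kb"] == 10.87

    def test_reference_has_unit_rho(self):
        scans = {s.name: s for s in mutant_scenarios()}
        assert scans["wild-type"].rho == 1.0

    def test_identity_scenario_is_noop(self, fig2_params):
        scen = MutantScenario(name="custom", K_D=137.1, rho=1.0)
        assert apply_mutant(fig2_params, scen) == fig2_params

    def test_k3_rescaling_rule(self, fig2_params):
        rho = 10.87 / 137.1
        p = apply_mutant(fig2_params, MutantScenario("A2/a3kb", 10.87, rho))
        assert p.kappa == pytest.approx(fig2_params.kappa * 137.1 / 10.87)
        assert p.x_T == pytest.approx(fig2_params.x_T * 137.1 / 10.87)
        assert p.nu == pytest.approx(fig2_params.nu * 10.87 / 137.1)
        assert p.alpha == fig2_params.alpha and p.m_T == fig2_params.m_T

    def test_weak_cd8_binding_lowers_effective_cd8(self, fig2_params):
        rho = 498.0 / 137.1
        p = apply_mutant(fig2_params, MutantScenario("A245V", 498.0, rho))
        assert p.x_T < fig2_params.x_T

    def test_group_action_composition(self, fig2_params):
        a = MutantScenario("a", 100.0, 2.0)
        b = MutantScenario("b", 100.0, 3.5)
        ab = MutantScenario("ab", 100.0, 7.0)
        left = apply_mutant(apply_mutant(fig2_params, a), b)
        right = apply_mutant(fig2_params, ab)
        assert left.kappa == pytest.approx(right.kappa, rel=1e-14)
        assert left.x_T == pytest.approx(right.x_T, rel=1e-14)
        assert left.nu == pytest.approx(right.nu, rel=1e-14)

    def test_nonpositive_rho_rejected(self):
        with pytest.raises(ValueError):
            MutantScenario("bad", 100.0, -1.0)
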