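"""Fixed-point solver: closed forms, brackets, and the ODE oracle."""

import numpy as np
import pytest

from clvwus import (ParameterSet, apply_genotype, integrate_to_steady_state,
                    lumped_rates, rhs, solve_equilibrium, solve_free_species,
                    wus_residual)
from clvwus.equilibrium import solve_equilibrium_model

from conftest import random_parameter_set


def decoupled_params(rng) -> ParameterSet:
    """Binding and feedback switched off (k1, k4, kW tiny): every
    species relaxes to its production/turnover balance and WUS* has a
    closed form."""
    p = random_parameter_set(rng)
    return p.with_overrides(k1=1e-12, k4=1e-12, kW=1e-12)


def closed_form_wus(p: ParameterSet) -> float:
    x = p.s4
    return p.k7 / p.dW / (1.0 + (x / p.K) ** p.n)


class TestFreeSpecies:
    def test_decoupled_balance(self, rng):
        p = decoupled_params(rng)
        m = apply_genotype(p, "wild_type")
        c1, c2, c3 = solve_free_species(m, wus=1.0)
        assert c1 == pytest.approx(p.s1, abs=1e-6)
        assert c2 == pytest.approx(p.s2, abs=1e-6)
        assert c3 == pytest.approx(p.s3, abs=1e-6)

    def test_removed_receptor_reduces_system(self, rng):
        p = random_parameter_set(rng)
        m = apply_genotype(p, "clv1_11")
        c1, c2, c3 = solve_free_species(m, wus=1.0)
        assert c1 == 0.0
        assert c2 > 0.0 and c3 > 0.0

    def test_residual_criterion_holds(self, rng):
        from clvwus import _kernels as _k
        for _ in range(20):
            p = random_parameter_set(rng)
            for g, hyp in [("wild_type", "background"),
                           ("clv1_1", "interference")]:
                m = apply_genotype(p, g, hyp)
                c1, c2, c3 = solve_free_species(m, wus=0.7)
                e = _k.free_species_residual(m.to_array(), c1, c2, c3, 0.7)
                assert np.linalg.norm(e) < 1e-3

    def test_conservation_of_complex_balances(self, rng):
        """Recomputing the bound complexes from the returned free
        species satisfies their steady-state relations exactly."""
        p = random_parameter_set(rng)
        st = solve_equilibrium(p, "wild_type", "background")
        b1 = p.k1 / (p.k2 + p.t1) * st.CLV1 * st.CLV3
        b2 = p.k4 / (p.k5 + p.t2) * st.CRN * st.CLV3
        assert st.CLV1_CLV3 == pytest.approx(b1, abs=1e-6)
        assert st.CRN_CLV3 == pytest.approx(b2, abs=1e-6)

    def test_negative_wus_rejected(self, unit_params):
        m = apply_genotype(unit_params, "wild_type")
        with pytest.raises(ValueError):
            solve_free_species(m, -0.1)


class TestWusResidual:
    def test_positive_at_zero(self, rng):
        p = random_parameter_set(rng)
        m = apply_genotype(p, "wild_type")
        assert wus_residual(m, 0.0) > 0.0

    def test_nonpositive_at_upper_bracket(self, rng):
        p = random_parameter_set(rng)
        m = apply_genotype(p, "wild_type")
        assert wus_residual(m, p.k7 / p.dW) <= 0.0

    def test_decoupled_closed_form(self, rng):
        p = decoupled_params(rng)
        m = apply_genotype(p, "wild_type")
        root = closed_form_wus(p)
        assert wus_residual(m, root) == pytest.approx(0.0, abs=1e-8)

    def test_strictly_decreasing_on_bracket(self, rng):
        """Raising WUS raises CLV3, bound receptors and X, lowering the
        Hill production while the sink grows: f has one sign change."""
        for _ in range(10):
            p = random_parameter_set(rng)
            m = apply_genotype(p, "clv1_1", "interference")
            grid = np.linspace(0.0, p.k7 / p.dW, 30)
            vals = [wus_residual(m, w) for w in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSolveEquilibrium:
    def test_decoupled_closed_form(self, rng):
        p = decoupled_params(rng)
        st = solve_equilibrium(p, "wild_type", "background")
        assert st.converged
        assert st.wus == pytest.approx(closed_form_wus(p), abs=1e-5)
        assert st.X == pytest.approx(p.s4, abs=1e-6)

    def test_residual_criteria_on_converged_solves(self, rng):
        for _ in range(10):
            p = random_parameter_set(rng)
            st = solve_equilibrium(p, "crn1", "background")
            assert st.converged
            assert st.final_residual < 1e-4
            m = apply_genotype(p, "crn1")
            d = rhs(st.concentrations, m)
            # free-species derivatives meet the Newton criterion
            assert np.linalg.norm(d[:3]) < 1e-3

    def test_all_concentrations_nonnegative(self, rng):
        for _ in range(10):
            p = random_parameter_set(rng)
            st = solve_equilibrium(p, "clv1_1", "loss_of_signal")
            assert st.converged
            assert np.all(st.concentrations >= 0.0)

    def test_removed_species_identically_zero(self, rng):
        p = random_parameter_set(rng)
        st = solve_equilibrium(p, "crn1_clv1_11", "loss_of_signal")
        assert st.CLV1 == 0.0 and st.CLV1_CLV3 == 0.0

    def test_continuity_in_k8(self, rng):
        """The interference clv1-1 equilibrium converges to the k8 = 0
        equilibrium as the interference rate vanishes."""
        p = random_parameter_set(rng)
        base = solve_equilibrium(p.with_overrides(k8=1e-10), "clv1_1",
                                 "interference")
        ref = solve_equilibrium(
            p.with_overrides(k3_weak=p.k3), "clv1_1", "loss_of_signal")
        assert base.wus == pytest.approx(ref.wus, abs=1e-4)

    def test_matches_time_integration(self, rng):
        """Brute-force oracle: stiff time integration of the full ODE
        system lands on the same fixed point."""
        for _ in range(5):
            p = random_parameter_set(rng)
            for g, hyp in [("wild_type", "background"),
                           ("clv1_1", "interference"),
                           ("crn1_clv1_1", "loss_of_signal")]:
                st = solve_equilibrium(p, g, hyp)
                y, reached = integrate_to_steady_state(p, g, hyp)
                assert st.converged and reached
                assert st.wus == pytest.approx(y[6], abs=1e-3)

    def test_uniqueness_from_different_initial_states(self, rng):
        p = random_parameter_set(rng)
        y1, ok1 = integrate_to_steady_state(p, "wild_type", "background")
        start = np.full(7, 5.0)
        y2, ok2 = integrate_to_steady_state(p, "wild_type", "background",
                                            initial_state=start)
        assert ok1 and ok2
        assert np.allclose(y1, y2, atol=1e-5)


class TestLumpedRates:
    def test_formula(self, unit_params):
        m = apply_genotype(unit_params, "wild_type")
        b1, b2 = lumped_rates(m)
        assert b1 == pytest.approx(1.0 * 1.0 / (1.0 + 1.0))
        assert b2 == pytest.approx(0.5)
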