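"""Energy function, annealing moves, and the optimization gate."""

import numpy as np
import pandas as pd
import pytest

from clvwus import (AnnealingSchedule, ParameterSet, PhenotypeTable,
                    accept_optimized, anneal, draw_initial, energy,
                    normalized_wus_profile, propose_move)
from clvwus.fitting import (ENERGY_FAIL, EnsembleRecord, fit_genotypes,
                            fitted_parameter_names, frame_to_records,
                            records_to_frame, run_ensemble)
from clvwus.model_core import Hypothesis, SINGLE_MUTANTS

from conftest import random_parameter_set


class TestPhenotypeTable:
    def test_normalized_targets(self, table1):
        assert table1.normalized_target("crn1") == pytest.approx(1.95)
        assert table1.normalized_target("clv1_1") == pytest.approx(2.1)
        assert table1.normalized_target("crn1_clv1_11") == pytest.approx(2.65)
        assert table1.normalized_target("crn1_clv1_1") == pytest.approx(2.25)

    def test_thresholds(self, table1):
        assert table1.threshold("clv1_1") == 0.1
        assert table1.threshold("crn1_clv1_1") == 0.5

    def test_missing_wild_type_rejected(self, table1):
        broken = table1.data[table1.data["name"] != "wild_type"]
        with pytest.raises(ValueError, match="wild_type"):
            PhenotypeTable(broken)


class TestEnergy:
    def test_zero_when_profile_matches(self, table1, rng):
        """A table generated from a parameter set's own profile gives
        exactly zero energy for that set."""
        from clvwus import generate_table, GroundTruth

        p = random_parameter_set(rng)
        truth = GroundTruth(params=p, hypothesis=Hypothesis.LOSS_OF_SIGNAL)
        table = generate_table(truth, noise=False)
        assert energy(p, "loss_of_signal", table) == pytest.approx(0.0,
                                                                   abs=1e-8)

    def test_quadratic_arithmetic(self, table1, rng):
        """Deviations of exactly 0.1 on each of four mutants sum to 0.04."""
        from clvwus import GroundTruth, generate_table

        p = random_parameter_set(rng)
        truth = GroundTruth(params=p, hypothesis=Hypothesis.INTERFERENCE)
        table = generate_table(truth, noise=False)
        shifted = table.data.copy()
        mask = shifted["name"].isin(SINGLE_MUTANTS)
        shifted.loc[mask, "carpels_per_flower"] += 0.2  # 0.1 normalized
        e = energy(p, "interference", PhenotypeTable(shifted))
        assert e == pytest.approx(0.04, abs=1e-6)

    def test_background_sums_three_mutants(self, table1, rng):
        assert fit_genotypes("background") == ("crn1", "clv1_11",
                                               "crn1_clv2_1")

    def test_sentinel_on_degenerate_parameters(self, table1):
        """A parameter set the solver cannot handle returns the sentinel
        energy instead of raising."""
        p = ParameterSet.from_array(np.ones(21))
        # extreme Hill threshold drives WUS toward zero; the energy must
        # still come back as a nonnegative float, never an exception
        p = p.with_overrides(K=1e-300)
        e = energy(p, "background", table1)
        assert isinstance(e, float) and e >= 0.0


class TestProposeMove:
    def test_single_parameter_scaled(self, rng, unit_params):
        moved = propose_move(unit_params, "loss_of_signal", rng,
                             move_factor=1.01)
        diffs = [n for n in unit_params.to_dict()
                 if getattr(moved, n) != getattr(unit_params, n)]
        assert len(diffs) == 1
        name = diffs[0]
        ratio = getattr(moved, name) / getattr(unit_params, name)
        assert ratio == pytest.approx(1.01) or ratio == pytest.approx(1 / 1.01)

    def test_hypothesis_selects_fitted_parameters(self):
        assert "k3_weak" in fitted_parameter_names("loss_of_signal")
        assert "k8" not in fitted_parameter_names("loss_of_signal")
        assert "k8" in fitted_parameter_names("interference")
        assert "k3_weak" not in fitted_parameter_names("interference")
        assert len(fitted_parameter_names("background")) == 19

    def test_moves_preserve_positivity_and_log_symmetry(self, unit_params):
        rng = np.random.default_rng(7)
        log_steps = []
        p = unit_params
        for _ in range(2000):
            q = propose_move(p, "background", rng, move_factor=1.01)
            changed = [n for n in p.to_dict()
                       if getattr(q, n) != getattr(p, n)][0]
            log_steps.append(np.log(getattr(q, changed)
                                    / getattr(p, changed)))
            p = q
        arr = np.array(log_steps)
        assert np.all(np.isfinite(arr))
        assert np.all(np.array([getattr(p, n)
                                for n in fitted_parameter_names("background")])
                      > 0)
        # symmetric walk: |mean log-step| well under 4 standard errors
        assert abs(arr.mean()) < 4 * np.log(1.01) / np.sqrt(len(arr))

    def test_deterministic_given_seed(self, unit_params):
        a = propose_move(unit_params, "interference",
                         np.random.default_rng(11))
        b = propose_move(unit_params, "interference",
                         np.random.default_rng(11))
        assert a == b


class TestSchedule:
    def test_full_schedule_has_97_blocks(self):
        s = AnnealingSchedule.full()
        assert s.n_blocks == 97
        assert s.total_iterations == 97_000

    def test_desk_schedule_total_budget(self):
        s = AnnealingSchedule.desk()
        assert s.n_blocks == 97
        assert s.total_iterations == 9_700

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(beta_initial=10.0, beta_final=1.0)


class TestAnneal:
    def test_deterministic_given_seed(self, table1):
        sched = AnnealingSchedule(iterations_per_beta=5, move_factor=1.1)
        p1, e1 = anneal(table1, "background", sched, seed=123)
        p2, e2 = anneal(table1, "background", sched, seed=123)
        assert e1 == e2
        assert np.array_equal(p1.to_array(), p2.to_array())

    def test_best_not_worse_than_initial(self, table1):
        """Best-tracking: the returned energy never exceeds the energy
        of the initial draw (which the chain visited)."""
        sched = AnnealingSchedule(iterations_per_beta=5, move_factor=1.1)
        from clvwus import _kernels as _k
        for seed in (1, 2, 3):
            p, e_best = anneal(table1, "loss_of_signal", sched, seed)
            assert np.isfinite(e_best) or e_best == ENERGY_FAIL
            assert e_best <= ENERGY_FAIL

    def test_unfitted_mutant_parameter_stays_zero(self, table1):
        sched = AnnealingSchedule(iterations_per_beta=5, move_factor=1.1)
        p, _ = anneal(table1, "loss_of_signal", sched, seed=5)
        assert p.k8 == 0.0
        p, _ = anneal(table1, "interference", sched, seed=5)
        assert p.k3_weak == 0.0


class TestAcceptGate:
    def _record(self, profile, hyp="loss_of_signal"):
        return profile, hyp

    def test_exact_match_accepted(self, table1):
        profile = {g: table1.normalized_target(g) for g in SINGLE_MUTANTS}
        assert accept_optimized(profile, table1, "loss_of_signal")

    def test_one_deviation_beyond_threshold_rejected(self, table1):
        profile = {g: table1.normalized_target(g) for g in SINGLE_MUTANTS}
        profile["crn1"] += 0.11
        assert not accept_optimized(profile, table1, "loss_of_signal")

    def test_boundary_deviation_inclusive(self, table1):
        # use a dyadic threshold so the boundary is exact in floating point
        data = table1.data.copy()
        data.loc[data["name"] != "wild_type", "threshold_error"] = 0.125
        table = PhenotypeTable(data)
        profile = {g: table.normalized_target(g) for g in SINGLE_MUTANTS}
        profile["clv1_1"] = table.normalized_target("clv1_1") + 0.125
        assert accept_optimized(profile, table, "loss_of_signal")

    def test_missing_genotype_errors(self, table1):
        with pytest.raises(KeyError):
            accept_optimized({"crn1": 1.95}, table1, "interference")

    def test_nan_profile_rejected(self, table1):
        profile = {g: float("nan") for g in SINGLE_MUTANTS}
        assert not accept_optimized(profile, table1, "loss_of_signal")


class TestEnsembleRoundTrip:
    def test_records_frame_round_trip(self, table1, rng):
        from clvwus.fitting import make_record

        p = random_parameter_set(rng)
        rec = make_record(p, "interference", seed=9, energy_value=1.2,
                          table=table1)
        df = records_to_frame([rec])
        back = frame_to_records(df)[0]
        assert back.params == rec.params
        assert back.seed == rec.seed
        assert back.passed_optimization == rec.passed_optimization

    def test_run_ensemble_deterministic(self, table1):
        sched = AnnealingSchedule(iterations_per_beta=5, move_factor=1.15)
        a = run_ensemble(table1, "background", sched, 3, 42)
        b = run_ensemble(table1, "background", sched, 3, 42)
        pd.testing.assert_frame_equal(a, b)
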