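"""Shared fixtures: parameter sets, the experimental table, and the
session-scoped desk-schedule ensembles used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clvwus
from clvwus import AnnealingSchedule, ParameterSet, load_table1, run_ensemble

#: Fixed base seed for every stochastic fixture in the suite.
SUITE_SEED = 20260924

#: Desk-schedule runs per hypothesis for the ensemble-level tests.
ENSEMBLE_RUNS = 250


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """Uniform draw from the initialization range for all 21 parameters."""
    return ParameterSet.from_array(rng.uniform(0.1, 10.0, 21))


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def unit_params() -> ParameterSet:
    """All parameters at 1 (k3_weak = 0.5, k8 = 1): a well-behaved
    generic operating point."""
    return ParameterSet.from_array(np.ones(21)).with_overrides(k3_weak=0.5)


@pytest.fixture(scope="session")
def desk_ensembles(table1) -> dict[str, pd.DataFrame]:
    """Desk-schedule ensembles for all three hypotheses, shared across
    the ensemble-level tests (computed once per session)."""
    schedule = AnnealingSchedule.desk()
    out = {}
    for i, hyp in enumerate(("loss_of_signal", "interference", "background")):
        out[hyp] = run_ensemble(table1, hyp, schedule, ENSEMBLE_RUNS,
                                SUITE_SEED + i * ENSEMBLE_RUNS)
    return out
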