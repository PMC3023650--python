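"""Synthetic phenotype tables from known ground-truth parameter sets.

The generator inverts the observable map used in fitting: a ground-truth
parameter set is pushed through the equilibrium solver to per-genotype
normalized WUS levels, which are rescaled to carpel counts (wild type
fixed at 2.0 carpels/flower) and optionally blurred with Gaussian
observation noise at the experimental standard errors.  Because the real
data only enter the pipeline through the phenotype table, a synthetic
table exercises every downstream stage, enabling end-to-end recovery
tests: with zero noise the truth itself must pass both acceptance gates,
and fitted ensembles must reproduce the truth's normalized WUS profile
(the model is deliberately under-constrained, so recovery is defined at
the level of observables, not parameter point values).

Noise is a test device — the published analysis handles uncertainty via
acceptance thresholds, not a noise model.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import pandas as pd
import numpy as np

from .model_core import (DOUBLE_MUTANTS, Hypothesis, ParameterSet,
                         SINGLE_MUTANTS)
from .fitting import (AnnealingSchedule, PhenotypeTable, anneal, load_table1,
                      make_record, normalized_wus_profile)
from .validation import validate

#: Threshold conventions of the experimental table.
SINGLE_THRESHOLD = 0.1
DOUBLE_THRESHOLD = 0.5
DEFAULT_SE = 0.1
WILD_TYPE_CARPELS = 2.0


@dataclass(frozen=True)
class GroundTruth:
    """A parameter set designated as generating truth, its clv1-1
    hypothesis, and the per-genotype observation-noise sd."""

    params: ParameterSet
    hypothesis: Hypothesis
    noise_sd: dict[str, float] = field(default_factory=dict)

    def sd(self, genotype: str) -> float:
        return self.noise_sd.get(genotype, DEFAULT_SE)


def generate_table(truth: GroundTruth,
                   rng: np.random.Generator | None = None,
                   noise: bool = True) -> PhenotypeTable:
    """Phenotype table implied by a ground truth.

    carpels_i = 2.0 * (WUS*_i / WUS*_wt) + N(0, sd_i); the wild-type row
    is pinned at 2.0 and thresholds follow the experimental conventions
    (0.1 for single mutants, 0.5 for doubles).
    """
    if rng is None:
        rng = np.random.default_rng()
    wt_wus, profile = normalized_wus_profile(truth.params, truth.hypothesis)
    if not np.isfinite(wt_wus) or any(not np.isfinite(v)
                                      for v in profile.values()):
        raise ValueError("ground truth has unsolvable genotype equilibria")
    rows = [{"name": "wild_type", "carpels_per_flower": WILD_TYPE_CARPELS,
             "se": 0.0, "threshold_error": float("nan"), "role": "reference"}]
    for g in SINGLE_MUTANTS + DOUBLE_MUTANTS:
        carpels = WILD_TYPE_CARPELS * profile[g]
        if noise:
            carpels += rng.normal(0.0, truth.sd(g))
        rows.append({
            "name": g,
            "carpels_per_flower": carpels,
            "se": truth.sd(g),
            "threshold_error": (SINGLE_THRESHOLD if g in SINGLE_MUTANTS
                                else DOUBLE_THRESHOLD),
            "role": "optimization" if g in SINGLE_MUTANTS else "validation",
        })
    return PhenotypeTable(pd.DataFrame(rows))


def find_demo_truth(hypothesis: Hypothesis | str, seed: int,
                    table: PhenotypeTable | None = None,
                    schedule: AnnealingSchedule | None = None,
                    max_attempts: int = 20) -> GroundTruth:
    """Search for one plausible parameter set for a hypothesis by short
    annealing against the experimental table, requiring the result to
    pass both the optimization and validation gates.

    Deterministic given the seed.  Raises if no passing set is found
    within ``max_attempts`` annealing runs (raise the budget or change
    the seed).
    """
    hyp = Hypothesis(hypothesis)
    if hyp is Hypothesis.BACKGROUND:
        raise ValueError("demo truths are defined for the two clv1-1 "
                         "hypotheses, not the background fit")
    if table is None:
        table = load_table1()
    if schedule is None:
        schedule = AnnealingSchedule.desk()
    for attempt in range(max_attempts):
        run_seed = int(seed) + attempt
        params, e_best = anneal(table, hyp, schedule, run_seed)
        rec = make_record(params, hyp, run_seed, e_best, table)
        if rec.passed_optimization and validate(rec, table):
            return GroundTruth(params=params, hypothesis=hyp)
    raise RuntimeError(
        f"no parameter set passed both gates in {max_attempts} annealing "
        f"runs for {hyp.value}; increase max_attempts or try another seed")


# --- packaged demo truths ---------------------------------------------------

def load_demo_truth(hypothesis: Hypothesis | str) -> GroundTruth:
    """Load the packaged demo ground truth for a hypothesis (a fitted,
    gate-passing parameter set cached in-repo for fast tests)."""
    hyp = Hypothesis(hypothesis)
    name = f"demo_truth_{hyp.value}.json"
    ref = importlib.resources.files("clvwus") / "data" / name
    payload = json.loads(ref.read_text())
    return GroundTruth(params=ParameterSet.from_dict(payload["params"]),
                       hypothesis=Hypothesis(payload["hypothesis"]))


def save_demo_truth(truth: GroundTruth, path) -> None:
    payload = {"hypothesis": truth.hypothesis.value,
               "params": truth.params.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
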