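"""Parameter-ensemble fitting by simulated annealing.

The observable is the equilibrium WUS level of each mutant normalized by
the wild-type level; carpel counts from the phenotype table are mapped
to targets the same way (D_i = carpels_i / carpels_wild_type, the
minimal proportional assumption).  The energy is the sum of squared
deviations over the mutants entering the fit:

    E(p) = sum_i (WUS*_i / WUS*_wt - D_i)^2

A Metropolis chain explores parameter space multiplicatively (one
randomly chosen parameter scaled by the move factor, up or down with
equal probability) under a geometric cooling schedule, and the
lowest-energy parameter set ever visited is the run's solution.  A run
"passes optimization" when every fitted mutant's normalized WUS lies
within the table's threshold of its target.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as _k
from .model_core import (BACKGROUND_MUTANTS, DOUBLE_MUTANTS, GENOTYPE_SPECS,
                         Genotype, Hypothesis, PARAM_NAMES, ParameterSet,
                         SINGLE_MUTANTS)
from .equilibrium import solve_equilibrium

#: Sentinel energy for parameter sets where any equilibrium solve fails.
ENERGY_FAIL = _k.ENERGY_FAIL

#: Default initialization range (uniform per fitted parameter).
INIT_RANGE = (0.1, 10.0)


# --- phenotype table --------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeTable:
    """Per-genotype carpel counts, SEs and acceptance thresholds.

    The wild-type row provides the reference carpel count (2.0 in the
    experimental table) against which mutant targets are normalized.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"name", "carpels_per_flower", "se", "threshold_error"}
        if not required.issubset(df.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if "wild_type" not in set(df["name"]):
            raise ValueError("table must contain a wild_type row")
        mutants = df[df["name"] != "wild_type"]
        if not (mutants["threshold_error"].astype(float) > 0).all():
            raise ValueError("mutant rows need positive thresholds")

    @property
    def wild_type_carpels(self) -> float:
        row = self.data.loc[self.data["name"] == "wild_type"]
        return float(row["carpels_per_flower"].iloc[0])

    def carpels(self, name: str) -> float:
        return float(self._row(name)["carpels_per_flower"])

    def normalized_target(self, name: str) -> float:
        """D_i = carpels_i / carpels_wild_type."""
        return self.carpels(name) / self.wild_type_carpels

    def threshold(self, name: str) -> float:
        return float(self._row(name)["threshold_error"])

    def se(self, name: str) -> float:
        return float(self._row(name)["se"])

    def _row(self, name: str) -> pd.Series:
        rows = self.data.loc[self.data["name"] == name]
        if rows.empty:
            raise KeyError(f"genotype {name!r} not in phenotype table")
        return rows.iloc[0]

    @property
    def genotypes(self) -> list[str]:
        return [n for n in self.data["name"] if n != "wild_type"]

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def load_table1() -> PhenotypeTable:
    """The packaged experimental carpel-count table (wild type, four
    single receptor mutants, two double mutants)."""
    ref = importlib.resources.files("clvwus") / "data" / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return PhenotypeTable.from_csv(path)


def fit_genotypes(hypothesis: Hypothesis | str) -> tuple[str, ...]:
    """Mutants entering the energy: the four singles, or three for the
    background fit which excludes clv1-1."""
    if Hypothesis(hypothesis) is Hypothesis.BACKGROUND:
        return BACKGROUND_MUTANTS
    return SINGLE_MUTANTS


def fitted_parameter_names(hypothesis: Hypothesis | str) -> tuple[str, ...]:
    hyp = Hypothesis(hypothesis)
    if hyp is Hypothesis.LOSS_OF_SIGNAL:
        return PARAM_NAMES[:19] + ("k3_weak",)
    if hyp is Hypothesis.INTERFERENCE:
        return PARAM_NAMES[:19] + ("k8",)
    return PARAM_NAMES[:19]


# --- annealing schedule -----------------------------------------------------

@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling schedule for the Metropolis chain.

    The published protocol runs 1000 iterations per inverse-temperature
    block with 1% multiplicative moves, multiplying beta by 1.1 from 1
    until it exceeds 10,000 (97 blocks).  The desk profile keeps the
    same temperature ladder but uses 100 iterations per block with the
    move factor enlarged to 1.032, preserving the full protocol's
    log-space diffusion variance (iterations x ln(move factor)^2) — the
    quantity that controls the spread of the resulting ensemble — at a
    tenth of the cost.
    """

    beta_initial: float = 1.0
    beta_final: float = 1.0e4
    beta_factor: float = 1.1
    iterations_per_beta: int = 1000
    move_factor: float = 1.01

    def __post_init__(self) -> None:
        if not self.beta_initial < self.beta_final:
            raise ValueError("beta_initial must be < beta_final")
        if self.beta_factor <= 1.0 or self.move_factor <= 1.0:
            raise ValueError("beta_factor and move_factor must be > 1")

    @property
    def n_blocks(self) -> int:
        """Number of beta blocks executed (beta runs 1, 1.1, ... while
        beta <= beta_final)."""
        n = 0
        beta = self.beta_initial
        while beta <= self.beta_final:
            n += 1
            beta *= self.beta_factor
        return n

    @property
    def total_iterations(self) -> int:
        return self.n_blocks * self.iterations_per_beta

    @classmethod
    def full(cls) -> "AnnealingSchedule":
        return cls()

    @classmethod
    def desk(cls) -> "AnnealingSchedule":
        # ln(1.032) ~ ln(1.01) * sqrt(1000/100): variance-matched moves
        return cls(iterations_per_beta=100, move_factor=1.032)

    @classmethod
    def named(cls, name: str) -> "AnnealingSchedule":
        try:
            return {"full": cls.full, "desk": cls.desk}[name]()
        except KeyError:
            raise ValueError(f"unknown schedule {name!r}") from None


# --- energy and moves -------------------------------------------------------

def _targets_for(table: PhenotypeTable, genotypes: tuple[str, ...]):
    codes = np.array([GENOTYPE_SPECS[g].code for g in genotypes], dtype=np.int64)
    targets = np.array([table.normalized_target(g) for g in genotypes])
    return codes, targets


def energy(params: ParameterSet, hypothesis: Hypothesis | str,
           table: PhenotypeTable,
           genotypes: tuple[str, ...] | None = None) -> float:
    """Sum of squared normalized-WUS deviations over the fit mutants.

    Returns the sentinel :data:`ENERGY_FAIL` if any equilibrium solve
    fails or the wild-type WUS is zero; never raises from solver
    trouble, so the annealing loop is exception-free.
    """
    hyp = Hypothesis(hypothesis)
    if genotypes is None:
        genotypes = fit_genotypes(hyp)
    codes, targets = _targets_for(table, genotypes)
    return float(_k.energy_arr(params.to_array(), hyp.code, codes, targets))


def propose_move(params: ParameterSet, hypothesis: Hypothesis | str,
                 rng: np.random.Generator,
                 move_factor: float = 1.01) -> ParameterSet:
    """Scale one randomly chosen fitted parameter by the move factor,
    up or down with equal probability.  Moves are multiplicative, so
    positivity is preserved unconditionally."""
    names = fitted_parameter_names(hypothesis)
    name = names[int(rng.integers(len(names)))]
    factor = move_factor if rng.random() < 0.5 else 1.0 / move_factor
    return params.with_overrides(**{name: getattr(params, name) * factor})


def draw_initial(hypothesis: Hypothesis | str, rng: np.random.Generator,
                 init_range: tuple[float, float] = INIT_RANGE) -> ParameterSet:
    """Initial parameter set: uniform draw per fitted parameter; the
    unused hypothesis-specific parameter is left at zero."""
    lo, hi = init_range
    values = dict.fromkeys(PARAM_NAMES, 0.0)
    for name in fitted_parameter_names(hypothesis):
        values[name] = float(rng.uniform(lo, hi))
    values["k3_weak"] = max(values["k3_weak"], 0.0)
    values["k8"] = max(values["k8"], 0.0)
    return ParameterSet(**values)


def anneal(table: PhenotypeTable, hypothesis: Hypothesis | str,
           schedule: AnnealingSchedule, seed: int,
           init_range: tuple[float, float] = INIT_RANGE,
           ) -> tuple[ParameterSet, float]:
    """One simulated-annealing run; returns (best parameters, best energy).

    Deterministic given the seed: two runs with identical seed and
    schedule produce identical trajectories.
    """
    hyp = Hypothesis(hypothesis)
    codes, targets = _targets_for(table, fit_genotypes(hyp))
    best, e_best = _k.anneal_arr(
        int(seed), hyp.code, codes, targets,
        float(schedule.beta_initial), float(schedule.beta_final),
        float(schedule.beta_factor), int(schedule.iterations_per_beta),
        float(schedule.move_factor), float(init_range[0]), float(init_range[1]))
    return ParameterSet.from_array(best), float(e_best)


# --- acceptance gate and records -------------------------------------------

@dataclass
class EnsembleRecord:
    """One fitted parameter set with its observables and gate flags."""

    params: ParameterSet
    hypothesis: Hypothesis
    seed: int
    energy: float
    wus_wild_type: float
    normalized_wus: dict[str, float] = field(default_factory=dict)
    passed_optimization: bool = False
    passed_validation: bool = False


def normalized_wus_profile(params: ParameterSet,
                           hypothesis: Hypothesis | str,
                           genotypes: tuple[str, ...] | None = None,
                           ) -> tuple[float, dict[str, float]]:
    """Wild-type WUS and normalized mutant WUS levels.

    Genotypes whose equilibrium fails to converge (or that are undefined
    under the background hypothesis because they carry clv1-1) map to
    NaN.
    """
    hyp = Hypothesis(hypothesis)
    if genotypes is None:
        genotypes = SINGLE_MUTANTS + DOUBLE_MUTANTS
    wt = solve_equilibrium(params, "wild_type", hyp)
    wt_wus = wt.wus if wt.converged else float("nan")
    out: dict[str, float] = {}
    for g in genotypes:
        if GENOTYPE_SPECS[g].has_clv1_1 and hyp is Hypothesis.BACKGROUND:
            out[g] = float("nan")
            continue
        st = solve_equilibrium(params, g, hyp)
        out[g] = st.wus / wt_wus if (st.converged and wt_wus > 0) else float("nan")
    return wt_wus, out


def accept_optimized(record: EnsembleRecord | dict[str, float],
                     table: PhenotypeTable,
                     hypothesis: Hypothesis | str | None = None) -> bool:
    """Optimization gate: every fitted mutant's normalized WUS within
    its (inclusive) threshold of the target."""
    if isinstance(record, EnsembleRecord):
        profile, hyp = record.normalized_wus, record.hypothesis
    else:
        if hypothesis is None:
            raise ValueError("hypothesis required with a bare profile")
        profile, hyp = record, Hypothesis(hypothesis)
    for g in fit_genotypes(hyp):
        if g not in profile:
            raise KeyError(f"profile lacks genotype {g!r}")
        dev = abs(profile[g] - table.normalized_target(g))
        if not dev <= table.threshold(g):  # NaN-safe: NaN comparisons fail
            return False
    return True


def make_record(params: ParameterSet, hypothesis: Hypothesis | str,
                seed: int, energy_value: float,
                table: PhenotypeTable) -> EnsembleRecord:
    """Assemble a full ensemble record (observables + optimization flag;
    validation is applied separately by the validation module)."""
    hyp = Hypothesis(hypothesis)
    wt_wus, profile = normalized_wus_profile(params, hyp)
    rec = EnsembleRecord(params=params, hypothesis=hyp, seed=int(seed),
                         energy=float(energy_value), wus_wild_type=wt_wus,
                         normalized_wus=profile)
    try:
        rec.passed_optimization = accept_optimized(rec, table)
    except KeyError:
        rec.passed_optimization = False
    return rec


# --- ensemble persistence ---------------------------------------------------

_NW_COLUMNS = [f"nw_{g}" for g in SINGLE_MUTANTS + DOUBLE_MUTANTS]
ENSEMBLE_COLUMNS = (["hypothesis", "seed"] + list(PARAM_NAMES)
                    + ["wus_wild_type"] + _NW_COLUMNS
                    + ["energy", "passed_optimization", "passed_validation"])


def records_to_frame(records: list[EnsembleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {"hypothesis": r.hypothesis.value, "seed": r.seed}
        row.update(r.params.to_dict())
        row["wus_wild_type"] = r.wus_wild_type
        for g in SINGLE_MUTANTS + DOUBLE_MUTANTS:
            row[f"nw_{g}"] = r.normalized_wus.get(g, float("nan"))
        row["energy"] = r.energy
        row["passed_optimization"] = bool(r.passed_optimization)
        row["passed_validation"] = bool(r.passed_validation)
        rows.append(row)
    return pd.DataFrame(rows, columns=ENSEMBLE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[EnsembleRecord]:
    records = []
    for _, row in df.iterrows():
        params = ParameterSet.from_dict({p: row[p] for p in PARAM_NAMES})
        rec = EnsembleRecord(
            params=params, hypothesis=Hypothesis(row["hypothesis"]),
            seed=int(row["seed"]), energy=float(row["energy"]),
            wus_wild_type=float(row["wus_wild_type"]),
            normalized_wus={g: float(row[f"nw_{g}"])
                            for g in SINGLE_MUTANTS + DOUBLE_MUTANTS},
            passed_optimization=bool(row["passed_optimization"]),
            passed_validation=bool(row["passed_validation"]))
        records.append(rec)
    return records


def run_ensemble(table: PhenotypeTable, hypothesis: Hypothesis | str,
                 schedule: AnnealingSchedule, n_runs: int, base_seed: int,
                 init_range: tuple[float, float] = INIT_RANGE,
                 validate_records: bool = True) -> pd.DataFrame:
    """Run ``n_runs`` independent annealing optimizations (run j seeded
    with base_seed + j), gate each best parameter set, and return the
    ensemble as a DataFrame with one row per run."""
    from .validation import validate  # local import to avoid a cycle

    hyp = Hypothesis(hypothesis)
    records = []
    for j in range(int(n_runs)):
        seed = int(base_seed) + j
        params, e_best = anneal(table, hyp, schedule, seed, init_range)
        rec = make_record(params, hyp, seed, e_best, table)
        if (validate_records and rec.passed_optimization
                and hyp is not Hypothesis.BACKGROUND):
            rec.passed_validation = validate(rec, table)
        records.append(rec)
    return records_to_frame(records)
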