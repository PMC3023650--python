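"""Double-mutant validation of optimized ensembles.

The two receptor double mutants (crn-1 clv1-11 and crn-1 clv1-1) are
held out of the fit and used afterwards to reject over-fitted parameter
sets: a set survives when both double-mutant normalized WUS levels fall
within the (larger) validation threshold of their targets.  Equilibria
are recomputed from the stored parameters rather than trusting cached
values, so ensembles written by older solver versions can be
re-validated.
"""

from __future__ import annotations

import pandas as pd

from .model_core import DOUBLE_MUTANTS, Hypothesis, ParameterSet
from .fitting import (EnsembleRecord, PhenotypeTable, frame_to_records,
                      normalized_wus_profile, records_to_frame)


def validate(record: EnsembleRecord | ParameterSet,
             table: PhenotypeTable,
             hypothesis: Hypothesis | str | None = None) -> bool:
    """True iff both double mutants reproduce their targets within the
    validation threshold (inclusive).  Accepts either a full ensemble
    record or a bare parameter set plus hypothesis."""
    if isinstance(record, EnsembleRecord):
        params, hyp = record.params, record.hypothesis
    else:
        if hypothesis is None:
            raise ValueError("hypothesis required with a bare parameter set")
        params, hyp = record, Hypothesis(hypothesis)
    if hyp is Hypothesis.BACKGROUND:
        raise ValueError("the background fit has no defined clv1-1 mechanism; "
                         "double-mutant validation does not apply")
    _, profile = normalized_wus_profile(params, hyp, DOUBLE_MUTANTS)
    for g in DOUBLE_MUTANTS:
        dev = abs(profile[g] - table.normalized_target(g))
        if not dev <= table.threshold(g):
            return False
    return True


def validate_ensemble(df: pd.DataFrame, table: PhenotypeTable) -> pd.DataFrame:
    """Recompute the ``passed_validation`` flag for every optimized row
    of an ensemble frame; returns a new frame."""
    records = frame_to_records(df)
    for rec in records:
        if rec.hypothesis is Hypothesis.BACKGROUND or not rec.passed_optimization:
            rec.passed_validation = False
        else:
            rec.passed_validation = validate(rec, table)
    return records_to_frame(records)
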