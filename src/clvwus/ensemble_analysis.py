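"""Statistical analysis of fitted parameter ensembles.

The ensemble — every parameter set the data admit, not a single best
fit — is the object of interest: differences between the loss-of-signal,
interference and background (clv1-1-free) ensembles are what the two
mutant hypotheses predict about the unperturbed network.  This module
provides the comparison toolkit:

* rank-based AUC (Mann-Whitney) between per-parameter distributions,
* logarithmic sensitivities S_p = (dM/dp)(p/M) of wild-type WUS,
* pathway-strength readouts (k3*[CLV1/CLV3] vs k6*[CRN/CLV3]),
* sequestration/abundance diagnostics for the clv1 mutants,
* joint PCA of log-parameters across labeled ensembles,
* CLV3 over/under-expression scans, and
* Table-style ensemble summaries (means, sensitivities, AUC rankings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA

from .model_core import (Hypothesis, PARAM_NAMES, ParameterSet,
                         SHARED_PARAM_NAMES, apply_genotype)
from .equilibrium import SolverError, solve_equilibrium


# --- AUC --------------------------------------------------------------------

@dataclass(frozen=True)
class AUCResult:
    """Oriented AUC between two samples: always >= 0.5, with ``relation``
    naming the sample whose values are systematically greater ("a > b",
    "b > a", or "a ~ b" at exactly 0.5)."""

    parameter: str
    auc: float
    relation: str
    raw_auc: float  # P(a > b), ties counted half

    def __post_init__(self) -> None:
        if not 0.5 <= self.auc <= 1.0:
            raise ValueError("oriented AUC must lie in [0.5, 1]")


def auc(sample_a, sample_b, parameter: str = "",
        label_a: str = "a", label_b: str = "b") -> AUCResult:
    """Rank-based AUC: Mann-Whitney U / (n_a * n_b), ties counted 0.5.

    0.5 means the two samples are indistinguishable by rank; 1 after
    orientation means complete separation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = mannwhitneyu(a, b, alternative="two-sided").statistic
    raw = float(u) / (a.size * b.size)  # P(a > b)
    if raw >= 0.5:
        oriented, relation = raw, f"{label_a} > {label_b}"
    else:
        oriented, relation = 1.0 - raw, f"{label_b} > {label_a}"
    if raw == 0.5:
        relation = f"{label_a} ~ {label_b}"
    return AUCResult(parameter=parameter, auc=oriented, relation=relation,
                     raw_auc=raw)


# --- sensitivity ------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    value: float


def sensitivity(params: ParameterSet, parameter_name: str,
                genotype: str = "wild_type",
                hypothesis: Hypothesis | str = Hypothesis.BACKGROUND,
                rel_step: float = 1.0e-3) -> float:
    """Logarithmic sensitivity S_p = (dM/dp) * p / M of the equilibrium
    WUS level, by central finite differences with a relative step.

    S_p = -1 means WUS* scales as 1/p locally; |S_p| >> 1 flags fragile
    parameters.
    """
    if parameter_name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    p0 = getattr(params, parameter_name)
    if p0 <= 0.0:
        raise ValueError("sensitivity requires a positive base value")

    def wus_at(value: float) -> float:
        st = solve_equilibrium(params.with_overrides(**{parameter_name: value}),
                               genotype, hypothesis)
        if not st.converged:
            raise SolverError(f"equilibrium failed at {parameter_name}={value}")
        return st.wus

    m0 = wus_at(p0)
    if m0 <= 0.0:
        raise SolverError("wild-type WUS is zero; sensitivity undefined")
    h = rel_step * p0
    m_plus = wus_at(p0 + h)
    m_minus = wus_at(p0 - h)
    return (m_plus - m_minus) / (2.0 * h) * p0 / m0


# --- pathway strengths and mutant diagnostics -------------------------------

def pathway_strengths(params: ParameterSet, genotype: str = "wild_type",
                      hypothesis: Hypothesis | str = Hypothesis.BACKGROUND,
                      ) -> tuple[float, float]:
    """Signal carried by each receptor pathway at equilibrium:
    (k3_eff * [CLV1/CLV3]*, k6_eff * [CRN/CLV3]*), using the genotype's
    effective signal strengths."""
    model = apply_genotype(params, genotype, hypothesis)
    st = solve_equilibrium(params, genotype, hypothesis)
    if not st.converged:
        raise SolverError(f"equilibrium failed for genotype {genotype}")
    return model.k3 * st.CLV1_CLV3, model.k6 * st.CRN_CLV3


def mutant_diagnostics(params: ParameterSet,
                       hypothesis: Hypothesis | str,
                       genotypes: tuple[str, ...] = ("wild_type", "clv1_1",
                                                     "clv1_11"),
                       ) -> pd.DataFrame:
    """Equilibrium quantities distinguishing the sequestration and
    interference mechanisms: bound CRN, free CLV3, and the free/bound
    receptor pools, per genotype.

    Under loss-of-signal, clv1-1 keeps binding CLV3 without signaling,
    so free CLV3 and bound CRN both drop relative to the clv1-11 null;
    under interference bound CRN drops without CLV3 depletion.
    """
    rows = []
    for g in genotypes:
        st = solve_equilibrium(params, g, hypothesis)
        if not st.converged:
            raise SolverError(f"equilibrium failed for genotype {g}")
        rows.append({
            "genotype": g,
            "free_clv1": st.CLV1,
            "free_crn": st.CRN,
            "free_clv3": st.CLV3,
            "bound_clv1": st.CLV1_CLV3,
            "bound_crn": st.CRN_CLV3,
            "free_receptors": st.CLV1 + st.CRN,
            "bound_receptors": st.CLV1_CLV3 + st.CRN_CLV3,
            "wus": st.wus,
        })
    return pd.DataFrame(rows).set_index("genotype")


# --- PCA --------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    components: np.ndarray          # orthonormal rows, loading per column
    explained_variance_ratio: np.ndarray
    projections: pd.DataFrame       # columns E1, E2, ... plus 'label'
    feature_names: tuple[str, ...]
    underdetermined: bool           # fewer members than dimensions


def pca_joint(ensembles: dict[str, pd.DataFrame],
              n_components: int = 2,
              log_transform: bool = True) -> PCAResult:
    """PCA on the pooled shared parameters of labeled ensembles.

    Parameters are log10-transformed by default (they are positive and
    explored multiplicatively) and standardized per column over the
    pooled data, so no single scale dominates.  Only the 19 parameters
    common to every hypothesis enter, keeping the spaces comparable.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least two labeled ensembles")
    frames, labels = [], []
    for label, df in ensembles.items():
        x = df[list(SHARED_PARAM_NAMES)].to_numpy(dtype=float)
        frames.append(x)
        labels.extend([label] * len(x))
    pooled = np.vstack(frames)
    if log_transform:
        pooled = np.log10(pooled)
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    std[std == 0.0] = 1.0
    z = (pooled - mean) / std
    n_comp = min(n_components, z.shape[0], z.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(z)
    proj = pd.DataFrame(coords, columns=[f"E{i+1}" for i in range(n_comp)])
    proj["label"] = labels
    return PCAResult(components=pca.components_,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     projections=proj,
                     feature_names=SHARED_PARAM_NAMES,
                     underdetermined=pooled.shape[0] < pooled.shape[1])


# --- CLV3 perturbation ------------------------------------------------------

DEFAULT_FACTORS = np.logspace(-1, 1, 21)


def clv3_perturbation_scan(params: ParameterSet,
                           hypothesis: Hypothesis | str = Hypothesis.BACKGROUND,
                           factors=DEFAULT_FACTORS) -> pd.DataFrame:
    """Scale CLV3 production (s3 and the WUS-driven term kW) by each
    factor and report wild-type WUS normalized by the unperturbed level.

    Under-expression (factor < 1) raises WUS, over-expression lowers it:
    the feedback loop's qualitative response to clv3 perturbations.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0.0):
        raise ValueError("factors must be positive")
    base = solve_equilibrium(params, "wild_type", hypothesis)
    if not base.converged or base.wus <= 0.0:
        raise SolverError("unperturbed equilibrium failed")
    rows = []
    for f in factors:
        perturbed = params.with_overrides(s3=params.s3 * f, kW=params.kW * f)
        st = solve_equilibrium(perturbed, "wild_type", hypothesis)
        rows.append({"factor": f,
                     "normalized_wus": st.wus / base.wus if st.converged
                     else float("nan")})
    return pd.DataFrame(rows)


# --- summary tables ---------------------------------------------------------

def _params_of(df: pd.DataFrame, validated_only: bool) -> pd.DataFrame:
    sel = df[df["passed_validation"]] if validated_only else df
    return sel


def parameter_means(df: pd.DataFrame, hypothesis: Hypothesis | str,
                    validated_only: bool = True) -> pd.DataFrame:
    """Ensemble mean +/- sd per fitted parameter (validated sets by
    default, matching the published post-validation summaries)."""
    from .fitting import fitted_parameter_names

    sel = _params_of(df, validated_only)
    names = fitted_parameter_names(hypothesis)
    rows = [{"parameter": p,
             "mean": float(sel[p].mean()),
             "sd": float(sel[p].std(ddof=1)) if len(sel) > 1 else float("nan")}
            for p in names]
    return pd.DataFrame(rows).set_index("parameter")


def ensemble_sensitivities(df: pd.DataFrame, hypothesis: Hypothesis | str,
                           validated_only: bool = True,
                           parameters: tuple[str, ...] | None = None,
                           ) -> pd.DataFrame:
    """Mean +/- sd of per-set wild-type WUS sensitivities over an
    ensemble (sensitivities of individual sets, then averaged)."""
    sel = _params_of(df, validated_only)
    if parameters is None:
        parameters = SHARED_PARAM_NAMES
    values: dict[str, list[float]] = {p: [] for p in parameters}
    for _, row in sel.iterrows():
        params = ParameterSet.from_dict({p: row[p] for p in PARAM_NAMES})
        for p in parameters:
            try:
                values[p].append(sensitivity(params, p, "wild_type", hypothesis))
            except SolverError:
                values[p].append(float("nan"))
    rows = []
    for p in parameters:
        arr = np.asarray(values[p])
        rows.append({"parameter": p,
                     "mean": float(np.nanmean(arr)) if arr.size else float("nan"),
                     "sd": float(np.nanstd(arr, ddof=1)) if arr.size > 1
                     else float("nan")})
    return pd.DataFrame(rows).set_index("parameter")


def auc_ranking(df_model: pd.DataFrame, df_background: pd.DataFrame,
                label_model: str = "model", label_background: str = "background",
                validated_only: bool = True) -> pd.DataFrame:
    """Per-parameter AUC between a hypothesis ensemble (validated sets)
    and the background ensemble (optimized sets), sorted descending —
    the Table-3 style ranking of which parameters the hypothesis
    constrains."""
    sel = _params_of(df_model, validated_only)
    rows = []
    for p in SHARED_PARAM_NAMES:
        r = auc(sel[p].to_numpy(), df_background[p].to_numpy(),
                parameter=p, label_a=label_model, label_b=label_background)
        rows.append({"parameter": p, "relation": r.relation, "auc": r.auc})
    out = pd.DataFrame(rows).sort_values("auc", ascending=False,
                                         kind="mergesort")
    return out.reset_index(drop=True)


def crn_stronger_fraction(df: pd.DataFrame, hypothesis: Hypothesis | str,
                          validated_only: bool = True) -> float:
    """Fraction of ensemble members whose CRN pathway carries more
    signal than the CLV1 pathway at the wild-type equilibrium."""
    sel = _params_of(df, validated_only)
    if len(sel) == 0:
        return float("nan")
    count = 0
    for _, row in sel.iterrows():
        params = ParameterSet.from_dict({p: row[p] for p in PARAM_NAMES})
        clv1_sig, crn_sig = pathway_strengths(params, "wild_type", hypothesis)
        count += crn_sig > clv1_sig
    return count / len(sel)


def summary_tables(ensembles: dict[str, pd.DataFrame],
                   background_label: str = "background",
                   include_sensitivities: bool = True) -> dict[str, pd.DataFrame]:
    """Assemble the standard ensemble report: per-hypothesis parameter
    means (+ sensitivities) and AUC rankings against the background.

    Hypothesis ensembles are summarized over their validated sets; a
    label with no validated sets is skipped (there is nothing to
    summarize).  The background is summarized over all its rows.
    """
    if background_label not in ensembles:
        raise ValueError(f"ensembles must include {background_label!r}")
    bg = ensembles[background_label]
    out: dict[str, pd.DataFrame] = {}
    for label, df in ensembles.items():
        validated = label != background_label
        if validated and not df["passed_validation"].any():
            continue
        means = parameter_means(df, label if validated else "background",
                                validated_only=validated)
        if include_sensitivities:
            sens = ensemble_sensitivities(
                df, label if validated else "background",
                validated_only=validated)
            means = means.join(sens, rsuffix="_sensitivity")
        out[f"parameters_{label}"] = means
        if validated and len(bg) > 0:
            out[f"auc_{label}_vs_{background_label}"] = auc_ranking(
                df, bg, label_model=label, label_background=background_label)
    return out
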