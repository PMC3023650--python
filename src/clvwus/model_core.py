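"""Core model definitions for the CLAVATA-WUSCHEL feedback network.

The model tracks seven species: the free receptors CLV1 and CRN (the
latter standing in for the CRN/CLV2 complex), the free CLV3 peptide, the
two bound receptor complexes CLV1/CLV3 and CRN/CLV3, an intracellular
signal X fed by both bound receptors, and the transcription factor WUS.
Bound receptors activate X, X represses WUS production through a Hill
function, and WUS activates CLV3 production, closing the negative
feedback loop that maintains stem-cell homeostasis in the shoot apical
meristem.

Receptor genotypes are described declaratively: each genotype names the
parameters it zeroes, the species it removes, and whether it carries the
clv1-1 allele, whose mechanism depends on the hypothesis in force
(loss-of-signal: k3 -> k3_weak; interference: a k8-rate drain forming
non-functional CLV1:CRN complexes).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as _k

#: Canonical parameter order used in arrays, CSV ensembles and configs.
PARAM_NAMES: tuple[str, ...] = (
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "K", "n",
    "t1", "s1", "t2", "s2", "t3", "s3", "t4", "s4", "dW", "kW",
    "k3_weak", "k8",
)

#: The 19 parameters shared by every hypothesis (excludes k3_weak, k8).
SHARED_PARAM_NAMES: tuple[str, ...] = PARAM_NAMES[:19]

SPECIES_NAMES: tuple[str, ...] = (
    "CLV1", "CRN", "CLV3", "CLV1_CLV3", "CRN_CLV3", "X", "WUS",
)


class Hypothesis(str, enum.Enum):
    """Mechanism assumed for the clv1-1 non-null allele.

    ``background`` fits the network without the clv1-1 mutant at all and
    serves as the hypothesis-neutral reference ensemble.
    """

    LOSS_OF_SIGNAL = "loss_of_signal"
    INTERFERENCE = "interference"
    BACKGROUND = "background"

    @property
    def code(self) -> int:
        return {"loss_of_signal": _k.LOSS_OF_SIGNAL,
                "interference": _k.INTERFERENCE,
                "background": _k.BACKGROUND}[self.value]


@dataclass(frozen=True)
class ParameterSet:
    """The 19 shared kinetic parameters plus the two mutant-specific ones.

    Units are arbitrary but consistent; only ratios between parameters
    are biologically meaningful here.  All parameters must be positive
    except ``k3_weak`` and ``k8`` which may be zero (inactive mechanism).
    """

    k1: float  # CLV3 + CLV1 binding
    k2: float  # CLV1/CLV3 unbinding
    k3: float  # signal strength of bound CLV1 into X
    k4: float  # CLV3 + CRN binding
    k5: float  # CRN/CLV3 unbinding
    k6: float  # signal strength of bound CRN into X
    k7: float  # maximal WUS production
    K: float   # Hill threshold of X on WUS
    n: float   # Hill coefficient
    t1: float  # CLV1 turnover
    s1: float  # CLV1 production
    t2: float  # CRN turnover
    s2: float  # CRN production
    t3: float  # CLV3 turnover
    s3: float  # CLV3 basal production
    t4: float  # X turnover
    s4: float  # X basal production
    dW: float  # WUS degradation
    kW: float  # WUS -> CLV3 activation
    k3_weak: float = 0.0  # clv1-1 signal strength (loss-of-signal model)
    k8: float = 0.0       # CLV1:CRN interference rate (interference model)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES[:19]:
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"parameter {name} must be > 0, got {v}")
        if self.k3_weak < 0.0 or self.k8 < 0.0:
            raise ValueError("k3_weak and k8 must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {p: float(getattr(self, p)) for p in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        return cls(**{p: float(d[p]) for p in PARAM_NAMES if p in d})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls.from_dict(json.loads(text))

    def with_overrides(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)


# --- genotype algebra -------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """Declarative description of how an allele combination transforms
    the model: parameters forced to zero, species removed, and whether
    the hypothesis-dependent clv1-1 mechanism applies."""

    code: int
    zero_params: tuple[str, ...] = ()
    remove_clv1: bool = False
    remove_crn: bool = False
    has_clv1_1: bool = False


#: Registry of supported genotypes; new alleles are added here, not in code.
GENOTYPE_SPECS: dict[str, GenotypeSpec] = {
    "wild_type": GenotypeSpec(code=_k.WILD_TYPE),
    "crn1": GenotypeSpec(code=_k.CRN1, zero_params=("k6",)),
    "clv1_11": GenotypeSpec(code=_k.CLV1_11, remove_clv1=True),
    "crn1_clv2_1": GenotypeSpec(code=_k.CRN1_CLV2_1, remove_crn=True),
    "clv1_1": GenotypeSpec(code=_k.CLV1_1, has_clv1_1=True),
    "crn1_clv1_11": GenotypeSpec(
        code=_k.CRN1_CLV1_11, zero_params=("k6",), remove_clv1=True),
    "crn1_clv1_1": GenotypeSpec(
        code=_k.CRN1_CLV1_1, zero_params=("k6",), has_clv1_1=True),
}

GENOTYPE_NAMES: tuple[str, ...] = tuple(GENOTYPE_SPECS)
SINGLE_MUTANTS: tuple[str, ...] = ("crn1", "clv1_11", "crn1_clv2_1", "clv1_1")
DOUBLE_MUTANTS: tuple[str, ...] = ("crn1_clv1_11", "crn1_clv1_1")
#: Single mutants entering the background (clv1-1-free) energy.
BACKGROUND_MUTANTS: tuple[str, ...] = ("crn1", "clv1_11", "crn1_clv2_1")


@dataclass(frozen=True)
class Genotype:
    """A named allele combination plus the clv1-1 hypothesis in force."""

    name: str
    hypothesis: Hypothesis | str = Hypothesis.BACKGROUND

    def __post_init__(self) -> None:
        if self.name not in GENOTYPE_SPECS:
            raise ValueError(f"unknown genotype {self.name!r}; "
                             f"known: {sorted(GENOTYPE_SPECS)}")
        object.__setattr__(self, "hypothesis", Hypothesis(self.hypothesis))
        if self.spec.has_clv1_1 and self.hypothesis is Hypothesis.BACKGROUND:
            raise ValueError(
                f"genotype {self.name!r} carries clv1-1 and needs an explicit "
                "hypothesis (loss_of_signal or interference)")

    @property
    def spec(self) -> GenotypeSpec:
        return GENOTYPE_SPECS[self.name]


@dataclass(frozen=True)
class EffectiveModel:
    """Parameter values and structural flags after applying a genotype."""

    values: np.ndarray  # 19 shared effective values + effective k8
    remove_clv1: bool
    remove_crn: bool

    def to_array(self) -> np.ndarray:
        arr = np.empty(22)
        arr[:20] = self.values
        arr[20] = float(self.remove_clv1)
        arr[21] = float(self.remove_crn)
        return arr

    def __getattr__(self, name: str):
        names = SHARED_PARAM_NAMES + ("k8",)
        if name in names:
            return float(self.values[names.index(name)])
        raise AttributeError(name)


def apply_genotype(params: ParameterSet, genotype: Genotype | str,
                   hypothesis: Hypothesis | str | None = None) -> EffectiveModel:
    """Transform a parameter set into the effective model of a genotype.

    ``genotype`` may be a name, in which case ``hypothesis`` supplies the
    clv1-1 mechanism (required for clv1-1-carrying genotypes).
    """
    if isinstance(genotype, str):
        genotype = Genotype(genotype, Hypothesis(hypothesis)
                            if hypothesis is not None else Hypothesis.BACKGROUND)
    eff = _k.apply_genotype_arr(params.to_array(), genotype.spec.code,
                                genotype.hypothesis.code)
    return EffectiveModel(values=eff[:20].copy(),
                          remove_clv1=bool(eff[20] > 0.5),
                          remove_crn=bool(eff[21] > 0.5))


# --- dynamics ---------------------------------------------------------------

def rhs(state: np.ndarray, model: EffectiveModel) -> np.ndarray:
    """Mass-action time derivatives of the seven species.

    State order: [CLV1, CRN, CLV3, CLV1/CLV3, CRN/CLV3, X, WUS].  When a
    receptor is removed its concentration must be zero and its derivative
    (and that of its complex) is pinned to zero, so the reduced system is
    closed.  The interference drain -k8*[CLV1]*[CRN] applies to both free
    receptors when k8 > 0.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (7,):
        raise ValueError("state must have 7 components")
    if np.any(state < 0.0):
        raise ValueError("concentrations must be nonnegative")
    c1, c2, c3, cc1, cc2, x, wus = state
    m = model
    d = np.empty(7)
    interference = m.k8 * c1 * c2
    d[0] = m.t1 * (m.s1 - c1) - m.k1 * c1 * c3 + m.k2 * cc1 - interference
    d[1] = m.t2 * (m.s2 - c2) - m.k4 * c2 * c3 + m.k5 * cc2 - interference
    d[2] = (m.t3 * (m.s3 - c3) + m.kW * wus
            - m.k1 * c1 * c3 + m.k2 * cc1
            - m.k4 * c2 * c3 + m.k5 * cc2)
    d[3] = m.k1 * c1 * c3 - m.k2 * cc1 - m.t1 * cc1
    d[4] = m.k4 * c2 * c3 - m.k5 * cc2 - m.t2 * cc2
    d[5] = m.t4 * (m.s4 - x) + m.k3 * cc1 + m.k6 * cc2
    hill = _k.hill_production(model.to_array(), x)
    d[6] = hill - m.dW * wus
    if m.remove_clv1:
        d[0] = 0.0
        d[3] = 0.0
    if m.remove_crn:
        d[1] = 0.0
        d[4] = 0.0
    return d
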