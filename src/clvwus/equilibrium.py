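"""Fixed-point solver for the receptor-ligand network.

At steady state the bound complexes and the signal X are explicit
functions of the free species, which collapses the seven-species system
to three coupled balance equations for free CLV1, CRN and CLV3 at a
given WUS level, plus a scalar balance f(WUS) = 0 for WUS itself.  The
free-species system is solved with a damped Newton iteration and the WUS
balance by bisection on [0, k7/dW], a bracket on which f provably
changes sign exactly once (f(0) > 0 since production is positive, and
f(k7/dW) <= 0 since production is bounded by k7; f is strictly
decreasing because raising WUS raises CLV3, bound receptors and X, which
lowers the Hill production while the linear sink grows).

``integrate_to_steady_state`` provides an independent route to the same
fixed point by stiff time integration of the full seven-species system;
it is deliberately kept off the fitting hot path and exists to
cross-check the root-finding solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels as _k
from .model_core import (EffectiveModel, Genotype, Hypothesis, ParameterSet,
                         SPECIES_NAMES, apply_genotype, rhs)

NEWTON_TOL = _k.NEWTON_TOL
BISECT_TOL = _k.BISECT_TOL


class SolverError(RuntimeError):
    """Raised when the free-species Newton iteration fails to converge."""


@dataclass(frozen=True)
class EquilibriumState:
    """Fixed-point concentrations and solver diagnostics for one genotype."""

    concentrations: np.ndarray  # order: SPECIES_NAMES
    converged: bool
    bisection_iterations: int
    final_residual: float

    def __getattr__(self, name: str) -> float:
        if name in SPECIES_NAMES:
            return float(self.concentrations[SPECIES_NAMES.index(name)])
        raise AttributeError(name)

    @property
    def wus(self) -> float:
        return float(self.concentrations[6])


def lumped_rates(model: EffectiveModel) -> tuple[float, float]:
    """Lumped binding rates b1 = t1*k1/(k2+t1), b2 = t2*k4/(k5+t2) that
    fold complex turnover into the free-species balances."""
    b1 = model.t1 * model.k1 / (model.k2 + model.t1)
    b2 = model.t2 * model.k4 / (model.k5 + model.t2)
    return b1, b2


def solve_free_species(model: EffectiveModel, wus: float) -> tuple[float, float, float]:
    """Free [CLV1]*, [CRN]*, [CLV3]* at a clamped WUS level.

    Raises :class:`SolverError` on non-convergence (the fitting layer
    converts this into a sentinel energy rather than letting it escape).
    """
    if wus < 0.0:
        raise ValueError("wus must be nonnegative")
    c1, c2, c3, ok, _ = _k.solve_free_species_arr(model.to_array(), float(wus))
    if not ok:
        raise SolverError(f"free-species Newton did not converge at WUS={wus}")
    return c1, c2, c3


def wus_residual(model: EffectiveModel, wus: float) -> float:
    """f(WUS): Hill production at X*(WUS) minus dW*WUS."""
    if wus < 0.0:
        raise ValueError("wus must be nonnegative")
    f, ok = _k.wus_residual_arr(model.to_array(), float(wus))
    if not ok:
        raise SolverError(f"inner solve failed at WUS={wus}")
    return f


def solve_equilibrium(params: ParameterSet,
                      genotype: Genotype | str,
                      hypothesis: Hypothesis | str | None = None) -> EquilibriumState:
    """Full equilibrium for a genotype/parameter pair.

    Bisects f(WUS) on [0, k7/dW] to |f| < 1e-4, with each evaluation
    solving the inner free-species system to residual norm < 1e-3.
    Non-convergence is reported via the ``converged`` flag, never as an
    exception.
    """
    model = apply_genotype(params, genotype, hypothesis)
    state, ok, iters, resid = _k.solve_equilibrium_arr(model.to_array())
    return EquilibriumState(concentrations=state, converged=bool(ok),
                            bisection_iterations=int(iters),
                            final_residual=float(resid))


def solve_equilibrium_model(model: EffectiveModel) -> EquilibriumState:
    """As :func:`solve_equilibrium` but starting from an effective model."""
    state, ok, iters, resid = _k.solve_equilibrium_arr(model.to_array())
    return EquilibriumState(concentrations=state, converged=bool(ok),
                            bisection_iterations=int(iters),
                            final_residual=float(resid))


def integrate_to_steady_state(params: ParameterSet,
                              genotype: Genotype | str,
                              hypothesis: Hypothesis | str | None = None,
                              t_max: float = 1.0e6,
                              tol: float = 1.0e-8,
                              initial_state: np.ndarray | None = None,
                              ) -> tuple[np.ndarray, bool]:
    """Time-integration oracle: run the full ODE system until the
    max-norm of the derivative falls below ``tol`` (or ``t_max``).

    Returns (state, reached_steady_state).  Uses LSODA, which switches
    to a stiff integrator automatically; integration failures raise.
    """
    model = apply_genotype(params, genotype, hypothesis)

    def fun(_t: float, y: np.ndarray) -> np.ndarray:
        return rhs(np.maximum(y, 0.0), model)

    if initial_state is None:
        y = np.zeros(7)
    else:
        y = np.asarray(initial_state, dtype=float).copy()
        if np.any(y < 0.0):
            raise ValueError("initial state must be nonnegative")
    if model.remove_clv1:
        y[0] = y[3] = 0.0
    if model.remove_crn:
        y[1] = y[4] = 0.0

    t, span = 0.0, 10.0
    while t < t_max:
        sol = solve_ivp(fun, (t, min(t + span, t_max)), y, method="LSODA",
                        rtol=1.0e-10, atol=1.0e-12)
        if not sol.success:
            raise SolverError(f"time integration failed: {sol.message}")
        y = np.maximum(sol.y[:, -1], 0.0)
        t = sol.t[-1]
        if np.max(np.abs(rhs(y, model))) < tol:
            return y, True
        span *= 4.0
    return y, False
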