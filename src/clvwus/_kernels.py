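"""Compiled numerical core.

Everything here operates on flat float64 arrays so it can be jitted with
numba; the public modules wrap these kernels in typed dataclass APIs.

Parameter vector layout (length 21)::

    0  k1   CLV3->CLV1 binding            11 t2   CRN turnover
    1  k2   CLV1/CLV3 unbinding           12 s2   CRN production
    2  k3   bound-CLV1 signal strength    13 t3   CLV3 turnover
    3  k4   CLV3->CRN binding             14 s3   CLV3 basal production
    4  k5   CRN/CLV3 unbinding            15 t4   X turnover
    5  k6   bound-CRN signal strength     16 s4   X basal production
    6  k7   maximal WUS production        17 dW   WUS degradation
    7  K    Hill threshold                18 kW   WUS->CLV3 activation
    8  n    Hill coefficient              19 k3_weak  clv1-1 loss-of-signal
    9  t1   CLV1 turnover                 20 k8       clv1-1 interference
    10 s1   CLV1 production

Effective-model vector layout (length 22): entries 0..18 as above after
genotype substitution, 19 = effective k8, 20 = remove_clv1 flag,
21 = remove_crn flag (flags stored as 0.0/1.0).
"""

import numpy as np
from numba import njit

N_PARAMS = 21
N_SHARED = 19

# genotype codes
WILD_TYPE = 0
CRN1 = 1
CLV1_11 = 2
CRN1_CLV2_1 = 3
CLV1_1 = 4
CRN1_CLV1_11 = 5
CRN1_CLV1_1 = 6

# hypothesis codes
LOSS_OF_SIGNAL = 0
INTERFERENCE = 1
BACKGROUND = 2

# solver tolerances: Newton residual on the free-species derivatives and
# bisection residual on the WUS balance
NEWTON_TOL = 1.0e-3
BISECT_TOL = 1.0e-4
NEWTON_MAX_ITER = 100
BISECT_MAX_ITER = 200

ENERGY_FAIL = 1.0e30


@njit(cache=True)
def apply_genotype_arr(params, genotype, hypothesis):
    """Map a parameter vector to the effective model of one genotype.

    Null alleles remove the receptor species; crn-1 silences the CRN
    signal (k6 = 0) but leaves binding intact; clv1-1 either swaps k3 for
    k3_weak (loss-of-signal) or switches on the k8 cross-complex drain
    (interference).
    """
    eff = np.zeros(22)
    eff[:N_SHARED] = params[:N_SHARED]
    # k8 inactive unless the interference clv1-1 allele is present
    eff[19] = 0.0
    if genotype == CRN1 or genotype == CRN1_CLV1_11 or genotype == CRN1_CLV1_1:
        eff[5] = 0.0  # k6: CRN binds but no longer signals
    if genotype == CLV1_11 or genotype == CRN1_CLV1_11:
        eff[20] = 1.0  # CLV1 species removed entirely
    if genotype == CRN1_CLV2_1:
        eff[21] = 1.0  # CRN species removed entirely
    if genotype == CLV1_1 or genotype == CRN1_CLV1_1:
        if hypothesis == LOSS_OF_SIGNAL:
            eff[2] = params[19]  # k3 -> k3_weak
        else:
            eff[19] = params[20]  # interference: k8 active
    return eff


@njit(cache=True)
def free_species_residual(eff, c1, c2, c3, wus):
    """Time derivatives of free CLV1, CRN and CLV3 with the bound
    complexes at their conditional steady state (the lumped b1/b2 form)."""
    k1, k2 = eff[0], eff[1]
    k4, k5 = eff[3], eff[4]
    t1, s1 = eff[9], eff[10]
    t2, s2 = eff[11], eff[12]
    t3, s3 = eff[13], eff[14]
    kw = eff[18]
    k8 = eff[19]
    b1 = t1 * k1 / (k2 + t1)
    b2 = t2 * k4 / (k5 + t2)
    f1 = t1 * (s1 - c1) - b1 * c1 * c3 - k8 * c1 * c2
    f2 = t2 * (s2 - c2) - b2 * c2 * c3 - k8 * c1 * c2
    f3 = t3 * (s3 - c3) - b1 * c1 * c3 - b2 * c2 * c3 + kw * wus
    return f1, f2, f3


@njit(cache=True)
def solve_free_species_arr(eff, wus):
    """Newton iteration for the free-species fixed point at a given WUS.

    Removed species are eliminated by pinning their row/column of the
    Jacobian to the identity, which keeps the 3x3 solve nonsingular.
    Steps are damped (halved) while any active concentration would go
    negative.  Returns (c1, c2, c3, converged, iterations).
    """
    no_clv1 = eff[20] > 0.5
    no_crn = eff[21] > 0.5
    k1, k2 = eff[0], eff[1]
    k4, k5 = eff[3], eff[4]
    t1, s1 = eff[9], eff[10]
    t2, s2 = eff[11], eff[12]
    t3, s3 = eff[13], eff[14]
    k8 = eff[19]
    b1 = t1 * k1 / (k2 + t1)
    b2 = t2 * k4 / (k5 + t2)

    # start from the fully uncoupled balance
    c1 = 0.0 if no_clv1 else s1
    c2 = 0.0 if no_crn else s2
    c3 = s3 + eff[18] * wus / t3

    for it in range(NEWTON_MAX_ITER):
        f1, f2, f3 = free_species_residual(eff, c1, c2, c3, wus)
        if no_clv1:
            f1 = 0.0
        if no_crn:
            f2 = 0.0
        norm = np.sqrt(f1 * f1 + f2 * f2 + f3 * f3)
        if norm < NEWTON_TOL:
            return c1, c2, c3, True, it
        # Jacobian of (f1, f2, f3) in (c1, c2, c3)
        j11 = -t1 - b1 * c3 - k8 * c2
        j12 = -k8 * c1
        j13 = -b1 * c1
        j21 = -k8 * c2
        j22 = -t2 - b2 * c3 - k8 * c1
        j23 = -b2 * c2
        j31 = -b1 * c3
        j32 = -b2 * c3
        j33 = -t3 - b1 * c1 - b2 * c2
        if no_clv1:
            j11, j12, j13 = 1.0, 0.0, 0.0
            j21 = 0.0
            j31 = 0.0
        if no_crn:
            j21, j22, j23 = 0.0, 1.0, 0.0
            j12 = 0.0
            j32 = 0.0
        det = (j11 * (j22 * j33 - j23 * j32)
               - j12 * (j21 * j33 - j23 * j31)
               + j13 * (j21 * j32 - j22 * j31))
        if det == 0.0:
            return c1, c2, c3, False, it
        r1, r2, r3 = -f1, -f2, -f3
        d1 = (r1 * (j22 * j33 - j23 * j32)
              - j12 * (r2 * j33 - j23 * r3)
              + j13 * (r2 * j32 - j22 * r3)) / det
        d2 = (j11 * (r2 * j33 - j23 * r3)
              - r1 * (j21 * j33 - j23 * j31)
              + j13 * (j21 * r3 - r2 * j31)) / det
        d3 = (j11 * (j22 * r3 - r2 * j32)
              - j12 * (j21 * r3 - r2 * j31)
              + r1 * (j21 * j32 - j22 * j31)) / det
        # damp while a step would cross zero
        for _ in range(60):
            if (c1 + d1 >= 0.0) and (c2 + d2 >= 0.0) and (c3 + d3 >= 0.0):
                break
            d1 *= 0.5
            d2 *= 0.5
            d3 *= 0.5
        c1 += d1
        c2 += d2
        c3 += d3
    f1, f2, f3 = free_species_residual(eff, c1, c2, c3, wus)
    if no_clv1:
        f1 = 0.0
    if no_crn:
        f2 = 0.0
    ok = np.sqrt(f1 * f1 + f2 * f2 + f3 * f3) < NEWTON_TOL
    return c1, c2, c3, ok, NEWTON_MAX_ITER


@njit(cache=True)
def complexes_and_x(eff, c1, c2, c3):
    """Bound complexes and the signal X from the free species."""
    k1, k2 = eff[0], eff[1]
    k4, k5 = eff[3], eff[4]
    t1, t2 = eff[9], eff[11]
    cc1 = k1 / (k2 + t1) * c1 * c3
    cc2 = k4 / (k5 + t2) * c2 * c3
    x = eff[16] + (eff[2] * cc1 + eff[5] * cc2) / eff[15]
    return cc1, cc2, x


@njit(cache=True)
def hill_production(eff, x):
    """WUS production k7 * K^n / (K^n + X^n), overflow safe."""
    k7, kk, n = eff[6], eff[7], eff[8]
    if x <= 0.0:
        return k7
    z = n * np.log(x / kk)
    if z > 700.0:
        return 0.0
    return k7 / (1.0 + np.exp(z))


@njit(cache=True)
def wus_residual_arr(eff, wus):
    """f(WUS) = production(X*(WUS)) - dW * WUS; root is the equilibrium.

    Returns (f, inner_converged)."""
    c1, c2, c3, ok, _ = solve_free_species_arr(eff, wus)
    if not ok:
        return 0.0, False
    _, _, x = complexes_and_x(eff, c1, c2, c3)
    return hill_production(eff, x) - eff[17] * wus, True


@njit(cache=True)
def solve_equilibrium_arr(eff):
    """Bisection on the WUS balance over [0, k7/dW].

    Returns (state7, converged, bisect_iters, final_residual) with
    state7 = [CLV1, CRN, CLV3, CLV1/CLV3, CRN/CLV3, X, WUS].
    """
    state = np.zeros(7)
    lo = 0.0
    hi = eff[6] / eff[17]
    # refine past the |f| criterion until the bracket itself is narrow,
    # so the returned WUS is accurate even where f is shallow (small dW)
    width_tol = 1.0e-7 * (1.0 + hi)
    wus = 0.5 * (lo + hi)
    f = 0.0
    ok = False
    it = 0
    for it in range(BISECT_MAX_ITER):
        wus = 0.5 * (lo + hi)
        f, inner_ok = wus_residual_arr(eff, wus)
        if not inner_ok:
            return state, False, it, np.inf
        if abs(f) < BISECT_TOL and (hi - lo) < width_tol:
            ok = True
            break
        if f > 0.0:
            lo = wus
        else:
            hi = wus
    c1, c2, c3, inner_ok, _ = solve_free_species_arr(eff, wus)
    cc1, cc2, x = complexes_and_x(eff, c1, c2, c3)
    state[0] = c1
    state[1] = c2
    state[2] = c3
    state[3] = cc1
    state[4] = cc2
    state[5] = x
    state[6] = wus
    return state, ok and inner_ok, it, abs(f)


@njit(cache=True)
def wus_star(params, genotype, hypothesis):
    """Equilibrium WUS for one genotype; (value, converged)."""
    eff = apply_genotype_arr(params, genotype, hypothesis)
    state, ok, _, _ = solve_equilibrium_arr(eff)
    return state[6], ok


@njit(cache=True)
def energy_arr(params, hypothesis, genotypes, targets):
    """Sum of squared deviations between normalized mutant WUS and the
    experimental targets; solver failures map to a sentinel energy."""
    w_wt, ok = wus_star(params, WILD_TYPE, hypothesis)
    if (not ok) or w_wt <= 0.0:
        return ENERGY_FAIL
    e = 0.0
    for i in range(genotypes.shape[0]):
        w, ok = wus_star(params, genotypes[i], hypothesis)
        if not ok:
            return ENERGY_FAIL
        d = w / w_wt - targets[i]
        e += d * d
    return e


@njit(cache=True)
def fitted_indices(hypothesis):
    """Indices of the parameters explored by the annealer: the 19 shared
    ones plus the hypothesis-specific mutant parameter."""
    if hypothesis == LOSS_OF_SIGNAL:
        idx = np.empty(20, dtype=np.int64)
        for i in range(19):
            idx[i] = i
        idx[19] = 19  # k3_weak
    elif hypothesis == INTERFERENCE:
        idx = np.empty(20, dtype=np.int64)
        for i in range(19):
            idx[i] = i
        idx[19] = 20  # k8
    else:
        idx = np.empty(19, dtype=np.int64)
        for i in range(19):
            idx[i] = i
    return idx


@njit(cache=True)
def anneal_arr(seed, hypothesis, genotypes, targets,
               beta_initial, beta_final, beta_factor,
               iterations_per_beta, move_factor,
               init_low, init_high):
    """One simulated-annealing optimization.

    Metropolis acceptance P = min(1, exp(-beta dE)); one randomly chosen
    fitted parameter multiplied or divided by move_factor per proposal;
    beta multiplied by beta_factor after each block.  Returns
    (best_params, best_energy).  Best tracking is bookkeeping only; the
    chain itself is never reset.
    """
    np.random.seed(seed)
    idx = fitted_indices(hypothesis)
    params = np.zeros(N_PARAMS)
    for i in range(idx.shape[0]):
        params[idx[i]] = init_low + (init_high - init_low) * np.random.random()
    e_old = energy_arr(params, hypothesis, genotypes, targets)
    best = params.copy()
    e_best = e_old
    beta = beta_initial
    while beta <= beta_final:
        for _ in range(iterations_per_beta):
            j = idx[np.random.randint(0, idx.shape[0])]
            old = params[j]
            if np.random.random() < 0.5:
                params[j] = old * move_factor
            else:
                params[j] = old / move_factor
            e_new = energy_arr(params, hypothesis, genotypes, targets)
            accept = True
            if e_new > e_old:
                accept = np.random.random() < np.exp(-beta * (e_new - e_old))
            if accept:
                e_old = e_new
                if e_new < e_best:
                    e_best = e_new
                    best = params.copy()
            else:
                params[j] = old
        beta *= beta_factor
    return best, e_best
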