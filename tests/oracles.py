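"""Independent brute-force reference implementations used as oracles.

These deliberately avoid the vectorized/cumulative-sum code paths of the
package: posteriors are evaluated state by state from the printed Poisson
product, weighted correlations by explicit double sums, and line
goodness-of-fit by per-line boolean masks.
"""

import math

import numpy as np


def bf_log_posterior(rates: np.ndarray, counts: np.ndarray, tau: float) -> np.ndarray:
    """Per-state log posterior from the Poisson product formula.

    rates: (n_units, n_states); counts: (n_units,).  Uniform prior,
    normalized across all states.
    """
    n_units, n_states = rates.shape
    log_num = np.empty(n_states)
    for s in range(n_states):
        acc = 0.0
        for i in range(n_units):
            acc += counts[i] * math.log(rates[i, s]) - tau * rates[i, s]
        log_num[s] = acc
    m = log_num.max()
    log_z = m + math.log(sum(math.exp(v - m) for v in log_num))
    return log_num - log_z


def bf_weighted_correlation(pmat: np.ndarray) -> float:
    """Weighted correlation by explicit double sums over (x, t)."""
    D, T = pmat.shape
    W = ex = et = 0.0
    for j in range(D):
        for i in range(T):
            W += pmat[j, i]
            ex += pmat[j, i] * j
            et += pmat[j, i] * i
    ex /= W
    et /= W
    cxt = cxx = ctt = 0.0
    for j in range(D):
        for i in range(T):
            cxt += pmat[j, i] * (j - ex) * (i - et)
            cxx += pmat[j, i] * (j - ex) ** 2
            ctt += pmat[j, i] * (i - et) ** 2
    return (cxt / W) / math.sqrt((cxx / W) * (ctt / W))


def bf_line_mass(
    pmat: np.ndarray, v_cm_s: float, rho_cm: float, bin_cm: float,
    dt_s: float, d_cm: float,
) -> float:
    """Average posterior mass within d of one line, via boolean masks."""
    P = np.asarray(pmat, float)
    csum = P.sum(axis=0, keepdims=True)
    csum = np.where(csum == 0, 1.0, csum)
    P = P / csum
    D, T = P.shape
    centers = (np.arange(D) + 0.5) * bin_cm
    total = 0.0
    for k in range(T):
        pos = rho_cm + v_cm_s * k * dt_s
        # same 1e-9 cm boundary tolerance as the implementation
        total += P[np.abs(centers - pos) <= d_cm + 1e-9, k].sum()
    return total / T


def bf_best_fit_line(
    pmat: np.ndarray, bin_cm: float, dt_s: float, d_cm: float = 8.0,
    v_min: float = 1.0, v_max: float = 15.0, v_step: float = 0.25,
):
    """Exhaustive line search with the same grid and tie-breaks."""
    D, _T = pmat.shape
    v_abs = np.arange(v_min, v_max + 1e-9, v_step)
    vs = np.concatenate([v_abs, -v_abs]) * 100.0
    vs = vs[np.argsort(np.abs(vs), kind="stable")]
    rhos = (np.arange(D) + 0.5) * bin_cm
    scored = [
        (bf_line_mass(pmat, v, rho, bin_cm, dt_s, d_cm), v, rho)
        for v in vs
        for rho in rhos
    ]
    r_max = max(s[0] for s in scored)
    ties = [s for s in scored if s[0] >= r_max - 1e-12]
    if len(ties) > 1:
        # same tie-break as the implementation: tight half-bin vicinity
        tight = [
            bf_line_mass(pmat, v, rho, bin_cm, dt_s, bin_cm / 2)
            for _, v, rho in ties
        ]
        tmax = max(tight)
        ties = [s for s, tg in zip(ties, tight) if tg >= tmax - 1e-12]
    _, v, rho = ties[0]
    return r_max, v / 100.0, rho  # (r_max, v_mps, rho_cm)


def random_pmat(rng: np.random.Generator, D: int, T: int) -> np.ndarray:
    P = rng.random((D, T))
    return P / P.sum()
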