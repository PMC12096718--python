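"""Independent oracles used by the test suite.

These deliberately avoid the package's evaluation paths: numerical ODE
integration for the PK model, exhaustive enumeration for the rank-sum
test, and brute-force search for ROC cutoffs and conditional modes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import solve_ivp

from firstdose.pk import DosingRegimen, StructuralParameters


def ode_concentrations(p: StructuralParameters, r: DosingRegimen, times) -> np.ndarray:
    """Two-compartment infusion concentrations by stiff ODE integration.

    dA1/dt = R(t) - (k10 + k12) A1 + k21 A2; dA2/dt = k12 A1 - k21 A2;
    C = A1/V1. Integrated piecewise between infusion knots so the
    discontinuous input never degrades accuracy.
    """
    times = np.asarray(times, dtype=float)
    k10, k12, k21 = p.k10, p.k12, p.k21
    evs = r.events(until=float(times.max()) + 1e-9)

    def rate(t: float) -> float:
        return sum(ev.rate for ev in evs if ev.start <= t < ev.end)

    def rhs(t, A):
        return [rate(t) - (k10 + k12) * A[0] + k21 * A[1], k12 * A[0] - k21 * A[1]]

    knots = sorted({0.0, *(ev.start for ev in evs), *(ev.end for ev in evs), *times.tolist()})
    A = np.array([0.0, 0.0])
    out = {0.0: 0.0}
    for a, b in zip(knots, knots[1:]):
        sol = solve_ivp(rhs, (a, b), A, method="LSODA", rtol=1e-11, atol=1e-13, dense_output=True)
        for t in times:
            if a < t <= b:
                out[float(t)] = float(sol.sol(t)[0]) / p.V1
        A = sol.y[:, -1]
    return np.array([out[float(t)] for t in times])


def wilcoxon_p_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Enumerates every way to split the pooled sample into groups of the
    observed sizes; the p-value is the fraction of splits whose rank sum is
    at least as extreme (two-sided, by min(2*min-tail, 1) on the U statistic
    with midranks for ties).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.array(x + y)
    m = len(x)
    idx_all = range(len(pooled))

    def u_stat(ix) -> float:
        xs = pooled[list(ix)]
        ys = pooled[[i for i in idx_all if i not in set(ix)]]
        gt = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        return gt

    u_obs = u_stat(range(m))
    mn = m * len(y)
    us = [u_stat(c) for c in itertools.combinations(idx_all, m)]
    dev_obs = abs(u_obs - mn / 2.0)
    count = sum(1 for u in us if abs(u - mn / 2.0) >= dev_obs - 1e-12)
    return count / len(us)


def youden_bruteforce(scores, condition) -> tuple[float, float]:
    """(best J, cutoff) over all midpoint candidates; positive = score below cutoff.

    Ties broken toward higher specificity, then the smaller cutoff, matching
    the documented rule.
    """
    scores = np.asarray(scores, dtype=float)
    condition = np.asarray(condition, dtype=bool)
    uniq = np.unique(scores)
    best = None
    for c in (uniq[:-1] + uniq[1:]) / 2.0:
        sens = float(np.mean(scores[condition] < c))
        spec = float(np.mean(scores[~condition] >= c))
        key = (sens + spec - 1.0, spec, -c)
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[0][0], best[1]


def grid_search_mode(fun, bounds, step) -> np.ndarray:
    """Arg-max of `fun` over a dense rectangular grid (brute-force mode oracle)."""
    axes = [np.arange(lo, hi + step / 2, step) for lo, hi in bounds]
    best_x, best_v = None, -math.inf
    for point in itertools.product(*axes):
        v = fun(np.array(point))
        if v > best_v:
            best_v, best_x = v, np.array(point)
    return best_x
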