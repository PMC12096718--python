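"""Cohort-level statistics: exact rank-sum comparisons, ROC cutoffs, ECDF analyses.

Two-group comparisons use the Wilcoxon rank-sum (Mann-Whitney) test —
exact for small samples, normal approximation with tie correction for
larger ones — together with the Hodges–Lehmann shift estimate and its
exact-inversion confidence interval. ROC analysis finds the Cmin/Cmax
ratio cutoff that best separates suspected-ARC from non-ARC patients
(Youden's J), where "positive" means a ratio BELOW the cutoff: a steep
peak-to-trough decline indicates augmented clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RocResult",
    "wilcoxon_exact",
    "roc_cutoff",
    "cda_curves",
    "summarize_cohort",
]

#: Combined sample size up to which the exact Mann-Whitney distribution is used.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: medians/IQRs, exact p, Hodges–Lehmann shift CI."""

    label_x: str
    label_y: str
    n_x: int
    n_y: int
    median_x: float
    median_y: float
    iqr_x: tuple[float, float]
    iqr_y: tuple[float, float]
    p_value: float
    shift_estimate: float  # Hodges-Lehmann estimate of location(x) - location(y)
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("confidence bounds must be ordered")


@dataclass(frozen=True)
class RocResult:
    """ROC cutoff analysis result; curve points are (FPR, TPR) sorted by FPR."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    curve: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if not 0 <= v <= 1:
                raise ValueError("sensitivity/specificity must be in [0, 1]")


@lru_cache(maxsize=None)
def _mannwhitney_null_counts(m: int, n: int) -> tuple[int, ...]:
    """Counts of rank arrangements per U value for sample sizes (m, n), no ties.

    Standard recursion: c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u), giving
    the number of ways U(x over y) = u out of C(m+n, m) arrangements.
    """
    from functools import lru_cache as _lc

    @_lc(maxsize=None)
    def c(a: int, b: int, u: int) -> int:
        if u < 0 or u > a * b:
            return 0
        if a == 0 or b == 0:
            return 1 if u == 0 else 0
        return c(a - 1, b, u - b) + c(a, b - 1, u)

    return tuple(c(m, n, u) for u in range(m * n + 1))


def _exact_critical_u(m: int, n: int, alpha_half: float) -> int:
    """Largest u with P(U <= u) <= alpha_half under the exact null; -1 if none."""
    counts = _mannwhitney_null_counts(m, n)
    total = math.comb(m + n, m)
    cum = 0
    k = -1
    for u, cnt in enumerate(counts):
        cum += cnt
        if cum / total <= alpha_half:
            k = u
        else:
            break
    return k


def wilcoxon_exact(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
    alpha: float = 0.05,
) -> GroupComparison:
    """Wilcoxon rank-sum comparison with Hodges–Lehmann shift estimate and CI.

    The two-sided p-value is exact (full null distribution) for combined
    n <= 25, and a tie-corrected normal approximation above. The shift is
    the median of all pairwise differences x_i - y_j; its CI inverts the
    exact Mann-Whitney distribution (normal-approximation ranks for large
    samples). If every value is tied across both groups, p = 1 is returned
    with a degenerate zero-width interval.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty")

    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    shift = float(np.median(diffs))

    all_tied = np.all(x == x[0]) and np.all(y == x[0])
    if all_tied:
        p = 1.0
        ci_low = ci_high = 0.0
    else:
        method = "exact" if (m + n <= EXACT_N_MAX and not _has_ties(x, y)) else "asymptotic"
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
        p = min(p, 1.0)
        if m + n <= EXACT_N_MAX:
            k = _exact_critical_u(m, n, alpha / 2.0)
        else:
            z = sps.norm.ppf(alpha / 2.0)
            k = int(math.floor(m * n / 2.0 + z * math.sqrt(m * n * (m + n + 1) / 12.0) - 0.5))
        if k < 0:  # too few arrangements for the requested coverage: widest interval
            ci_low, ci_high = float(diffs[0]), float(diffs[-1])
        else:
            ci_low, ci_high = float(diffs[k]), float(diffs[m * n - 1 - k])

    qx = np.percentile(x, [25, 75])
    qy = np.percentile(y, [25, 75])
    return GroupComparison(
        label_x=label_x,
        label_y=label_y,
        n_x=m,
        n_y=n,
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
        iqr_x=(float(qx[0]), float(qx[1])),
        iqr_y=(float(qy[0]), float(qy[1])),
        p_value=p,
        shift_estimate=shift,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def roc_cutoff(scores: Sequence[float], condition: Sequence[bool]) -> RocResult:
    """Youden-optimal cutoff where "positive" means score BELOW the cutoff.

    Candidate cutoffs are the midpoints between adjacent sorted unique
    scores. Ties in J are broken toward higher specificity, then toward the
    smaller cutoff. Sensitivity = P(score < c | condition); specificity =
    P(score >= c | not condition).
    """
    scores = np.asarray(list(scores), dtype=float)
    condition = np.asarray(list(condition), dtype=bool)
    if scores.shape != condition.shape:
        raise ValueError("scores and condition must have equal length")
    n_pos = int(condition.sum())
    if n_pos == 0 or n_pos == len(condition):
        raise ValueError("both classes must be represented")

    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct scores")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    pos = scores[condition]
    neg = scores[~condition]
    best = None  # (J, specificity, -cutoff) maximized lexicographically
    curve: list[tuple[float, float]] = [(0.0, 0.0)]
    for c in candidates:
        sens = float(np.mean(pos < c))
        spec = float(np.mean(neg >= c))
        curve.append((1.0 - spec, sens))
        key = (sens + spec - 1.0, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    curve.append((1.0, 1.0))
    curve_sorted = tuple(sorted(set(curve)))
    assert best is not None
    (j, _, _), cutoff, sens, spec = best
    return RocResult(cutoff=float(cutoff), sensitivity=sens, specificity=spec, youden_j=float(j), curve=curve_sorted)


def cda_curves(
    scores: Sequence[float], condition: Sequence[bool]
) -> tuple[pd.DataFrame, float]:
    """Per-group empirical CDFs on a shared grid and the max-separation cutoff.

    Returns a DataFrame with columns score, ecdf_condition, ecdf_other
    evaluated at the candidate cutoffs (midpoints between adjacent unique
    scores), and the cutoff maximizing the vertical ECDF distance — which
    coincides with the Youden cutoff of `roc_cutoff` for this construction.
    """
    scores = np.asarray(list(scores), dtype=float)
    condition = np.asarray(list(condition), dtype=bool)
    if condition.sum() in (0, len(condition)):
        raise ValueError("both classes must be represented")
    uniq = np.unique(scores)
    grid = np.concatenate([(uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]]) if len(uniq) > 1 else uniq
    pos = np.sort(scores[condition])
    neg = np.sort(scores[~condition])
    ecdf_pos = np.searchsorted(pos, grid, side="left") / len(pos)
    ecdf_neg = np.searchsorted(neg, grid, side="left") / len(neg)
    # at the top grid point include equal values so both ECDFs reach 1
    ecdf_pos[-1] = np.searchsorted(pos, grid[-1], side="right") / len(pos)
    ecdf_neg[-1] = np.searchsorted(neg, grid[-1], side="right") / len(neg)
    df = pd.DataFrame({"score": grid, "ecdf_condition": ecdf_pos, "ecdf_other": ecdf_neg})
    sep = ecdf_pos - ecdf_neg
    best = int(np.argmax(sep[:-1])) if len(grid) > 1 else 0
    return df, float(grid[best])


def _median_iqr(s: pd.Series) -> str:
    q1, q2, q3 = s.quantile([0.25, 0.5, 0.75])
    return f"{q2:.3g} ({q1:.3g}-{q3:.3g})"


def summarize_cohort(report: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-drug cohort summary tables from a per-patient exposure report.

    `report` needs one row per patient with columns: drug, age, weight,
    height, serum_creatinine, relative_egfr, crcl, egfr_group, arc,
    suspected_arc, regimen, cmin_observed, cmin_predicted, attained_100,
    ft_above_interval, ft_above_24h, cmin_cmax_ratio. Returns tables
    'characteristics', 'regimens', 'attainment', 'cmin_by_egfr'.
    """
    if report.empty:
        raise ValueError("cohort report is empty")
    out: dict[str, pd.DataFrame] = {}

    cont = ["age", "weight", "height", "serum_creatinine", "relative_egfr", "crcl"]
    rows = {}
    for drug, grp in report.groupby("drug"):
        col = {f"{c}": _median_iqr(grp[c]) for c in cont if c in grp}
        col["n"] = str(len(grp))
        col["suspected_arc"] = f"{int(grp['suspected_arc'].sum())} ({100 * grp['suspected_arc'].mean():.0f}%)"
        rows[drug] = col
    out["characteristics"] = pd.DataFrame(rows)

    regimens = report.groupby(["drug", "regimen"]).size().rename("n").reset_index()
    regimens["pct"] = regimens.groupby("drug")["n"].transform(lambda s: 100 * s / s.sum())
    out["regimens"] = regimens

    att = []
    for drug, grp in report.groupby("drug"):
        non = ~grp["attained_100"].astype(bool)
        sub = grp.loc[non]
        att.append(
            {
                "drug": drug,
                "n": len(grp),
                "n_not_attained": int(non.sum()),
                "pct_not_attained": 100.0 * non.mean(),
                "median_ft_interval_nonattained": float(sub["ft_above_interval"].median()) if len(sub) else float("nan"),
                "median_ft_24h_nonattained": float(sub["ft_above_24h"].median()) if len(sub) else float("nan"),
                "n_nonattained_suspected_arc": int((non & grp["suspected_arc"].astype(bool)).sum()),
                "n_nonattained_egfr_above_90": int((non & (grp["egfr_group"] == "above_90")).sum()),
            }
        )
    out["attainment"] = pd.DataFrame(att)

    cmin_rows = []
    for (drug, group), grp in report.groupby(["drug", "egfr_group"]):
        s = grp["cmin_observed"].dropna()
        if len(s):
            cmin_rows.append({"drug": drug, "egfr_group": group, "n": len(s), "median_cmin": float(s.median())})
    out["cmin_by_egfr"] = pd.DataFrame(cmin_rows)
    return out
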