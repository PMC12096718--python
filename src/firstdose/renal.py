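"""Renal function estimation and classification for critically ill adults.

Implements the creatinine-based estimators used in beta-lactam dosing
studies: the race-free CKD-EPI 2021 eGFR equation, Du Bois body surface
area, absolute (de-indexed) eGFR, Cockcroft-Gault creatinine clearance,
the ARC (augmented renal clearance) risk score, the suspected-ARC
classification rule, and KDIGO acute-kidney-injury criteria.

Serum creatinine is stored in µmol/L throughout; the classic formulas use
mg/dL, and the fixed conversion factor is 88.42 µmol/L per mg/dL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

__all__ = [
    "PatientCovariates",
    "RenalAssessment",
    "CreatinineTimeline",
    "UMOL_PER_MGDL",
    "relative_egfr_ckdepi2021",
    "bsa_dubois",
    "absolute_egfr",
    "crcl_cockcroft_gault",
    "arc_score",
    "classify_arc",
    "kdigo_aki",
    "assess_renal_function",
    "DEFAULT_ARC_SCORE_TABLE",
]

#: µmol/L of creatinine per mg/dL.
UMOL_PER_MGDL = 88.42


@dataclass(frozen=True)
class PatientCovariates:
    """Demographic and clinical covariates feeding renal estimators and PK models.

    Attributes
    ----------
    age : float
        Years, strictly positive.
    sex : str
        ``"male"`` or ``"female"``.
    weight, height : float
        kg and cm, strictly positive.
    serum_creatinine : float
        Plasma creatinine in µmol/L, strictly positive.
    sofa : int
        Sequential organ failure assessment score, >= 0.
    trauma_admission : bool
        Whether the ICU admission was for trauma.
    """

    patient_id: str
    age: float
    sex: Literal["male", "female"]
    weight: float
    height: float
    serum_creatinine: float
    sofa: int = 0
    trauma_admission: bool = False

    def __post_init__(self) -> None:
        for name in ("age", "weight", "height", "serum_creatinine"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.sofa < 0:
            raise ValueError(f"sofa must be >= 0, got {self.sofa}")


@dataclass(frozen=True)
class RenalAssessment:
    """Bundle of renal-function quantities for one patient on the sampling day."""

    relative_egfr: float  # mL/min/1.73 m^2
    bsa: float  # m^2
    absolute_egfr: float  # mL/min
    crcl: float  # mL/min
    arc_score: int  # points
    arc: bool
    suspected_arc: bool
    egfr_group: Literal["above_90", "at_or_below_90"]

    def __post_init__(self) -> None:
        expected = self.relative_egfr * self.bsa / 1.73
        if abs(self.absolute_egfr - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("absolute_egfr inconsistent with relative_egfr * bsa / 1.73")
        if self.arc and not self.suspected_arc:
            raise ValueError("arc implies suspected_arc")


@dataclass(frozen=True)
class CreatinineTimeline:
    """Timed plasma creatinine values and urine-output episodes for AKI screening.

    Times are hours from admission and must be strictly increasing. If
    ``baseline_creatinine`` is None, the earliest available value is used.
    Urine-output episodes are (duration h, rate mL/kg/h) pairs.
    """

    points: Sequence[tuple[float, float]]
    baseline_creatinine: Optional[float] = None
    urine_output_episodes: Sequence[tuple[float, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("creatinine timeline must be non-empty")
        times = [t for t, _ in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("timeline times must be strictly increasing")
        if any(c <= 0 for _, c in self.points):
            raise ValueError("creatinine values must be > 0")
        if self.baseline_creatinine is not None and self.baseline_creatinine <= 0:
            raise ValueError("baseline creatinine must be > 0")

    @property
    def baseline(self) -> float:
        if self.baseline_creatinine is not None:
            return self.baseline_creatinine
        return self.points[0][1]


def relative_egfr_ckdepi2021(cov: PatientCovariates) -> float:
    """Relative eGFR (mL/min/1.73 m^2) by the race-free CKD-EPI 2021 creatinine equation.

    eGFR = 142 * min(SCr/k, 1)^a * max(SCr/k, 1)^-1.200 * 0.9938^age
    (* 1.012 if female), with k = 0.7 / 0.9 and a = -0.241 / -0.302 for
    female / male, SCr in mg/dL.
    """
    if cov.serum_creatinine <= 0 or cov.age <= 0:
        raise ValueError("serum_creatinine and age must be positive")
    scr_mgdl = cov.serum_creatinine / UMOL_PER_MGDL
    if cov.sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.241, 1.012
    else:
        kappa, alpha, sex_factor = 0.9, -0.302, 1.0
    ratio = scr_mgdl / kappa
    return 142.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.200 * 0.9938 ** cov.age * sex_factor


def bsa_dubois(height: float, weight: float) -> float:
    """Du Bois body surface area (m^2): 0.007184 * height^0.725 * weight^0.425."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be strictly positive")
    return 0.007184 * height**0.725 * weight**0.425


def absolute_egfr(relative_egfr: float, bsa: float) -> float:
    """De-index a relative eGFR to mL/min: relative_egfr * bsa / 1.73."""
    if relative_egfr <= 0 or bsa <= 0:
        raise ValueError("relative_egfr and bsa must be strictly positive")
    return relative_egfr * bsa / 1.73


def crcl_cockcroft_gault(cov: PatientCovariates) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min), absolute, actual body weight.

    CrCL = (140 - age) * weight / (72 * SCr[mg/dL]), * 0.85 if female.
    Not BSA-normalized.
    """
    if cov.serum_creatinine <= 0:
        raise ValueError("serum_creatinine must be positive")
    if cov.age >= 140:
        raise ValueError("Cockcroft-Gault is undefined for age >= 140")
    scr_mgdl = cov.serum_creatinine / UMOL_PER_MGDL
    crcl = (140.0 - cov.age) * cov.weight / (72.0 * scr_mgdl)
    if cov.sex == "female":
        crcl *= 0.85
    return crcl


#: Default ARC-score point allocations: (criterion, points).
#: Age <= 50 years scores 6, trauma admission 3, SOFA <= 4 scores 1 (max 10).
DEFAULT_ARC_SCORE_TABLE = {
    "age_le_50": 6,
    "trauma": 3,
    "sofa_le_4": 1,
}


def arc_score(cov: PatientCovariates, table: Optional[dict[str, int]] = None) -> int:
    """ARC risk score (points) from age, trauma history and SOFA.

    The default table allocates 6 points for age <= 50 years, 3 for trauma
    admission and 1 for SOFA <= 4; a score > 6 flags high ARC risk.
    """
    t = DEFAULT_ARC_SCORE_TABLE if table is None else table
    score = 0
    if cov.age <= 50:
        score += t["age_le_50"]
    if cov.trauma_admission:
        score += t["trauma"]
    if cov.sofa <= 4:
        score += t["sofa_le_4"]
    return score


def classify_arc(crcl: float, score: int) -> tuple[bool, bool]:
    """(arc, suspected_arc) from estimated CrCL (mL/min) and ARC score.

    arc: CrCL > 130 mL/min. suspected_arc: CrCL > 130, or CrCL > 90 mL/min
    together with an elevated ARC score (> 6 points).
    """
    if crcl < 0:
        raise ValueError("crcl must be >= 0")
    arc = crcl > 130.0
    suspected = arc or (crcl > 90.0 and score > 6)
    return arc, suspected


def kdigo_aki(tl: CreatinineTimeline, weight: float) -> tuple[bool, list[str]]:
    """Screen a creatinine/urine-output timeline against KDIGO AKI criteria.

    Criteria: creatinine rise >= 26.5 µmol/L within 48 h; rise to >= 1.5x
    baseline within 7 days of the baseline; urine output <= 0.5 mL/kg/h
    sustained >= 6 h. Returns (aki, list of criteria that fired), criteria
    labelled ``"delta_48h"``, ``"ratio_7d"``, ``"oliguria"``.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    fired: list[str] = []

    pts = list(tl.points)
    # any pair within 48 h with rise >= 26.5 µmol/L
    if any(
        c2 - c1 >= 26.5
        for i, (t1, c1) in enumerate(pts)
        for (t2, c2) in pts[i + 1 :]
        if t2 - t1 <= 48.0
    ):
        fired.append("delta_48h")

    baseline = tl.baseline
    baseline_time = tl.points[0][0] if tl.baseline_creatinine is None else 0.0
    if any(c >= 1.5 * baseline for t, c in pts if 0.0 <= t - baseline_time <= 168.0):
        fired.append("ratio_7d")

    if any(rate <= 0.5 and dur >= 6.0 for dur, rate in tl.urine_output_episodes):
        fired.append("oliguria")

    return bool(fired), fired


def assess_renal_function(cov: PatientCovariates, arc_table: Optional[dict[str, int]] = None) -> RenalAssessment:
    """Full renal work-up for one patient: eGFR, BSA, CrCL, ARC score and flags."""
    rel = relative_egfr_ckdepi2021(cov)
    bsa = bsa_dubois(cov.height, cov.weight)
    abs_egfr = absolute_egfr(rel, bsa)
    crcl = crcl_cockcroft_gault(cov)
    score = arc_score(cov, arc_table)
    arc, suspected = classify_arc(crcl, score)
    group = "above_90" if rel > 90.0 else "at_or_below_90"
    return RenalAssessment(
        relative_egfr=rel,
        bsa=bsa,
        absolute_egfr=abs_egfr,
        crcl=crcl,
        arc_score=score,
        arc=arc,
        suspected_arc=suspected,
        egfr_group=group,
    )
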