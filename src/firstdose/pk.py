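"""Two-compartment infusion pharmacokinetics and population PK models.

Dosing regimens are piecewise constant-rate infusions into the central
compartment. Linear kinetics make the concentration–time profile the
superposition of per-event closed-form biexponential solutions, which is
exact and fast; there is no numerical integration on the evaluation path.

Parameterization: clearance CL (L/h), central volume V1 (L),
inter-compartmental clearance Q (L/h), peripheral volume V2 (L), with
micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2. Q = 0 degenerates
exactly to one-compartment kinetics. Concentrations are TOTAL plasma
concentrations (central amount / V1) in mg/L; unbound conversion is the
exposure layer's concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import yaml

from .renal import PatientCovariates

__all__ = [
    "InfusionEvent",
    "DosingRegimen",
    "StructuralParameters",
    "CovariateEffect",
    "PopulationModel",
    "PKProfile",
    "individual_parameters",
    "concentration_at",
    "simulate_profile",
    "residual_sd",
    "load_population_model",
    "default_model_path",
]


@dataclass(frozen=True)
class InfusionEvent:
    """A constant-rate infusion: start (h), duration (h, > 0), amount (mg, > 0)."""

    start: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("infusion start must be >= 0")
        if self.duration <= 0:
            raise ValueError("infusion duration must be > 0")
        if self.amount <= 0:
            raise ValueError("infusion amount must be > 0")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DosingRegimen:
    """Loading dose plus maintenance extended infusions every tau hours.

    The loading infusion runs over [0, loading.duration]; the first
    maintenance infusion starts exactly when the loading infusion ends,
    and the maintenance clock is anchored there: maintenance infusions
    start at loading.duration + k*tau for k = 0, 1, ... within `horizon`.
    The "first dosing interval" is [0, loading.duration + tau].
    """

    drug: Literal["meropenem", "piperacillin"]
    loading: InfusionEvent
    maintenance_amount: float
    tau: float
    maintenance_duration: float = 3.0
    horizon: float = 24.0

    def __post_init__(self) -> None:
        if self.maintenance_amount <= 0:
            raise ValueError("maintenance_amount must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.maintenance_duration <= 0 or self.maintenance_duration > self.tau:
            raise ValueError("maintenance_duration must be in (0, tau]")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")

    @property
    def first_interval_end(self) -> float:
        """End of the first dosing interval: loading duration + tau."""
        return self.loading.duration + self.tau

    def events(self, until: Optional[float] = None) -> list[InfusionEvent]:
        """All infusion events with start < `until` (default: horizon)."""
        t_max = self.horizon if until is None else until
        evs = []
        if self.loading.start < t_max:
            evs.append(self.loading)
        t = self.loading.duration
        while t < t_max:
            evs.append(InfusionEvent(start=t, duration=self.maintenance_duration, amount=self.maintenance_amount))
            t += self.tau
        return evs


@dataclass(frozen=True)
class StructuralParameters:
    """Individual structural PK parameters (CL, V1 in L/h, L; Q, V2 may be 0)."""

    CL: float
    V1: float
    Q: float = 0.0
    V2: float = 0.0

    def __post_init__(self) -> None:
        if self.CL <= 0 or self.V1 <= 0:
            raise ValueError("CL and V1 must be > 0")
        if self.Q < 0 or self.V2 < 0:
            raise ValueError("Q and V2 must be >= 0")
        if (self.Q > 0) != (self.V2 > 0):
            raise ValueError("Q and V2 must be both zero or both positive")

    @property
    def k10(self) -> float:
        return self.CL / self.V1

    @property
    def k12(self) -> float:
        return self.Q / self.V1

    @property
    def k21(self) -> float:
        return self.Q / self.V2 if self.V2 > 0 else 0.0

    def hybrid_rate_constants(self) -> tuple[float, float]:
        """(alpha, beta): the fast and slow disposition rate constants.

        Roots of lambda^2 - (k10+k12+k21) lambda + k10*k21 = 0; for Q = 0
        this returns (k10, 0.0).
        """
        if self.Q == 0.0:
            return self.k10, 0.0
        s = self.k10 + self.k12 + self.k21
        p = self.k10 * self.k21
        disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
        alpha = 0.5 * (s + disc)
        beta = p / alpha  # numerically stable product form
        return alpha, beta


PARAM_NAMES = ("CL", "V1", "Q", "V2")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate effect on a structural parameter.

    power: multiplier = (x / reference) ** coefficient
    proportional: multiplier = 1 + coefficient * (x - reference)
    `covariate` is a PatientCovariates field name or ``"crcl"``.
    """

    parameter: str
    covariate: str
    form: Literal["power", "proportional"]
    coefficient: float
    reference: float

    def multiplier(self, value: float) -> float:
        if self.form == "power":
            if value <= 0:
                raise ValueError(f"covariate {self.covariate} must be > 0 for a power effect")
            return (value / self.reference) ** self.coefficient
        return 1.0 + self.coefficient * (value - self.reference)


@dataclass(frozen=True)
class PopulationModel:
    """Population PK model: typical values, covariate effects, IIV, residual error.

    Between-subject variability is log-normal: parameter_i = typical_i *
    covariate_multiplier_i * exp(eta_i), eta ~ N(0, diag(omega^2)). The
    residual error SD is combined: g(f) = a + b*f (mg/L).
    """

    drug: str
    typical: StructuralParameters
    omega: dict[str, float] = field(default_factory=dict)  # per-parameter log-normal SD
    covariate_effects: tuple[CovariateEffect, ...] = ()
    error_additive_a: float = 0.0
    error_proportional_b: float = 0.0

    def __post_init__(self) -> None:
        for name, sd in self.omega.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown omega parameter {name!r}")
            if sd < 0:
                raise ValueError("omega SDs must be >= 0")
        if self.error_additive_a < 0 or self.error_proportional_b < 0:
            raise ValueError("error coefficients must be >= 0")
        if self.error_additive_a == 0 and self.error_proportional_b == 0:
            raise ValueError("at least one residual-error coefficient must be > 0")
        for eff in self.covariate_effects:
            if eff.parameter not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {eff.parameter!r} in covariate effect")

    @property
    def eta_names(self) -> tuple[str, ...]:
        """Parameters carrying between-subject variability, in canonical order."""
        return tuple(p for p in PARAM_NAMES if self.omega.get(p, 0.0) > 0)

    @property
    def omega_vector(self) -> np.ndarray:
        return np.array([self.omega[p] for p in self.eta_names], dtype=float)


def _covariate_value(name: str, cov: Optional[PatientCovariates], crcl: Optional[float]) -> float:
    if name == "crcl":
        if crcl is None:
            raise ValueError("model requires covariate 'crcl' but none was supplied")
        return crcl
    if cov is None or not hasattr(cov, name):
        raise ValueError(f"model requires covariate {name!r} but none was supplied")
    return float(getattr(cov, name))


def individual_parameters(
    pop: PopulationModel,
    cov: Optional[PatientCovariates] = None,
    crcl: Optional[float] = None,
    eta: Optional[Sequence[float]] = None,
) -> StructuralParameters:
    """Individual parameters: typical * covariate multipliers * exp(eta).

    `eta` is ordered as `pop.eta_names`; omitted or empty means eta = 0.
    """
    names = pop.eta_names
    if eta is None:
        eta = np.zeros(len(names))
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(names),):
        raise ValueError(f"eta must have length {len(names)} (order {names}), got shape {eta.shape}")

    values = {p: getattr(pop.typical, p) for p in PARAM_NAMES}
    for eff in pop.covariate_effects:
        x = _covariate_value(eff.covariate, cov, crcl)
        values[eff.parameter] *= eff.multiplier(x)
    for name, e in zip(names, eta):
        values[name] *= math.exp(e)
    return StructuralParameters(**values)


def _unit_bolus_coefficients(p: StructuralParameters) -> tuple[float, float, float, float]:
    """(A, alpha, B, beta) of the unit-bolus response C(t) = A e^-at + B e^-bt."""
    alpha, beta = p.hybrid_rate_constants()
    if p.Q == 0.0:
        return 1.0 / p.V1, alpha, 0.0, 0.0
    denom = p.V1 * (alpha - beta)
    if denom == 0.0:  # degenerate repeated root; nudge apart (measure-zero case)
        alpha *= 1.0 + 1e-9
        beta *= 1.0 - 1e-9
        denom = p.V1 * (alpha - beta)
    A = (alpha - p.k21) / denom
    B = (p.k21 - beta) / denom
    return A, alpha, B, beta


def concentration_at(
    p: StructuralParameters,
    r: DosingRegimen,
    t: Union[float, Sequence[float], np.ndarray],
) -> Union[float, np.ndarray]:
    """Total plasma concentration (mg/L) at time(s) t (hours from loading start).

    Exact closed-form superposition over all infusion events of the
    constant-rate-infusion solution of the two-compartment model. Accepts a
    scalar or an array of times; vectorized over times.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise ValueError("times must be >= 0")

    A, alpha, B, beta = _unit_bolus_coefficients(p)
    conc = np.zeros_like(t_arr)
    t_max = float(t_arr.max()) if t_arr.size else 0.0
    for ev in r.events(until=t_max + 1e-12):
        s = np.clip(t_arr - ev.start, 0.0, ev.duration)  # infused time so far
        w = np.maximum(t_arr - ev.start - ev.duration, 0.0)  # washout time since end
        active = t_arr > ev.start
        # R * [A/alpha (1-e^-alpha s) e^-alpha w + B/beta (1-e^-beta s) e^-beta w]
        term = A / alpha * (1.0 - np.exp(-alpha * s)) * np.exp(-alpha * w)
        if B != 0.0:
            if beta > 0:
                term = term + B / beta * (1.0 - np.exp(-beta * s)) * np.exp(-beta * w)
            else:  # beta == 0: limit of (1-e^-bs)/b is s
                term = term + B * s
        conc += np.where(active, ev.rate * term, 0.0)
    return float(conc[0]) if scalar else conc


@dataclass(frozen=True)
class PKProfile:
    """A concentration–time profile on a fixed grid (hours, mg/L)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal shape")
        if np.any(self.concentrations < -1e-12):
            raise ValueError("concentrations must be >= 0")


def simulate_profile(p: StructuralParameters, r: DosingRegimen, grid_step: float = 0.05) -> PKProfile:
    """Dense profile over [0, horizon]; the grid contains every infusion knot exactly."""
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    base = np.arange(0.0, r.horizon + grid_step / 2, grid_step)
    knots = []
    for ev in r.events():
        knots.extend([ev.start, min(ev.end, r.horizon)])
    times = np.unique(np.concatenate([base, np.asarray(knots), [r.horizon]]))
    times = times[times <= r.horizon + 1e-12]
    return PKProfile(times=times, concentrations=np.asarray(concentration_at(p, r, times)))


def residual_sd(pred: Union[float, np.ndarray], pop: PopulationModel):
    """Combined residual error SD: g = a + b * prediction (mg/L)."""
    pred_arr = np.asarray(pred, dtype=float)
    if np.any(pred_arr < 0):
        raise ValueError("prediction must be >= 0")
    g = pop.error_additive_a + pop.error_proportional_b * pred_arr
    return float(g) if np.ndim(pred) == 0 else g


# ---------------------------------------------------------------------------
# Model configuration files


def default_model_path(drug: str) -> Path:
    """Path to the packaged YAML configuration for `drug`."""
    path = Path(__file__).parent / "models" / f"{drug}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"no packaged model for drug {drug!r}")
    return path


def load_population_model(source: Union[str, Path]) -> PopulationModel:
    """Load a PopulationModel from a YAML configuration file.

    Expected keys: drug; typical {CL, V1, Q, V2}; omega {param: sd};
    covariate_effects: list of {parameter, covariate, form, coefficient,
    reference}; error {additive_a, proportional_b}.
    """
    raw = yaml.safe_load(Path(source).read_text())
    effects = tuple(
        CovariateEffect(
            parameter=e["parameter"],
            covariate=e["covariate"],
            form=e["form"],
            coefficient=float(e["coefficient"]),
            reference=float(e["reference"]),
        )
        for e in raw.get("covariate_effects", []) or []
    )
    return PopulationModel(
        drug=raw["drug"],
        typical=StructuralParameters(**{k: float(v) for k, v in raw["typical"].items()}),
        omega={k: float(v) for k, v in (raw.get("omega") or {}).items()},
        covariate_effects=effects,
        error_additive_a=float(raw.get("error", {}).get("additive_a", 0.0)),
        error_proportional_b=float(raw.get("error", {}).get("proportional_b", 0.0)),
    )
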