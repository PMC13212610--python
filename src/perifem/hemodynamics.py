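"""Reduced-order hemodynamics of a stenosed femoropopliteal segment.

The axial pressure profile is built from two contributions:

* a distributed viscous (Poiseuille) gradient ``dp/dx = 8 mu Q / (pi r(x)^4)``
  integrated trapezoidally along the sampled centerline, and
* a localized post-stenotic expansion loss per lesion, an empirical
  Young-Tsai-type turbulent term
  ``dp = Kt * (rho/2) * (A_ref/A_min - 1)^2 * V_ref |V_ref|``
  applied as a pressure step at the lesion exit.

Blood is Newtonian with a hematocrit-dependent viscosity
``mu = 1.2 * (1 + 2.5 eta + 6.2 eta^2)`` mPa*s (1.2 mPa*s plasma baseline).

Boundary conditions follow two strategies: a population-average resting
inflow of 1.26 mL/s (CFDm) or an individualized DUS-derived inflow (CFDi).
Hyperemia is modelled by dividing the calibrated peripheral resistance by 3
and solving for the flow at which the vessel drop plus the peripheral drop
balances the (unchanged) inlet pressure.

Unit conventions: lengths mm, radii mm, flow mL/s, viscosity mPa*s,
density g/cm^3, pressures mmHg.  With mm / (mL/s) / mPa*s the Poiseuille
gradient conveniently evaluates to Pa per mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import LesionAnnotation, RadiusProfile

__all__ = [
    "MMHG_PA",
    "POPULATION_FLOW_ML_S",
    "DEFAULT_KT",
    "Strategy",
    "Condition",
    "BloodModel",
    "BoundaryCondition",
    "SimulationResult",
    "viscosity_from_hematocrit",
    "viscous_pressure_drop",
    "lesion_expansion_loss",
    "pressure_profile",
    "total_pressure_drop",
    "solve_resting",
    "calibrate_peripheral_resistance",
    "solve_hyperemia",
]

MMHG_PA = 133.322  # Pa per mmHg
POPULATION_FLOW_ML_S = 1.26  # population-average resting flow (CFDm strategy)
DEFAULT_KT = 1.52  # empirical expansion-loss coefficient
DEFAULT_DENSITY = 1.06  # g/cm^3


class Strategy(str, Enum):
    """Inflow boundary-condition strategy."""

    CFDM = "CFDm"  # population-average resting inflow
    CFDI = "CFDi"  # individualized DUS-derived inflow


class Condition(str, Enum):
    REST = "rest"
    HYPEREMIA = "hyperemia"


def viscosity_from_hematocrit(hematocrit: float) -> float:
    """Blood viscosity in mPa*s from the hematocrit fraction.

    Quadratic suspension model ``1.2 * (1 + 2.5 eta + 6.2 eta^2)`` with a
    1.2 mPa*s plasma baseline; valid for eta in [0, 0.7].
    """
    if not 0.0 <= hematocrit <= 0.7:
        raise ValueError("hematocrit fraction must lie in [0, 0.7]")
    eta = hematocrit
    return 1.2 * (1.0 + 2.5 * eta + 6.2 * eta**2)


@dataclass(frozen=True)
class BloodModel:
    """Newtonian blood with hematocrit-derived constant viscosity."""

    hematocrit: float = 0.42
    density: float = DEFAULT_DENSITY  # g/cm^3
    viscosity: float = field(init=False)  # mPa*s

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        object.__setattr__(self, "viscosity", viscosity_from_hematocrit(self.hematocrit))


@dataclass(frozen=True)
class BoundaryCondition:
    strategy: Strategy
    inflow_rate: float  # mL/s
    inlet_pressure: float  # mmHg
    venous_pressure: float = 0.0  # mmHg
    peripheral_resistance: float | None = None  # mmHg*s/mL, calibrated at rest
    hyperemia_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.inflow_rate <= 0:
            raise ValueError("inflow rate must be positive")
        if self.inlet_pressure <= self.venous_pressure:
            raise ValueError("inlet pressure must exceed venous pressure")
        if self.hyperemia_factor < 1:
            raise ValueError("hyperemia factor must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Axial pressure solution for one vessel under one flow condition."""

    axial_position: np.ndarray  # mm
    pressure: np.ndarray  # mmHg
    distal_pressure: float  # mmHg
    gradient: float  # mmHg, inlet minus distal
    flow_rate: float  # mL/s
    condition: Condition
    strategy: Strategy | None = None
    warning: str | None = None  # set when the solution is non-physical

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure, dtype=float)
        x = np.asarray(self.axial_position, dtype=float)
        if x.shape != p.shape:
            raise ValueError("axial_position and pressure must have equal length")
        if abs(self.gradient - (p[0] - p[-1])) > 1e-9:
            raise ValueError("gradient must equal inlet minus distal pressure")
        object.__setattr__(self, "axial_position", x)
        object.__setattr__(self, "pressure", p)


def _poiseuille_gradient_pa_per_mm(radius_mm: np.ndarray, q_ml_s: float, mu_mpa_s: float) -> np.ndarray:
    # 8 mu Q / (pi r^4) with mu in mPa*s, Q in mL/s, r in mm gives Pa/mm
    return 8.0 * mu_mpa_s * q_ml_s / (np.pi * radius_mm**4)


def viscous_pressure_drop(profile: RadiusProfile, q: float, blood: BloodModel) -> float:
    """Distributed viscous drop over the whole profile, in mmHg."""
    if q < 0:
        raise ValueError("flow rate must be non-negative")
    grad = _poiseuille_gradient_pa_per_mm(profile.lumen_radius, q, blood.viscosity)
    return float(np.trapezoid(grad, profile.axial_position) / MMHG_PA)


def lesion_expansion_loss(
    lesion: LesionAnnotation, q: float, blood: BloodModel, kt: float = DEFAULT_KT
) -> float:
    """Post-stenotic expansion (separation) loss across one lesion, in mmHg.

    ``Kt * (rho/2) * (A_ref/A_min - 1)^2 * V_ref * |V_ref|`` with the
    reference velocity ``V_ref = Q / A_ref``.
    """
    if q < 0:
        raise ValueError("flow rate must be non-negative")
    if kt <= 0:
        raise ValueError("Kt must be positive")
    a_ref_cm2 = np.pi * (lesion.reference_radius / 10.0) ** 2
    a_min_cm2 = np.pi * (lesion.minimal_radius / 10.0) ** 2
    v_ref_m_s = q / a_ref_cm2 * 1e-2  # (mL/s)/cm^2 = cm/s -> m/s
    rho_kg_m3 = blood.density * 1000.0
    dp_pa = kt * 0.5 * rho_kg_m3 * (a_ref_cm2 / a_min_cm2 - 1.0) ** 2 * v_ref_m_s * abs(v_ref_m_s)
    return float(dp_pa / MMHG_PA)


def pressure_profile(
    profile: RadiusProfile,
    lesions: Sequence[LesionAnnotation],
    q: float,
    blood: BloodModel,
    inlet_pressure: float,
    kt: float = DEFAULT_KT,
    venous_floor: float = 0.0,
    condition: Condition = Condition.REST,
    strategy: Strategy | None = None,
) -> SimulationResult:
    """Axial pressure solution at steady flow ``q`` (mL/s).

    The distributed viscous gradient is accumulated trapezoidally along the
    sampled axis; each lesion's expansion loss is applied as a step at the
    lesion end (the post-stenotic expansion site).  A result whose distal
    pressure falls to or below the venous floor is returned with a warning
    status rather than rejected: it flags a flow/geometry combination the
    steady model considers non-physical.
    """
    x = profile.axial_position
    for les in lesions:
        if les.start < x[0] - 1e-9 or les.end > x[-1] + 1e-9:
            raise ValueError("lesion span lies outside the profile's axial extent")
    grad = _poiseuille_gradient_pa_per_mm(profile.lumen_radius, q, blood.viscosity)
    seg = 0.5 * (grad[1:] + grad[:-1]) * np.diff(x) / MMHG_PA
    cumulative = np.concatenate([[0.0], np.cumsum(seg)])
    for les in lesions:
        step = lesion_expansion_loss(les, q, blood, kt)
        cumulative = cumulative + np.where(x >= les.end - 1e-12, step, 0.0)
    pressure = inlet_pressure - cumulative
    distal = float(pressure[-1])
    warning = None
    if q > 0 and distal <= venous_floor:
        warning = (
            f"non-physical: distal pressure {distal:.1f} mmHg at or below the "
            f"venous floor {venous_floor:.1f} mmHg"
        )
    return SimulationResult(
        axial_position=x,
        pressure=pressure,
        distal_pressure=distal,
        gradient=float(pressure[0] - pressure[-1]),
        flow_rate=q,
        condition=condition,
        strategy=strategy,
        warning=warning,
    )


def total_pressure_drop(
    profile: RadiusProfile,
    lesions: Sequence[LesionAnnotation],
    q: float,
    blood: BloodModel,
    kt: float = DEFAULT_KT,
) -> float:
    """Total vessel drop (mmHg) at flow ``q``: viscous integral plus lesion losses."""
    drop = viscous_pressure_drop(profile, q, blood)
    for les in lesions:
        drop += lesion_expansion_loss(les, q, blood, kt)
    return drop


@dataclass(frozen=True)
class VesselCase:
    """Everything needed to simulate one limb.

    ``dus_site_mm`` locates the popliteal DUS sampling site on the profile;
    the cross-sectional area there converts the velocity trace into a flow
    rate under the CFDi strategy.
    """

    case_id: str
    profile: RadiusProfile
    lesions: tuple[LesionAnnotation, ...]
    blood: BloodModel
    inlet_pressure: float  # mmHg
    venous_pressure: float = 0.0
    dus_trace: "object | None" = None  # VelocityTrace, optional
    dus_site_mm: float | None = None
    dus_correction: float = -0.10
    kt: float = DEFAULT_KT


def solve_resting(case: VesselCase, strategy: Strategy | str = Strategy.CFDI) -> SimulationResult:
    """Resting simulation under the chosen inflow strategy.

    CFDm imposes the population-average 1.26 mL/s for every patient; CFDi
    derives the inflow from the case's DUS trace and sampling-site area.
    """
    from .dus import estimate_flow  # local import to avoid a cycle

    strategy = Strategy(strategy)
    if strategy is Strategy.CFDM:
        q = POPULATION_FLOW_ML_S
    else:
        if case.dus_trace is None or case.dus_site_mm is None:
            raise ValueError("CFDi requires a DUS trace and a sampling site on the profile")
        area = case.profile.cross_section_cm2(case.dus_site_mm)
        q = estimate_flow(case.dus_trace, area, correction=case.dus_correction).flow_rate
    return pressure_profile(
        case.profile,
        case.lesions,
        q,
        case.blood,
        case.inlet_pressure,
        kt=case.kt,
        venous_floor=case.venous_pressure,
        condition=Condition.REST,
        strategy=strategy,
    )


def calibrate_peripheral_resistance(
    pd_rest: float, venous_pressure: float, q_rest: float
) -> float:
    """Distal (runoff) resistance that carries the resting flow: (Pd - Pv)/Q."""
    if pd_rest <= venous_pressure:
        raise ValueError("resting distal pressure must exceed venous pressure")
    if q_rest <= 0:
        raise ValueError("resting flow must be positive")
    return (pd_rest - venous_pressure) / q_rest


def solve_hyperemia(
    case: VesselCase,
    resting_result: SimulationResult,
    hyperemia_factor: float = 3.0,
) -> SimulationResult:
    """Hyperemic simulation: peripheral resistance divided by ``hyperemia_factor``.

    The peripheral resistance is calibrated from the resting solution, then
    the hyperemic flow Q* solves

        Pa = vessel_drop(Q*) + (R / f) * Q* + Pv

    Both terms increase monotonically with Q, so the root is unique and is
    bracketed by [Q_rest, f * Q_rest]: with zero vessel resistance flow
    scales exactly by f, and any vessel resistance pulls Q* below that.
    """
    if hyperemia_factor < 1:
        raise ValueError("hyperemia factor must be >= 1")
    q_rest = resting_result.flow_rate
    r_per = calibrate_peripheral_resistance(
        resting_result.distal_pressure, case.venous_pressure, q_rest
    )
    r_hyp = r_per / hyperemia_factor

    def residual(q: float) -> float:
        drop = total_pressure_drop(case.profile, case.lesions, q, case.blood, case.kt)
        return drop + r_hyp * q + case.venous_pressure - case.inlet_pressure

    lo, hi = q_rest, hyperemia_factor * q_rest
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo > 1e-9:
        raise RuntimeError(
            f"hyperemia solver: residual at Q_rest is positive ({f_lo:.3g}); "
            "the resting solution does not balance its own boundary condition"
        )
    if f_hi < -1e-9:
        # zero-vessel-resistance limit: the upper bracket is the exact solution
        q_star = hi
    else:
        q_star = brentq(residual, lo, hi, xtol=1e-9)
    return pressure_profile(
        case.profile,
        case.lesions,
        float(q_star),
        case.blood,
        case.inlet_pressure,
        kt=case.kt,
        venous_floor=case.venous_pressure,
        condition=Condition.HYPEREMIA,
        strategy=resting_result.strategy,
    )
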