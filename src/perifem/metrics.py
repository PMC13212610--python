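"""Clinical pressure endpoints: resting gradient, FFR, per-lesion pullback FFR.

The resting pressure gradient is Pa - Pd without vasodilation; the
peripheral fractional flow reserve (FFR) is Pd/Pa under pharmacologic
vasodilation.  For multi-segmental disease a (virtual) pressure-wire
pullback localizes the pressure jump of each lesion, giving an
individual-lesion FFR of (Pa - dP_lesion)/Pa.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import LesionAnnotation

__all__ = [
    "MeasurementCondition",
    "PressurePair",
    "PullbackTrace",
    "LesionFfr",
    "resting_gradient",
    "ffr",
    "lesion_pressure_jumps",
]


class MeasurementCondition(str, Enum):
    REST = "rest"
    VASODILATION = "vasodilation"


@dataclass(frozen=True)
class PressurePair:
    """A simultaneous proximal/distal mean-pressure measurement (mmHg)."""

    proximal: float
    distal: float
    condition: MeasurementCondition

    def __post_init__(self) -> None:
        if self.proximal <= 0 or self.distal <= 0:
            raise ValueError("pressures must be positive")
        object.__setattr__(self, "condition", MeasurementCondition(self.condition))


@dataclass(frozen=True)
class PullbackTrace:
    """Pressure versus axial position recorded while withdrawing the wire.

    ``direction`` declares how axial_position is ordered: ``"proximal_to_distal"``
    (increasing x) or ``"distal_to_proximal"`` (decreasing x).
    """

    axial_position: np.ndarray  # mm
    pressure: np.ndarray  # mmHg
    condition: MeasurementCondition
    direction: str = "proximal_to_distal"

    def __post_init__(self) -> None:
        x = np.asarray(self.axial_position, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if x.shape != p.shape or x.ndim != 1:
            raise ValueError("axial_position and pressure must be 1-D arrays of equal length")
        if self.direction not in ("proximal_to_distal", "distal_to_proximal"):
            raise ValueError("unknown pullback direction")
        d = np.diff(x)
        if self.direction == "proximal_to_distal" and not np.all(d > 0):
            raise ValueError("positions must increase for a proximal_to_distal trace")
        if self.direction == "distal_to_proximal" and not np.all(d < 0):
            raise ValueError("positions must decrease for a distal_to_proximal trace")
        object.__setattr__(self, "axial_position", x)
        object.__setattr__(self, "pressure", p)
        object.__setattr__(self, "condition", MeasurementCondition(self.condition))

    def oriented(self) -> tuple[np.ndarray, np.ndarray]:
        """Trace samples ordered proximal (small x) to distal (large x)."""
        if self.direction == "distal_to_proximal":
            return self.axial_position[::-1], self.pressure[::-1]
        return self.axial_position, self.pressure


@dataclass(frozen=True)
class LesionFfr:
    lesion_id: int
    delta_p: float  # mmHg, pressure jump across the lesion under vasodilation
    ffr: float


def resting_gradient(pair: PressurePair) -> float:
    """Resting trans-segment gradient Pa - Pd, mmHg."""
    if pair.condition is not MeasurementCondition.REST:
        raise ValueError("resting gradient requires a resting pressure pair")
    return pair.proximal - pair.distal


def ffr(pair: PressurePair) -> float:
    """Peripheral fractional flow reserve Pd/Pa under vasodilation.

    A resting Pd/Pa is a distinct quantity and is deliberately rejected here.
    """
    if pair.condition is not MeasurementCondition.VASODILATION:
        raise ValueError("FFR is defined under vasodilation; got a resting pair")
    return pair.distal / pair.proximal


def lesion_pressure_jumps(
    trace: PullbackTrace,
    lesions: Sequence[LesionAnnotation],
    margin_mm: float = 5.0,
) -> list[LesionFfr]:
    """Attribute pullback pressure jumps to annotated lesions.

    Each lesion's jump is the pressure difference between a point ``margin_mm``
    proximal of its start and ``margin_mm`` distal of its end (clipped to the
    trace; margins of adjacent lesions are shrunk to the midpoint between
    them so no sample is attributed twice).  The individual-lesion FFR is
    ``(Pa - dP) / Pa`` with Pa the most-proximal trace pressure.
    """
    x, p = trace.oriented()
    ordered = sorted(lesions, key=lambda l: l.start)
    for les in ordered:
        if les.start < x[0] - 1e-9 or les.end > x[-1] + 1e-9:
            raise ValueError("lesion span lies outside the pullback extent")
    pa = float(p[0])
    out: list[LesionFfr] = []
    for i, les in enumerate(ordered):
        lo = les.start - margin_mm
        hi = les.end + margin_mm
        if i > 0:
            lo = max(lo, 0.5 * (ordered[i - 1].end + les.start))
        if i + 1 < len(ordered):
            hi = min(hi, 0.5 * (les.end + ordered[i + 1].start))
        lo = float(np.clip(lo, x[0], x[-1]))
        hi = float(np.clip(hi, x[0], x[-1]))
        p_prox = float(np.interp(lo, x, p))
        p_dist = float(np.interp(hi, x, p))
        delta = p_prox - p_dist
        out.append(LesionFfr(lesion_id=i, delta_p=delta, ffr=(pa - delta) / pa))
    return out
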