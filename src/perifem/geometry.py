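"""Axial lumen geometry of a stenosed vessel segment.

A vessel is described by its lumen radius sampled along the centerline,
proximal (x = 0) to distal, in millimetres.  Individual stenotic lesions are
annotated as axial spans with a reference ("healthy") radius and a minimal
radius, from which the conventional diameter-stenosis percentage follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RadiusProfile",
    "LesionAnnotation",
    "percent_stenosis",
    "detect_lesions",
]


@dataclass(frozen=True)
class RadiusProfile:
    """Lumen radius along the vessel centerline.

    Parameters
    ----------
    axial_position
        Axial coordinate in mm, strictly increasing, 0 at the proximal inlet.
    lumen_radius
        Lumen radius in mm at each axial position; strictly positive.
    """

    axial_position: np.ndarray
    lumen_radius: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.axial_position, dtype=float)
        r = np.asarray(self.lumen_radius, dtype=float)
        if x.ndim != 1 or r.ndim != 1 or x.shape != r.shape:
            raise ValueError("axial_position and lumen_radius must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError("a radius profile needs at least 2 samples")
        if not np.all(np.diff(x) > 0):
            raise ValueError("axial positions must be strictly increasing")
        if not np.all(r > 0):
            raise ValueError("all lumen radii must be positive")
        object.__setattr__(self, "axial_position", x)
        object.__setattr__(self, "lumen_radius", r)

    @property
    def length(self) -> float:
        """Axial extent of the profile in mm."""
        return float(self.axial_position[-1] - self.axial_position[0])

    def radius_at(self, x: float) -> float:
        """Linearly interpolated lumen radius (mm) at axial position ``x``."""
        return float(np.interp(x, self.axial_position, self.lumen_radius))

    def cross_section_cm2(self, x: float) -> float:
        """Circular cross-sectional area in cm**2 at axial position ``x``."""
        r_cm = self.radius_at(x) / 10.0
        return float(np.pi * r_cm**2)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"axial_mm": self.axial_position, "radius_mm": self.lumen_radius}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RadiusProfile":
        df = pd.read_csv(path)
        return cls(df["axial_mm"].to_numpy(), df["radius_mm"].to_numpy())


@dataclass(frozen=True)
class LesionAnnotation:
    """One stenotic lesion: an axial span plus its severity description."""

    start: float
    end: float
    reference_radius: float
    minimal_radius: float
    diameter_stenosis: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("lesion start must lie proximal of its end")
        if self.minimal_radius > self.reference_radius:
            raise ValueError("minimal radius cannot exceed the reference radius")
        if self.minimal_radius <= 0:
            raise ValueError("minimal radius must be positive")
        object.__setattr__(
            self,
            "diameter_stenosis",
            percent_stenosis(self.reference_radius, self.minimal_radius),
        )


def percent_stenosis(reference_radius: float, minimal_radius: float) -> float:
    """Diameter stenosis in percent: ``100 * (1 - d_min / d_ref)``.

    The ratio of diameters equals the ratio of radii for a circular lumen,
    so the radii are used directly.
    """
    if minimal_radius <= 0 or reference_radius <= 0:
        raise ValueError("radii must be positive")
    if minimal_radius > reference_radius:
        raise ValueError("minimal radius cannot exceed the reference radius")
    return 100.0 * (1.0 - minimal_radius / reference_radius)


def _runs_below(radius: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal contiguous index runs where radius < threshold, as (i0, i1) inclusive."""
    below = radius < threshold
    runs: list[tuple[int, int]] = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def detect_lesions(profile: RadiusProfile, min_severity: float = 50.0) -> list[LesionAnnotation]:
    """Locate stenotic lesions at least ``min_severity`` percent severe.

    A lesion is a maximal contiguous region whose local diameter falls below
    ``(1 - min_severity/100)`` times the reference diameter.  There is no
    healthy reference segment in diffuse multi-segmental disease, so the
    reference radius is estimated robustly in two passes: first the global
    median radius, then the median recomputed with the candidate lesion spans
    excluded.  Lesions are returned proximal to distal and never overlap.

    Parameters
    ----------
    profile
        The vessel lumen description.
    min_severity
        Detection threshold as diameter-stenosis percent, in (0, 100).
    """
    if not 0 < min_severity < 100:
        raise ValueError("min_severity must lie strictly between 0 and 100 percent")
    x = profile.axial_position
    r = profile.lumen_radius

    # pass 1: candidate spans against the global median
    ref = float(np.median(r))
    runs = _runs_below(r, (1.0 - min_severity / 100.0) * ref)
    if not runs:
        return []

    # pass 2: reference from the non-lesion portion only
    mask = np.ones(r.size, dtype=bool)
    for i0, i1 in runs:
        mask[i0 : i1 + 1] = False
    if mask.any():
        ref = float(np.median(r[mask]))
    runs = _runs_below(r, (1.0 - min_severity / 100.0) * ref)

    lesions: list[LesionAnnotation] = []
    dx = float(np.min(np.diff(x)))
    for i0, i1 in runs:
        start, end = float(x[i0]), float(x[i1])
        if start == end:  # single-sample run: widen by half a grid step each side
            start -= 0.5 * dx
            end += 0.5 * dx
        lesions.append(
            LesionAnnotation(
                start=start,
                end=end,
                reference_radius=ref,
                minimal_radius=float(np.min(r[i0 : i1 + 1])),
            )
        )
    return lesions
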