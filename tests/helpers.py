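"""Shared constructors for synthetic test vessels."""

import numpy as np

from perifem import RadiusProfile


def make_tube(radius_mm=2.0, length_mm=100.0, step_mm=1.0):
    x = np.arange(0.0, length_mm + step_mm / 2, step_mm)
    return RadiusProfile(x, np.full_like(x, radius_mm))


def make_gaussian_narrowing(ref_mm=3.0, min_mm=1.2, center_mm=100.0,
                            sigma_mm=10.0, length_mm=200.0, step_mm=0.5):
    """Tube with a single Gaussian narrowing of known reference/minimal radius."""
    x = np.arange(0.0, length_mm + step_mm / 2, step_mm)
    r = ref_mm - (ref_mm - min_mm) * np.exp(-0.5 * ((x - center_mm) / sigma_mm) ** 2)
    return RadiusProfile(x, r)
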