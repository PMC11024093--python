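"""Micropattern geometry utilities.

For a disc ("O" micropattern) the maximum distance between two points
is the diameter, 2*sqrt(area/pi).  Under isotropic scaling of any fixed
shape, distances grow with the square root of area, so the relative
increase in maximum inter-point distance between two pattern sizes is
(sqrt(A_large/A_small) - 1) * 100 percent regardless of the shape.
"""

from __future__ import annotations

import math

__all__ = ["disc_max_chord", "isotropic_scaling_percent"]


def disc_max_chord(area: float) -> float:
    """Diameter (um) of a disc with the given area (um^2)."""
    if not area > 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area / math.pi)


def isotropic_scaling_percent(area_large: float, area_small: float) -> float:
    """Percent increase in any linear dimension between two isotropic sizes."""
    if not (area_large > 0 and area_small > 0):
        raise ValueError("areas must be positive")
    return (math.sqrt(area_large / area_small) - 1.0) * 100.0
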