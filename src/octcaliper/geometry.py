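"""Parametric full-thickness macular hole (FTMH) geometry and chord-sampling math.

A horizontal OCT b-scan raster samples the hole with parallel slices a fixed
distance apart.  A slice that misses the hole centre sees a *chord* of the
(assumed circular) aperture rather than its true diameter, so discrete
sampling can only under-measure a horizontal diameter.  This module provides
the hole's ground-truth description and the closed-form worst-case apparent
size as a function of true diameter and b-scan spacing.

All lengths are µm, double precision; no unit conversion anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MacularHoleModel",
    "chord_width",
    "min_apparent_size",
    "relative_undermeasurement",
]


@dataclass(frozen=True)
class MacularHoleModel:
    """Ground-truth 3-D geometry of one full-thickness macular hole.

    The minimum linear diameter (MLD) and basal diameter (BD) apertures are
    modelled as concentric circles in their respective horizontal planes;
    irregular hole shapes are out of scope.

    Parameters
    ----------
    d_mld : float
        True minimum linear diameter, µm. The narrowest horizontal extent of
        the hole; the key surgical prognostic metric.
    d_bd : float
        True basal diameter at the retinal pigment epithelium (RPE), µm.
        Must satisfy ``d_mld <= d_bd`` (the MLD aperture nests inside the
        basal aperture).
    h_nasal, h_temporal : float
        Hole height on the nasal / temporal side: distance from the RPE to
        the vitreoretinal interface at the hole rim, µm. Strictly positive.
    center_y : float
        Lateral offset of the hole centre from the raster origin along the
        slow-scan axis, µm.  Positive superior; origin at raster centre.
    """

    d_mld: float
    d_bd: float
    h_nasal: float
    h_temporal: float
    center_y: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_mld <= self.d_bd):
            raise ValueError(
                f"require 0 < d_mld <= d_bd, got d_mld={self.d_mld}, d_bd={self.d_bd}"
            )
        if self.h_nasal <= 0.0 or self.h_temporal <= 0.0:
            raise ValueError("hole heights must be strictly positive")


def chord_width(diameter: float, offset: float) -> float:
    """Chord of a circular aperture cut by a slice at a given offset.

    Parameters
    ----------
    diameter : float
        Aperture diameter, µm.  Must be > 0.
    offset : float
        Perpendicular distance of the slice from the aperture centre, µm.
        May be signed; only its magnitude matters.

    Returns
    -------
    float
        ``2 * sqrt((diameter/2)**2 - offset**2)`` when ``|offset| < diameter/2``,
        else 0.0 (the slice misses the aperture).  Always ``<= diameter``.
    """
    if diameter <= 0.0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    half = diameter / 2.0
    off = abs(offset)
    if off >= half:
        return 0.0
    return 2.0 * math.sqrt(half * half - off * off)


def min_apparent_size(true_diameter: float, scan_spacing: float) -> float:
    """Worst-case apparent diameter under a raster of given b-scan spacing.

    The raster phase (position of the grid relative to the hole centre) is a
    nuisance parameter.  For each phase, an observer reads the widest chord
    over slices; the worst phase places the two nearest slices symmetrically
    at ±s/2 from the centre, where the widest chord is the chord at offset
    s/2 of a circle of diameter D:

        2 * sqrt((D/2)**2 - (s/2)**2) = sqrt(D**2 - s**2)

    Hence min-over-phase of max-over-slices chord = sqrt(D^2 - s^2).

    Returns 0.0 when ``scan_spacing >= true_diameter``: a raster phase then
    exists for which no slice intersects the aperture at all (the hole is
    missed entirely); kept total rather than raising.
    """
    if true_diameter <= 0.0:
        raise ValueError(f"true_diameter must be > 0, got {true_diameter}")
    if scan_spacing < 0.0:
        raise ValueError(f"scan_spacing must be >= 0, got {scan_spacing}")
    if scan_spacing >= true_diameter:
        return 0.0
    return math.sqrt(true_diameter * true_diameter - scan_spacing * scan_spacing)


def relative_undermeasurement(true_diameter: float, scan_spacing: float) -> float:
    """Worst-case fractional shortfall (D - min_apparent_size) / D.

    Strictly decreasing in ``true_diameter`` for fixed spacing > 0: smaller
    holes are proportionally the most under-measured by a sparse raster.
    Equals 1.0 when the spacing reaches the diameter (hole missed).
    """
    return (true_diameter - min_apparent_size(true_diameter, scan_spacing)) / true_diameter
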