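"""Discrete b-scan acquisition of a macular hole under a scan protocol.

Simulates what a horizontal macular-volume raster actually records: for each
b-scan slice, the apparent (chord) MLD and basal diameter at that slice's
offset from the hole centre.  The raster phase — where the grid falls
relative to the fovea — is the nuisance parameter that produces the
scan-density under-measurement phenomenon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .geometry import MacularHoleModel, chord_width

__all__ = [
    "ScanProtocol",
    "SliceProfile",
    "SPECTRALIS_LIKE",
    "TRITON_LIKE",
    "PROTOCOL_PRESETS",
    "acquire",
    "widest_slice",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanProtocol:
    """One OCT machine's acquisition and display parameters.

    Parameters
    ----------
    name : str
        Label used in measurement records (e.g. ``"spectralis-like"``).
    bscan_spacing : float
        Distance between consecutive horizontal b-scans, µm.
    n_bscans : int
        Number of b-scans in the macular volume.
    lateral_resolution : float
        In-plane resolving power, µm/pixel; drives observer endpoint jitter.
    axial_resolution : float
        Depth resolving power, µm/pixel (carried for completeness).
    default_vscale : float
        Vertical:horizontal display aspect ratio of the machine's default
        viewing platform (>= 1). Values > 1 vertically magnify the image and
        enable accidentally oblique "vertical" calliper placements.
    """

    name: str
    bscan_spacing: float
    n_bscans: int
    lateral_resolution: float
    axial_resolution: float
    default_vscale: float

    def __post_init__(self) -> None:
        if self.bscan_spacing <= 0.0:
            raise ValueError("bscan_spacing must be > 0")
        if self.n_bscans < 1:
            raise ValueError("n_bscans must be >= 1")
        if self.lateral_resolution <= 0.0 or self.axial_resolution <= 0.0:
            raise ValueError("resolutions must be > 0")
        if self.default_vscale < 1.0:
            raise ValueError("default_vscale must be >= 1")

    @property
    def field_span(self) -> float:
        """Slow-axis extent covered by the raster, µm."""
        return (self.n_bscans - 1) * self.bscan_spacing


# Presets for the two machine configurations the simulator emulates:
# a dense high-lateral-resolution volume displayed at 1:3.775, and a
# 50 µm-spacing volume at 20 µm lateral resolution displayed at 1:2.
SPECTRALIS_LIKE = ScanProtocol(
    name="spectralis-like",
    bscan_spacing=125.0,
    n_bscans=49,
    lateral_resolution=5.7,
    axial_resolution=3.9,
    default_vscale=3.775,
)
TRITON_LIKE = ScanProtocol(
    name="triton-like",
    bscan_spacing=50.0,
    n_bscans=149,
    lateral_resolution=20.0,
    axial_resolution=8.0,
    default_vscale=2.0,
)
PROTOCOL_PRESETS = {p.name: p for p in (SPECTRALIS_LIKE, TRITON_LIKE)}


@dataclass(frozen=True)
class SliceProfile:
    """Apparent hole dimensions on one acquired b-scan.

    ``offset`` is the signed distance of the slice from the hole centre
    along the slow axis, µm.  ``apparent_mld``/``apparent_bd`` are the
    chords of the MLD and basal apertures at that offset (0 if missed).
    """

    slice_index: int
    offset: float
    apparent_mld: float
    apparent_bd: float


def acquire(
    hole: MacularHoleModel, protocol: ScanProtocol, phase: float
) -> list[SliceProfile]:
    """Acquire a raster of b-scans over the hole at a given raster phase.

    Slice positions on the slow axis are ``-span/2 + phase + j*spacing`` for
    ``j = 0..n_bscans-1`` (the raster is centred on the origin, then shifted
    by ``phase``).  Offsets are computed relative to the hole centre
    (``hole.center_y``); apparent diameters are chords of the circular
    apertures at each offset.

    Parameters
    ----------
    phase : float
        Raster phase in ``[0, bscan_spacing)``.

    Returns
    -------
    list of SliceProfile, ordered by slice_index.
    """
    if not (0.0 <= phase < protocol.bscan_spacing):
        raise ValueError(
            f"phase must lie in [0, {protocol.bscan_spacing}), got {phase}"
        )
    half_span = protocol.field_span / 2.0
    hole_extent = abs(hole.center_y) + hole.d_bd / 2.0
    if hole_extent > half_span + protocol.bscan_spacing:
        logger.warning(
            "raster field (span %.0f um) does not cover the hole "
            "(extent %.0f um from origin); apparent sizes will be truncated",
            protocol.field_span,
            hole_extent,
        )
    slices = []
    base = -half_span + phase
    for j in range(protocol.n_bscans):
        pos = base + j * protocol.bscan_spacing
        off = pos - hole.center_y
        slices.append(
            SliceProfile(
                slice_index=j,
                offset=off,
                apparent_mld=chord_width(hole.d_mld, off),
                apparent_bd=chord_width(hole.d_bd, off),
            )
        )
    return slices


def widest_slice(slices: Sequence[SliceProfile]) -> SliceProfile:
    """The slice an ideal grader would measure: maximal apparent MLD.

    Ties are broken by smaller ``|offset|``, then by lower ``slice_index``,
    so the choice is deterministic.
    """
    if not slices:
        raise ValueError("widest_slice requires a non-empty slice list")
    best = slices[0]
    for s in slices[1:]:
        if s.apparent_mld > best.apparent_mld:
            best = s
        elif s.apparent_mld == best.apparent_mld:
            if abs(s.offset) < abs(best.offset) or (
                abs(s.offset) == abs(best.offset) and s.slice_index < best.slice_index
            ):
                best = s
    return best
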