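"""Human grader behaviour: calliper placement error mechanisms.

Three mechanisms are modelled, each with its own knob:

* **Endpoint jitter** — at low lateral resolution the hole borders are
  ambiguous, so each calliper endpoint lands with a Gaussian error whose SD
  scales with the machine's lateral resolution.
* **Systematic reference-point bias** — a grader may consistently choose a
  different landmark on low-resolution scans; modelled as a signed offset
  proportional to lateral resolution, so it vanishes on high-resolution
  machines.
* **Oblique height measurement** — the default viewing platform displays
  the image vertically magnified (vscale > 1).  A calliper that looks
  vertical on screen within a small angular tolerance is actually tilted in
  true µm space, so the measured height sqrt(dx^2 + h^2) can only exceed
  the true height, and more so at larger vscale.

Slice mis-selection (picking a neighbour of the widest slice) is also
available, off by default.

All stochastic operations take a ``numpy.random.Generator`` and are
bit-reproducible given its state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .raster import ScanProtocol, SliceProfile, widest_slice

__all__ = [
    "ObserverModel",
    "DEFAULT_OBSERVERS",
    "measure_horizontal",
    "measure_height_scaled",
    "select_slice",
]


@dataclass(frozen=True)
class ObserverModel:
    """Behavioural error parameters of one grader.

    Parameters
    ----------
    observer_id : str
        Label used in measurement records.
    jitter_coeff : float
        Dimensionless multiplier mapping lateral resolution to the SD of
        each endpoint's localisation error (two independent endpoints per
        calliper).  Default 0.5.
    bias_coeff : float
        Signed dimensionless multiplier mapping lateral resolution to a
        systematic per-measurement offset.  Default 0 (no bias).
    slice_error_prob : float
        Probability of selecting a neighbour of the widest slice instead of
        the widest slice itself.  Default 0: slice mis-selection is an
        opt-in mechanism so that the default configuration isolates the
        resolution- and scaling-driven effects.
    oblique_tol_deg : float
        Maximum apparent deviation from vertical, in *display* coordinates,
        tolerated when drawing a height calliper, degrees.  Default 3.
    """

    observer_id: str
    jitter_coeff: float = 0.5
    bias_coeff: float = 0.0
    slice_error_prob: float = 0.0
    oblique_tol_deg: float = 3.0

    def __post_init__(self) -> None:
        if self.jitter_coeff < 0.0:
            raise ValueError("jitter_coeff must be >= 0")
        if not (0.0 <= self.slice_error_prob <= 1.0):
            raise ValueError("slice_error_prob must be in [0, 1]")
        if not (0.0 <= self.oblique_tol_deg < 90.0):
            raise ValueError("oblique_tol_deg must be in [0, 90)")


# Default grader pair: observer1 carries a negative reference-point bias
# that only materialises on low-resolution scans; observer2 is unbiased.
DEFAULT_OBSERVERS = (
    ObserverModel(observer_id="observer1", bias_coeff=-0.75),
    ObserverModel(observer_id="observer2", bias_coeff=0.0),
)


def measure_horizontal(
    true_width: float,
    protocol: ScanProtocol,
    obs: ObserverModel,
    rng: np.random.Generator,
) -> float:
    """One manual horizontal calliper reading, µm.

    Returns ``max(0, true_width + bias + eps_L + eps_R)`` where the
    systematic part is ``bias_coeff * lateral_resolution`` and ``eps_L``,
    ``eps_R`` are independent zero-mean Gaussian endpoint errors with SD
    ``jitter_coeff * lateral_resolution``.
    """
    if true_width < 0.0:
        raise ValueError("true_width must be >= 0")
    sd = obs.jitter_coeff * protocol.lateral_resolution
    eps = rng.normal(0.0, sd, size=2) if sd > 0.0 else np.zeros(2)
    value = true_width + obs.bias_coeff * protocol.lateral_resolution + eps.sum()
    return max(0.0, value)


def measure_height_scaled(
    true_height: float,
    vscale: float,
    obs: ObserverModel,
    rng: np.random.Generator,
) -> float:
    """One manual height calliper reading under vertical display scaling, µm.

    The height is drawn perpendicular to the RPE in model space; on the
    display it spans ``vscale * true_height`` vertically.  Within an angular
    tolerance of ``oblique_tol_deg`` from vertical *on screen*, the top
    endpoint may drift horizontally by up to
    ``w = vscale * true_height * tan(oblique_tol_deg)`` true µm (horizontal
    display units map 1:1 to µm).  The drift is uniform on ``[-w, +w]`` and
    the reported length is ``sqrt(dx^2 + true_height^2)`` — always at least
    the true height, with the inflation growing with vscale.
    """
    if true_height <= 0.0:
        raise ValueError("true_height must be > 0")
    if vscale < 1.0:
        raise ValueError("vscale must be >= 1")
    w = vscale * true_height * math.tan(math.radians(obs.oblique_tol_deg))
    dx = rng.uniform(-w, w) if w > 0.0 else 0.0
    return math.hypot(dx, true_height)


def select_slice(
    slices: Sequence[SliceProfile],
    obs: ObserverModel,
    rng: np.random.Generator,
) -> SliceProfile:
    """The slice a grader actually measures on.

    With probability ``1 - slice_error_prob`` this is the widest slice
    (ties resolved as in :func:`octcaliper.raster.widest_slice`); otherwise
    an adjacent slice in the list (position ±1, equiprobable, clamped to
    the valid range) is chosen.
    """
    if not slices:
        raise ValueError("select_slice requires a non-empty slice list")
    best = widest_slice(slices)
    if len(slices) == 1:
        return best
    # Draw unconditionally so the RNG stream does not depend on the knobs.
    u = rng.uniform()
    step = 1 if rng.uniform() < 0.5 else -1
    if u >= obs.slice_error_prob:
        return best
    pos = next(i for i, s in enumerate(slices) if s is best)
    pos = min(max(pos + step, 0), len(slices) - 1)
    return slices[pos]
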