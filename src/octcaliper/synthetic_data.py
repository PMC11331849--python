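"""Seeded synthetic cohorts and full measurement-study simulation.

Emulates the study design the simulator exists to probe: a cohort of eyes
with full-thickness macular holes, each imaged on two OCT machines and
measured by two graders, four parameters per scan (MLD, BD, nasal and
temporal hole height) — 8 eyes x 2 machines x 2 observers x 4 parameters
= 128 calliper readings at the default cohort size.

RNG discipline: one master seed; per-(eye, protocol) and
per-(eye, protocol, observer) child generators are derived from it by key,
so subsetting the cohort or the protocol list does not shift the draws of
the remaining units.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import MacularHoleModel
from .observer import (
    ObserverModel,
    measure_height_scaled,
    measure_horizontal,
    select_slice,
)
from .raster import ScanProtocol, acquire

__all__ = [
    "PARAMETERS",
    "CohortConfig",
    "MeasurementRecord",
    "generate_cohort",
    "simulate_study",
    "records_to_frame",
    "write_measurements_csv",
    "read_measurements_csv",
]

#: The four parameters measured per scan.
PARAMETERS = ("MLD", "BD", "HH_nasal", "HH_temporal")

CSV_COLUMNS = ["eye_id", "machine", "observer", "parameter", "value_um", "vscale_used"]


@dataclass(frozen=True)
class CohortConfig:
    """Distributional description of a synthetic macular-hole cohort.

    Defaults emulate a plausible surgical FTMH case mix: MLD lognormal with
    median 350 µm and log-SD 0.45 (roughly 150-800 µm across the cohort),
    basal diameter 1.5-2.5x the MLD, hole heights Gaussian 420 ± 60 µm, and
    a per-acquisition fixation decentration SD of 50 µm (poor vision or
    eccentric fixation shifts the raster relative to the fovea).

    All SDs in µm except ``mld_log_sd`` (log-scale, dimensionless).
    """

    n_eyes: int = 8
    mld_log_mean: float = math.log(350.0)
    mld_log_sd: float = 0.45
    bd_ratio_min: float = 1.5
    bd_ratio_max: float = 2.5
    height_mean: float = 420.0
    height_sd: float = 60.0
    fixation_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if not (1.0 < self.bd_ratio_min <= self.bd_ratio_max):
            raise ValueError("require 1 < bd_ratio_min <= bd_ratio_max")
        if min(self.mld_log_sd, self.height_sd, self.fixation_sd) < 0.0:
            raise ValueError("all SDs must be >= 0")
        if self.height_mean <= 0.0:
            raise ValueError("height_mean must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from YAML or JSON; unspecified fields keep defaults."""
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        ) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config fields")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MeasurementRecord:
    """One simulated (or imported) calliper reading."""

    eye_id: str
    machine: str
    observer: str
    parameter: str
    value_um: float
    vscale_used: float

    def __post_init__(self) -> None:
        if self.value_um < 0.0:
            raise ValueError("value_um must be >= 0")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"parameter must be one of {PARAMETERS}")


def _child_rng(*key: int) -> np.random.Generator:
    # Keyed child stream: stable under subsetting of eyes/protocols/observers.
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def generate_cohort(cfg: CohortConfig) -> list[MacularHoleModel]:
    """Draw ``cfg.n_eyes`` ground-truth holes; deterministic given ``cfg.seed``.

    MLD is lognormal, BD a uniform multiple of the MLD, heights Gaussian
    truncated at > 0 (resampled).  ``center_y`` is left at 0: fixation
    decentration is an acquisition-time effect applied by
    :func:`simulate_study`, not a property of the hole.
    """
    holes = []
    for i in range(cfg.n_eyes):
        rng = _child_rng(cfg.seed, 0, i)
        d_mld = float(np.exp(rng.normal(cfg.mld_log_mean, cfg.mld_log_sd)))
        d_bd = d_mld * float(rng.uniform(cfg.bd_ratio_min, cfg.bd_ratio_max))
        heights = []
        for _ in range(2):
            h = float(rng.normal(cfg.height_mean, cfg.height_sd))
            while h <= 0.0:
                h = float(rng.normal(cfg.height_mean, cfg.height_sd))
            heights.append(h)
        holes.append(
            MacularHoleModel(
                d_mld=d_mld,
                d_bd=d_bd,
                h_nasal=heights[0],
                h_temporal=heights[1],
                center_y=0.0,
            )
        )
    return holes


def simulate_study(
    cohort: Sequence[MacularHoleModel],
    protocols: Sequence[ScanProtocol],
    observers: Sequence[ObserverModel],
    use_default_vscale: bool = True,
    seed: int = 0,
    fixation_sd: float = 50.0,
) -> list[MeasurementRecord]:
    """Simulate the full measurement study on a cohort.

    For each eye x protocol, one acquisition is simulated: a raster phase
    uniform on ``[0, spacing)`` and a Gaussian fixation offset
    (SD ``fixation_sd``) are drawn and shared by both observers — the
    graders measure the same acquired volume.  Each observer then selects a
    slice independently, reads MLD and BD from that slice's chords with
    endpoint jitter and bias, and reads the two heights under the
    protocol's default vertical scaling (or 1:1 when
    ``use_default_vscale`` is False).

    Returns ``len(cohort) * len(protocols) * len(observers) * 4`` records.
    """
    if not protocols or not observers:
        raise ValueError("protocols and observers must be non-empty")
    records: list[MeasurementRecord] = []
    for i, hole in enumerate(cohort):
        eye_id = f"eye{i + 1:03d}"
        for p_idx, proto in enumerate(protocols):
            acq_rng = _child_rng(seed, 1, i, p_idx)
            phase = float(acq_rng.uniform(0.0, proto.bscan_spacing))
            fix = (
                float(acq_rng.normal(0.0, fixation_sd)) if fixation_sd > 0.0 else 0.0
            )
            # Raster centred on fovea + fixation error <=> hole displaced by -fix.
            seen = replace(hole, center_y=hole.center_y - fix)
            slices = acquire(seen, proto, phase)
            vscale = proto.default_vscale if use_default_vscale else 1.0
            for o_idx, obs in enumerate(observers):
                rng = _child_rng(seed, 2, i, p_idx, o_idx)
                chosen = select_slice(slices, obs, rng)
                values = {
                    "MLD": float(measure_horizontal(chosen.apparent_mld, proto, obs, rng)),
                    "BD": float(measure_horizontal(chosen.apparent_bd, proto, obs, rng)),
                    "HH_nasal": float(measure_height_scaled(hole.h_nasal, vscale, obs, rng)),
                    "HH_temporal": float(
                        measure_height_scaled(hole.h_temporal, vscale, obs, rng)
                    ),
                }
                for param in PARAMETERS:
                    records.append(
                        MeasurementRecord(
                            eye_id=eye_id,
                            machine=proto.name,
                            observer=obs.observer_id,
                            parameter=param,
                            value_um=values[param],
                            vscale_used=vscale if param.startswith("HH") else 1.0,
                        )
                    )
    return records


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Measurement records as a tidy DataFrame (one row per calliper reading)."""
    return pd.DataFrame([asdict(r) for r in records], columns=CSV_COLUMNS)


def write_measurements_csv(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write the measurement table CSV (UTF-8, comma separated, '.' decimal).

    Values are written with ``repr`` round-trip precision so the file is
    bit-stable for a fixed seed.
    """
    records_to_frame(records).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> list[MeasurementRecord]:
    """Read a measurement table CSV; extra columns are tolerated and ignored."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        MeasurementRecord(
            eye_id=str(row.eye_id),
            machine=str(row.machine),
            observer=str(row.observer),
            parameter=str(row.parameter),
            value_um=float(row.value_um),
            vscale_used=float(row.vscale_used),
        )
        for row in df[CSV_COLUMNS].itertuples(index=False)
    ]
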