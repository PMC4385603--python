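"""Raw-count <-> physical-unit conversion and trace file I/O.

Standard units: accelerometer in g, gyroscope in rad/s, magnetometer in
gauss.  The g unit converts to SI via the fixed constant
``STANDARD_GRAVITY`` = 9.812865328 m/s^2.

Traces travel as CSV (columns ``t, ax, ay, az, gx, gy, gz, mx, my, mz``)
with a JSON sidecar recording the units ("raw" or "standard") and the node
placement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import STANDARD_GRAVITY, PLACEMENTS

__all__ = [
    "RawSample",
    "InertialSample",
    "SensorScale",
    "ConversionTable",
    "default_conversion_table",
    "raw_to_inertial",
    "inertial_to_raw",
    "g_to_ms2",
    "write_trace_csv",
    "read_trace_csv",
]

TRACE_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


@dataclass(frozen=True)
class RawSample:
    """One timestamped reading of integer sensor counts."""

    t: float
    accel_raw: Tuple[int, int, int]
    gyro_raw: Tuple[int, int, int]
    mag_raw: Tuple[int, int, int]


@dataclass(frozen=True)
class InertialSample:
    """Standardized tri-sensor reading (accel g, gyro rad/s, mag gauss)."""

    t: float
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray


@dataclass(frozen=True)
class SensorScale:
    """Affine map between counts and physical units for one sensor."""

    scale: float          # units per count
    offset: float = 0.0   # counts

    def __post_init__(self) -> None:
        if self.scale == 0.0:
            raise ValueError("sensor scale must be non-zero")


@dataclass(frozen=True)
class ConversionTable:
    """Per-sensor conversion scales and the ADC bit width."""

    accel: SensorScale
    gyro: SensorScale
    mag: SensorScale
    adc_bits: int = 16

    @property
    def count_min(self) -> int:
        return -(2 ** (self.adc_bits - 1))

    @property
    def count_max(self) -> int:
        return 2 ** (self.adc_bits - 1) - 1


def default_conversion_table() -> ConversionTable:
    """+-8 g accel, +-2000 deg/s gyro, +-4 gauss mag at 16-bit resolution."""
    full = 2**15
    return ConversionTable(
        accel=SensorScale(scale=8.0 / full),
        gyro=SensorScale(scale=np.deg2rad(2000.0) / full),
        mag=SensorScale(scale=4.0 / full),
        adc_bits=16,
    )


def _decode(counts: Sequence[int], sc: SensorScale, tab: ConversionTable) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    lo, hi = tab.count_min, tab.count_max
    if np.any(c < lo) or np.any(c > hi):
        warnings.warn("raw count outside ADC range; clamping", stacklevel=3)
        c = np.clip(c, lo, hi)
    return (c - sc.offset) * sc.scale


def _encode(values: Sequence[float], sc: SensorScale, tab: ConversionTable) -> Tuple[int, int, int]:
    v = np.asarray(values, dtype=float)
    counts = np.rint(v / sc.scale + sc.offset)
    counts = np.clip(counts, tab.count_min, tab.count_max)
    return tuple(int(c) for c in counts)


def raw_to_inertial(r: RawSample, tab: ConversionTable) -> InertialSample:
    """Decode integer counts into standard physical units."""
    return InertialSample(
        t=r.t,
        accel=_decode(r.accel_raw, tab.accel, tab),
        gyro=_decode(r.gyro_raw, tab.gyro, tab),
        mag=_decode(r.mag_raw, tab.mag, tab),
    )


def inertial_to_raw(s: InertialSample, tab: ConversionTable) -> RawSample:
    """Encode standard units into integer counts (round, clamp to ADC range)."""
    return RawSample(
        t=s.t,
        accel_raw=_encode(s.accel, tab.accel, tab),
        gyro_raw=_encode(s.gyro, tab.gyro, tab),
        mag_raw=_encode(s.mag, tab.mag, tab),
    )


def g_to_ms2(a_g):
    """Convert acceleration from g to m/s^2 (1 g = 9.812865328 m/s^2)."""
    return np.multiply(a_g, STANDARD_GRAVITY)


# ---------------------------------------------------------------------------
# Trace I/O


def write_trace_csv(
    path: str | Path,
    samples: Sequence[RawSample] | Sequence[InertialSample],
    placement: str,
    units: str,
) -> None:
    """Write a node trace as CSV plus a ``<stem>.meta.json`` sidecar."""
    if placement not in PLACEMENTS:
        raise ValueError(f"unknown placement {placement!r}")
    if units not in ("raw", "standard"):
        raise ValueError("units must be 'raw' or 'standard'")
    path = Path(path)
    rows = []
    for s in samples:
        if units == "raw":
            rows.append([s.t, *s.accel_raw, *s.gyro_raw, *s.mag_raw])
        else:
            rows.append([s.t, *s.accel, *s.gyro, *s.mag])
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps({"units": units, "placement": placement}, indent=2))


def read_trace_csv(path: str | Path):
    """Read a node trace CSV; returns (samples, placement, units).

    Samples are :class:`RawSample` for raw traces and :class:`InertialSample`
    for standard ones, according to the sidecar.
    """
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"timestamps not strictly increasing in {path}")
    samples: List = []
    if meta["units"] == "raw":
        for row in df.itertuples(index=False):
            samples.append(
                RawSample(
                    t=float(row.t),
                    accel_raw=(int(row.ax), int(row.ay), int(row.az)),
                    gyro_raw=(int(row.gx), int(row.gy), int(row.gz)),
                    mag_raw=(int(row.mx), int(row.my), int(row.mz)),
                )
            )
    else:
        for row in df.itertuples(index=False):
            samples.append(
                InertialSample(
                    t=float(row.t),
                    accel=np.array([row.ax, row.ay, row.az]),
                    gyro=np.array([row.gx, row.gy, row.gz]),
                    mag=np.array([row.mx, row.my, row.mz]),
                )
            )
    return samples, meta["placement"], meta["units"]
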