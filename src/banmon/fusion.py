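"""Orientation fusion: Madgwick AHRS filter, calibration capture, frame
normalization.

The filter implements the gradient-descent MARG update: the quaternion
derivative from gyro integration is corrected by ``beta`` times the
normalized gradient of the combined gravity + magnetic-field alignment
objective.  The quaternion maps body-frame vectors into the world frame
(z-up), consistent with :mod:`banmon.quatmath`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quatmath import (
    Calibration,
    Quaternion,
    compute_rotation,
    normalize_to_external,
    quat_mean,
)
from .sensor_model import InertialSample

__all__ = [
    "FilterParams",
    "FusedSample",
    "madgwick_update",
    "fuse_stream",
    "capture_calibration",
    "CalibrationUnavailableError",
    "write_fused_csv",
    "read_fused_csv",
    "save_calibration",
    "load_calibration",
]

logger = logging.getLogger(__name__)


class CalibrationUnavailableError(RuntimeError):
    """Raised when a calibration cannot be captured from the given streams."""


@dataclass(frozen=True)
class FilterParams:
    """Fusion filter configuration: gain ``beta`` and sample period ``dt``."""

    beta: float = 0.1
    dt: float = 0.02

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class FusedSample:
    """Fused orientation plus the filtered proper acceleration (g)."""

    t: float
    q: Quaternion
    accel: np.ndarray


def _madgwick_step(
    q: Tuple[float, float, float, float],
    gyro: Sequence[float],
    accel: Sequence[float],
    mag: Sequence[float],
    beta: float,
    dt: float,
) -> Tuple[float, float, float, float]:
    """One MARG update on plain floats; returns the unnormalized new q.

    Gradient terms follow the standard formulation with q = (q1,q2,q3,q4)
    mapping body to world; the magnetic reference (bx, 0, bz) is rebuilt
    from the current estimate each step so only the field's inclination
    matters.
    """
    q1, q2, q3, q4 = q
    gx, gy, gz = float(gyro[0]), float(gyro[1]), float(gyro[2])

    # Rate of change from gyroscope
    qDot1 = 0.5 * (-q2 * gx - q3 * gy - q4 * gz)
    qDot2 = 0.5 * (q1 * gx + q3 * gz - q4 * gy)
    qDot3 = 0.5 * (q1 * gy - q2 * gz + q4 * gx)
    qDot4 = 0.5 * (q1 * gz + q2 * gy - q3 * gx)

    ax, ay, az = float(accel[0]), float(accel[1]), float(accel[2])
    mx, my, mz = float(mag[0]), float(mag[1]), float(mag[2])
    a_norm = math.sqrt(ax * ax + ay * ay + az * az)
    m_norm = math.sqrt(mx * mx + my * my + mz * mz)

    if beta > 0.0 and a_norm > 1e-12 and m_norm > 1e-12:
        ax, ay, az = ax / a_norm, ay / a_norm, az / a_norm
        mx, my, mz = mx / m_norm, my / m_norm, mz / m_norm

        # Reference direction of the magnetic field in the world frame
        hx = (
            mx * (q1 * q1 + q2 * q2 - q3 * q3 - q4 * q4)
            + 2.0 * my * (q2 * q3 - q1 * q4)
            + 2.0 * mz * (q2 * q4 + q1 * q3)
        )
        hy = (
            2.0 * mx * (q2 * q3 + q1 * q4)
            + my * (q1 * q1 - q2 * q2 + q3 * q3 - q4 * q4)
            + 2.0 * mz * (q3 * q4 - q1 * q2)
        )
        hz = (
            2.0 * mx * (q2 * q4 - q1 * q3)
            + 2.0 * my * (q3 * q4 + q1 * q2)
            + mz * (q1 * q1 - q2 * q2 - q3 * q3 + q4 * q4)
        )
        bx = math.sqrt(hx * hx + hy * hy)
        bz = hz

        # Objective: predicted body-frame gravity and field minus measurements
        fg1 = 2.0 * (q2 * q4 - q1 * q3) - ax
        fg2 = 2.0 * (q1 * q2 + q3 * q4) - ay
        fg3 = 2.0 * (0.5 - q2 * q2 - q3 * q3) - az
        fb1 = 2.0 * bx * (0.5 - q3 * q3 - q4 * q4) + 2.0 * bz * (q2 * q4 - q1 * q3) - mx
        fb2 = 2.0 * bx * (q2 * q3 - q1 * q4) + 2.0 * bz * (q1 * q2 + q3 * q4) - my
        fb3 = 2.0 * bx * (q1 * q3 + q2 * q4) + 2.0 * bz * (0.5 - q2 * q2 - q3 * q3) - mz

        # Gradient = J^T f
        s1 = (
            -2.0 * q3 * fg1
            + 2.0 * q2 * fg2
            - 2.0 * bz * q3 * fb1
            + (-2.0 * bx * q4 + 2.0 * bz * q2) * fb2
            + 2.0 * bx * q3 * fb3
        )
        s2 = (
            2.0 * q4 * fg1
            + 2.0 * q1 * fg2
            - 4.0 * q2 * fg3
            + 2.0 * bz * q4 * fb1
            + (2.0 * bx * q3 + 2.0 * bz * q1) * fb2
            + (2.0 * bx * q4 - 4.0 * bz * q2) * fb3
        )
        s3 = (
            -2.0 * q1 * fg1
            + 2.0 * q4 * fg2
            - 4.0 * q3 * fg3
            + (-4.0 * bx * q3 - 2.0 * bz * q1) * fb1
            + (2.0 * bx * q2 + 2.0 * bz * q4) * fb2
            + (2.0 * bx * q1 - 4.0 * bz * q3) * fb3
        )
        s4 = (
            2.0 * q2 * fg1
            + 2.0 * q3 * fg2
            + (-4.0 * bx * q4 + 2.0 * bz * q2) * fb1
            + (-2.0 * bx * q1 + 2.0 * bz * q3) * fb2
            + 2.0 * bx * q2 * fb3
        )
        s_norm = math.sqrt(s1 * s1 + s2 * s2 + s3 * s3 + s4 * s4)
        if s_norm > 1e-12:
            qDot1 -= beta * s1 / s_norm
            qDot2 -= beta * s2 / s_norm
            qDot3 -= beta * s3 / s_norm
            qDot4 -= beta * s4 / s_norm
    elif beta > 0.0:
        # Degenerate measurement: fall back to pure gyro integration
        logger.debug("zero accel or mag sample; skipping corrective step")

    return (q1 + qDot1 * dt, q2 + qDot2 * dt, q3 + qDot3 * dt, q4 + qDot4 * dt)


def madgwick_update(q_prev: Quaternion, s: InertialSample, p: FilterParams) -> Quaternion:
    """Advance the orientation estimate by one sample."""
    q = _madgwick_step(
        (q_prev.w, q_prev.x, q_prev.y, q_prev.z), s.gyro, s.accel, s.mag, p.beta, p.dt
    )
    return Quaternion(*q).normalized()


def fuse_stream(
    samples: Sequence[InertialSample],
    p: FilterParams,
    cal: Optional[Calibration] = None,
    q0: Optional[Quaternion] = None,
    invert_rotation: bool = True,
) -> List[FusedSample]:
    """Fuse an inertial stream into per-sample orientations.

    When ``cal`` is given each orientation is re-expressed in the external
    referential via the rotation/normalization transforms; the filtered
    proper acceleration is carried through untouched.
    """
    out: List[FusedSample] = []
    q = (1.0, 0.0, 0.0, 0.0) if q0 is None else (q0.w, q0.x, q0.y, q0.z)
    for s in samples:
        q = _madgwick_step(q, s.gyro, s.accel, s.mag, p.beta, p.dt)
        n = math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
        q = (q[0] / n, q[1] / n, q[2] / n, q[3] / n)
        quat = Quaternion(*q)
        if cal is not None:
            quat = normalize_to_external(
                compute_rotation(quat, cal), cal, invert_rotation=invert_rotation
            )
        out.append(FusedSample(t=s.t, q=quat, accel=np.asarray(s.accel, dtype=float)))
    return out


def capture_calibration(
    internal_qs: Sequence[Quaternion], external_qs: Sequence[Quaternion]
) -> Calibration:
    """Average both orientation streams into a :class:`Calibration`."""
    if len(internal_qs) == 0 or len(external_qs) == 0:
        raise CalibrationUnavailableError("both orientation streams must be non-empty")
    return Calibration(
        q_wn=quat_mean(internal_qs),
        q_cv=quat_mean(external_qs),
        n_samples=min(len(internal_qs), len(external_qs)),
    )


# ---------------------------------------------------------------------------
# I/O helpers

FUSED_COLUMNS = ["t", "qw", "qx", "qy", "qz", "ax", "ay", "az"]


def write_fused_csv(path: str | Path, samples: Sequence[FusedSample]) -> None:
    rows = [[s.t, s.q.w, s.q.x, s.q.y, s.q.z, *s.accel] for s in samples]
    pd.DataFrame(rows, columns=FUSED_COLUMNS).to_csv(path, index=False)


def read_fused_csv(path: str | Path) -> List[FusedSample]:
    df = pd.read_csv(path)
    return [
        FusedSample(
            t=float(r.t),
            q=Quaternion(float(r.qw), float(r.qx), float(r.qy), float(r.qz)).normalized(),
            accel=np.array([r.ax, r.ay, r.az]),
        )
        for r in df.itertuples(index=False)
    ]


def save_calibration(path: str | Path, cal: Calibration) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "q_wn": list(cal.q_wn.as_array()),
                "q_cv": list(cal.q_cv.as_array()),
                "n_samples": cal.n_samples,
            },
            indent=2,
        )
    )


def load_calibration(path: str | Path) -> Calibration:
    data = json.loads(Path(path).read_text())
    return Calibration(
        q_wn=Quaternion.from_array(data["q_wn"]).normalized(),
        q_cv=Quaternion.from_array(data["q_cv"]).normalized(),
        n_samples=int(data["n_samples"]),
    )
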