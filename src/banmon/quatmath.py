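"""Quaternion algebra and reference-frame calibration transforms.

Conventions
-----------
Components are ordered ``(w, x, y, z)`` with the Hamilton product and
right-handed frames.  A quaternion ``q`` maps body-frame vectors into the
world frame: ``v_world = q v_body q^-1``.  The world frame is z-up, so a
node at rest with its longitudinal (z) axis pointing up measures proper
acceleration ``(0, 0, +1)`` g.

The calibration transforms align the internal (sensor-fused) referential
with an external reference system.  Given the averaged initial orientation
of each system (``q_wn`` internal, ``q_cv`` external), a fused orientation
``q`` is first turned into the rotation relative to the internal average,

    q_rot = q * q_wn^-1

and that rotation is then applied to the external average,

    q_norm = q_cv * q_rot^-1

The second formula uses the *inverse* of the just-computed rotation; the
conventional composition would be ``q_cv * q_rot``.  Both variants are
implemented (see :func:`normalize_to_external`), with the inverse form the
default.  Note that the tilt angle relative to world vertical is invariant
under quaternion inversion, so the downstream posture logic is unaffected
by the choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Quaternion",
    "Calibration",
    "InvalidQuaternionError",
    "DegenerateAverageError",
    "quat_multiply",
    "quat_inverse",
    "quat_rotate_vector",
    "quat_mean",
    "compute_rotation",
    "normalize_to_external",
    "from_axis_angle",
    "angle_between",
    "tilt_deg",
]

UNIT_TOL = 1e-9


class InvalidQuaternionError(ValueError):
    """Raised for non-finite or zero quaternion inputs."""


class DegenerateAverageError(ValueError):
    """Raised when an average collapses below usable norm."""


@dataclass(frozen=True)
class Quaternion:
    """Unit rotation quaternion with components ``(w, x, y, z)``."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.w, self.x, self.y, self.z)):
            raise InvalidQuaternionError(f"non-finite components: {self}")

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "Quaternion":
        w, x, y, z = (float(c) for c in arr)
        return cls(w, x, y, z)

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    @property
    def norm(self) -> float:
        return math.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)

    def normalized(self) -> "Quaternion":
        n = self.norm
        if n < 1e-12:
            raise InvalidQuaternionError("cannot normalize zero quaternion")
        return Quaternion(self.w / n, self.x / n, self.y / n, self.z / n)

    def conjugate(self) -> "Quaternion":
        return Quaternion(self.w, -self.x, -self.y, -self.z)

    def canonical(self) -> "Quaternion":
        """Flip sign so that w >= 0 (q and -q are the same rotation)."""
        if self.w < 0:
            return Quaternion(-self.w, -self.x, -self.y, -self.z)
        return self

    def is_unit(self, tol: float = 1e-6) -> bool:
        return abs(self.norm - 1.0) < tol


@dataclass(frozen=True)
class Calibration:
    """Averaged initial orientations of the internal and external systems."""

    q_wn: Quaternion
    q_cv: Quaternion
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (self.q_wn.is_unit() and self.q_cv.is_unit()):
            raise InvalidQuaternionError("calibration quaternions must be unit-norm")


def quat_multiply(q1: Quaternion, q2: Quaternion) -> Quaternion:
    """Hamilton product ``q1 * q2``, renormalized."""
    w1, x1, y1, z1 = q1.w, q1.x, q1.y, q1.z
    w2, x2, y2, z2 = q2.w, q2.x, q2.y, q2.z
    out = Quaternion(
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    )
    return out.normalized()


def quat_inverse(q: Quaternion) -> Quaternion:
    """Inverse of a unit quaternion (its conjugate)."""
    if q.norm < 1e-12:
        raise InvalidQuaternionError("zero quaternion has no inverse")
    return q.conjugate().normalized()


def quat_rotate_vector(q: Quaternion, v: Iterable[float]) -> np.ndarray:
    """Rotate a 3-vector by ``q``: returns ``q v q^-1`` (body -> world)."""
    vx, vy, vz = (float(c) for c in v)
    w, x, y, z = q.w, q.x, q.y, q.z
    # v' = v + 2 * r x (r x v + w v), r = (x, y, z)
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return np.array(
        [
            vx + w * tx + (y * tz - z * ty),
            vy + w * ty + (z * tx - x * tz),
            vz + w * tz + (x * ty - y * tx),
        ]
    )


def quat_mean(qs: Sequence[Quaternion]) -> Quaternion:
    """Sign-aligned component-wise mean, renormalized, canonical w >= 0.

    Each element is flipped to the hemisphere of ``qs[0]`` before averaging,
    so the double cover of SO(3) cannot cancel the sum.  Adequate for the
    small-dispersion clusters produced by a calibration window.
    """
    if len(qs) == 0:
        raise InvalidQuaternionError("cannot average an empty sequence")
    ref = qs[0].as_array()
    acc = np.zeros(4)
    for q in qs:
        arr = q.as_array()
        if float(arr @ ref) < 0.0:
            arr = -arr
        acc += arr
    acc /= len(qs)
    n = float(np.linalg.norm(acc))
    if n < 1e-6:
        raise DegenerateAverageError("quaternion average collapsed to ~zero norm")
    return Quaternion.from_array(acc / n).canonical()


def compute_rotation(q: Quaternion, cal: Calibration) -> Quaternion:
    """Rotation relative to the internal average: ``q_rot = q * q_wn^-1``."""
    return quat_multiply(q, quat_inverse(cal.q_wn))


def normalize_to_external(
    q_rot: Quaternion, cal: Calibration, invert_rotation: bool = True
) -> Quaternion:
    """Express a rotation in the external referential.

    Default (``invert_rotation=True``) computes ``q_cv * q_rot^-1``; with
    ``invert_rotation=False`` it computes the conventional ``q_cv * q_rot``.
    """
    if invert_rotation:
        return quat_multiply(cal.q_cv, quat_inverse(q_rot))
    return quat_multiply(cal.q_cv, q_rot)


def from_axis_angle(axis: Iterable[float], angle_rad: float) -> Quaternion:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``."""
    ax = np.asarray(list(axis), dtype=float)
    n = float(np.linalg.norm(ax))
    if n < 1e-12:
        raise InvalidQuaternionError("axis must be non-zero")
    ax = ax / n
    half = 0.5 * angle_rad
    s = math.sin(half)
    return Quaternion(math.cos(half), ax[0] * s, ax[1] * s, ax[2] * s).normalized()


def angle_between(q1: Quaternion, q2: Quaternion) -> float:
    """Geodesic angle (radians) between two rotations."""
    dot = abs(float(q1.as_array() @ q2.as_array()))
    dot = min(1.0, dot)
    return 2.0 * math.acos(dot)


def tilt_deg(q: Quaternion) -> float:
    """Angle (degrees) between the node's longitudinal axis and world up.

    The longitudinal axis is the body z-axis; its world direction is the
    third column of the rotation matrix of ``q``.  Invariant under q -> q^-1.
    """
    w, x, y, z = q.w, q.x, q.y, q.z
    cz = 1.0 - 2.0 * (x * x + y * y)  # (R e_z) . e_z
    cz = max(-1.0, min(1.0, cz))
    return math.degrees(math.acos(cz))
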