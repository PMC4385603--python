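"""Synthetic three-node IMU trace generator with ground truth.

Each scenario prescribes, per node (chest, hip, leg), a smooth orientation
trajectory (tilt about the world x-axis plus yaw about z) and a world-frame
dynamic acceleration.  Sensor streams follow from the kinematics:

* ``accel = R(t)^T (z_hat + a_w(t)/g0) + noise``      (g, body frame)
* ``gyro  = body angular rate + noise``               (rad/s)
* ``mag   = R(t)^T B + noise``                        (gauss)

encoded to integer counts through the shared conversion table.  Walking is
modelled as a vertical sinusoid at the step frequency (one annotated step
per crest) plus a small high-frequency "locomotion jitter" that keeps the
moving-variance detector above threshold during motion; falls inject a
free-fall dip followed by sharp impact peaks; hampered falls add an
intermediate wall-contact deceleration before the ground impact.

The generator also annotates ground truth (per-sample body states, step
times, fall interval, expected anomaly flags), standing in for the human
volunteers and the external calibration system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import STANDARD_GRAVITY, PLACEMENTS, PipelineConfig
from .quatmath import Quaternion
from .sensor_model import (
    ConversionTable,
    InertialSample,
    RawSample,
    default_conversion_table,
    inertial_to_raw,
)
from .state_evaluator import (
    HORIZONTAL,
    MOVING,
    STATIONARY,
    VERTICAL,
    InsufficientDataError,
    UserProfile,
)
from .body_state import _derive_orientation

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "GroundTruth",
    "SimResult",
    "simulate_scenario",
    "make_profile",
    "calibration_suite",
    "hampered_fall_suite",
    "write_sim",
    "read_sim_inputs",
]

SCENARIOS = (
    "stand_still",
    "stand_fidget",
    "walk_L",
    "walk_hump",
    "walk_cadence_change",
    "sit_correct",
    "sit_inclined",
    "sit_rough",
    "fall_unhampered",
    "fall_hampered",
    "rest",
)

_DEFAULT_DURATION = {
    "stand_still": 10.0,
    "stand_fidget": 10.0,
    "walk_L": 16.0,
    "walk_hump": 16.0,
    "walk_cadence_change": 16.0,
    "sit_correct": 10.0,
    "sit_inclined": 10.0,
    "sit_rough": 10.0,
    "fall_unhampered": 8.0,
    "fall_hampered": 9.0,
    "rest": 60.0,
}

#: World magnetic field (gauss); a realistic dip angle so yaw is observable.
WORLD_MAG_FIELD = np.array([0.2, 0.0, -0.4])

#: Hampered falls shorter than this drop are "too small to harm" and leave
#: every screened quantity inside its normal interval.
HARMLESS_FALL_DISTANCE_M = 0.15

# Walking model constants (amplitudes of the vertical accel sinusoid, g)
_WALK_AMP = {"hip": 0.25, "leg": 0.28, "chest": 0.15}
_WALK_PHASE = {"hip": 0.0, "chest": math.pi / 2, "leg": math.pi}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic trial."""

    scenario: str
    duration: Optional[float] = None
    height_m: float = 1.73
    weight_kg: float = 75.33
    cadence: float = 1.8           # steps/s
    step_length: float = 0.7       # m (nominal, annotation only)
    fall_distance: float = 0.5     # m
    impact_peak_g: float = 3.0     # |accel| at the main impact
    wall_contact: bool = False
    variant: int = 0               # hampered-fall variant selector (0-5)
    accel_noise_g: float = 0.02
    gyro_noise: float = 0.01       # rad/s
    mag_noise: float = 0.005       # gauss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.duration is not None and self.duration <= 0):
            raise ValueError("duration must be > 0")
        for lvl in (self.accel_noise_g, self.gyro_noise, self.mag_noise):
            if lvl < 0:
                raise ValueError("noise levels must be >= 0")

    @property
    def total_duration(self) -> float:
        return self.duration if self.duration is not None else _DEFAULT_DURATION[self.scenario]


@dataclass
class GroundTruth:
    """Per-sample truth annotations, consistent with the kinematics."""

    t: np.ndarray
    body_movement: List[str]
    body_orientation: List[str]
    node_orientation: Dict[str, List[str]]
    node_tilt: Dict[str, np.ndarray]
    step_times: np.ndarray
    fall_interval: Optional[Tuple[float, float]] = None
    fall_type: Optional[str] = None
    expect_alert: Optional[bool] = None
    expect_forwarded: bool = False
    expected_candidates: Tuple[str, ...] = ()
    scenario: Optional[str] = None

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        data = {
            "scenario": self.scenario,
            "t": self.t.tolist(),
            "body_movement": self.body_movement,
            "body_orientation": self.body_orientation,
            "node_orientation": self.node_orientation,
            "node_tilt": {k: v.tolist() for k, v in self.node_tilt.items()},
            "step_times": self.step_times.tolist(),
            "fall_interval": list(self.fall_interval) if self.fall_interval else None,
            "fall_type": self.fall_type,
            "expect_alert": self.expect_alert,
            "expect_forwarded": self.expect_forwarded,
            "expected_candidates": list(self.expected_candidates),
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(
            t=np.asarray(d["t"]),
            body_movement=d["body_movement"],
            body_orientation=d["body_orientation"],
            node_orientation=d["node_orientation"],
            node_tilt={k: np.asarray(v) for k, v in d["node_tilt"].items()},
            step_times=np.asarray(d["step_times"]),
            fall_interval=tuple(d["fall_interval"]) if d["fall_interval"] else None,
            fall_type=d["fall_type"],
            expect_alert=d["expect_alert"],
            expect_forwarded=d["expect_forwarded"],
            expected_candidates=tuple(d["expected_candidates"]),
            scenario=d.get("scenario"),
        )


@dataclass
class SimResult:
    spec: ScenarioSpec
    traces: Dict[str, List[RawSample]]
    inertial: Dict[str, List[InertialSample]]
    external_ref: Dict[str, List[Quaternion]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Shape helpers


def _smoothstep(x: np.ndarray) -> np.ndarray:
    u = np.clip(x, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _env(t: np.ndarray, t0: float, t1: float, edge: float = 0.3) -> np.ndarray:
    """Smooth on/off envelope over [t0, t1]."""
    return _smoothstep((t - t0) / edge) * _smoothstep((t1 - t) / edge)


def _ramp(t: np.ndarray, t0: float, t1: float, v0: float, v1: float) -> np.ndarray:
    return v0 + (v1 - v0) * _smoothstep((t - t0) / max(t1 - t0, 1e-9))


def _pulse(t: np.ndarray, tc: float, amp: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - tc) / sigma) ** 2)


def _jitter(t: np.ndarray, env: np.ndarray, amp_g: float, phase: float) -> np.ndarray:
    """High-frequency deterministic body vibration (m/s^2, world z)."""
    wave = 0.55 * np.sin(2 * math.pi * 4.3 * t + phase) + 0.45 * np.sin(
        2 * math.pi * 6.1 * t + 1.7 * phase + 0.9
    )
    return amp_g * STANDARD_GRAVITY * wave * env


@dataclass
class _Tracks:
    """Mutable per-node kinematic tracks while a scenario is being built."""

    t: np.ndarray
    theta: Dict[str, np.ndarray]   # tilt about world x, rad
    yaw: Dict[str, np.ndarray]     # rad
    aw: Dict[str, np.ndarray]      # world dynamic accel, m/s^2, (n, 3)
    moving: Dict[str, np.ndarray]  # truth movement envelope (bool)
    step_times: List[float] = field(default_factory=list)

    @classmethod
    def zeros(cls, t: np.ndarray) -> "_Tracks":
        n = t.shape[0]
        return cls(
            t=t,
            theta={p: np.zeros(n) for p in PLACEMENTS},
            yaw={p: np.zeros(n) for p in PLACEMENTS},
            aw={p: np.zeros((n, 3)) for p in PLACEMENTS},
            moving={p: np.zeros(n, dtype=bool) for p in PLACEMENTS},
        )

    def mark_moving(self, t0: float, t1: float, nodes: Sequence[str] = PLACEMENTS) -> None:
        mask = (self.t >= t0) & (self.t <= t1)
        for p in nodes:
            self.moving[p][mask] = True


def _add_walking_bout(tr: _Tracks, t0: float, t1: float, cadence: float) -> None:
    t = tr.t
    env = _env(t, t0, t1, edge=0.3)
    for node in PLACEMENTS:
        amp = _WALK_AMP[node] * STANDARD_GRAVITY
        ph = _WALK_PHASE[node]
        tr.aw[node][:, 2] += amp * np.sin(2 * math.pi * cadence * (t - t0) + ph) * env
        tr.aw[node][:, 0] += 0.08 * STANDARD_GRAVITY * np.sin(
            2 * math.pi * cadence * (t - t0) + ph + 1.3
        ) * env
        tr.aw[node][:, 2] += _jitter(t, env, 0.05, ph)
    # gait-coupled orientation wobble: chest pitch, leg swing
    tr.theta["chest"] += np.deg2rad(3.0) * np.sin(2 * math.pi * cadence * (t - t0)) * env
    stride = cadence / 2.0
    tr.theta["leg"] += np.deg2rad(12.0) * 0.5 * (1 - np.cos(2 * math.pi * stride * (t - t0))) * env
    tr.mark_moving(t0, t1)
    # one annotated step per crest of the hip sinusoid
    n_steps = int(math.floor(cadence * (t1 - t0)))
    for k in range(n_steps):
        tr.step_times.append(t0 + (k + 0.25) / cadence)


def _add_vertical_bump(
    tr: _Tracks, t0: float, t1: float, amp_ms2: float, nodes: Sequence[str] = PLACEMENTS
) -> None:
    """One down/up accel cycle (e.g. a sit-down dip): -amp then +amp."""
    t = tr.t
    mask_env = _env(t, t0, t1, edge=0.2)
    cyc = -amp_ms2 * np.sin(2 * math.pi * (t - t0) / max(t1 - t0, 1e-9))
    for node in nodes:
        tr.aw[node][:, 2] += cyc * mask_env


def _add_impact(tr: _Tracks, tc: float, peaks_g: Dict[str, float], sigma: float = 0.03) -> None:
    """Sharp vertical deceleration so |accel| reaches ``peaks_g[node]``."""
    for node, peak in peaks_g.items():
        tr.aw[node][:, 2] += _pulse(tr.t, tc, (peak - 1.0) * STANDARD_GRAVITY, sigma)


def _add_transition_jitter(tr: _Tracks, t0: float, t1: float, amp_g: float = 0.08,
                           nodes: Sequence[str] = PLACEMENTS) -> None:
    env = _env(tr.t, t0, t1, edge=0.2)
    for i, node in enumerate(nodes):
        tr.aw[node][:, 2] += _jitter(tr.t, env, amp_g, phase=0.8 * i)


# ---------------------------------------------------------------------------
# Scenario builders


def _build_stand(tr: _Tracks, spec: ScenarioSpec, fidget: bool) -> dict:
    if fidget:
        t0, t1 = 3.0, spec.total_duration - 1.0
        _add_transition_jitter(tr, t0, t1, amp_g=0.1, nodes=["chest"])
        tr.mark_moving(t0, t1, nodes=["chest"])
    return {"expect_alert": False}


def _build_walk(tr: _Tracks, spec: ScenarioSpec, style: str) -> dict:
    D = spec.total_duration
    meta: dict = {"expect_alert": False}
    if style == "L":
        b1 = (3.0, 8.5)
        b2 = (10.5, D - 1.5)
        _add_walking_bout(tr, *b1, spec.cadence)
        _add_walking_bout(tr, *b2, spec.cadence)
        for node in PLACEMENTS:  # 90 degree turn during the stop
            tr.yaw[node] += np.deg2rad(90.0) * _smoothstep((tr.t - 9.0) / 1.0)
        bouts = [b1, b2]
    else:
        b1 = (3.0, D - 2.0)
        _add_walking_bout(tr, *b1, spec.cadence)
        bouts = [b1]
    if style == "hump":
        hump = np.deg2rad(40.0)
        for (t0, t1) in bouts:
            tr.theta["chest"] += hump * _env(tr.t, t0 + 0.5, t1 + 0.5, edge=0.8)
        meta.update(expect_alert=None, expected_candidates=("tilt",))
    if style == "cadence":
        meta.update(expect_alert=None, expected_candidates=("step_cadence",))
    return meta


def _build_sit(tr: _Tracks, spec: ScenarioSpec, style: str) -> dict:
    t0 = 3.0
    dur = 0.8 if style == "rough" else 1.5
    t1 = t0 + dur
    tr.theta["leg"] += np.deg2rad(90.0) * _smoothstep((tr.t - t0) / dur)
    if style == "inclined":
        tr.theta["chest"] += np.deg2rad(35.0) * _smoothstep((tr.t - t0) / dur)
    _add_vertical_bump(tr, t0, t1, amp_ms2=1.5)
    _add_transition_jitter(tr, t0 - 0.2, t1 + 0.3)
    tr.mark_moving(t0, t1 + 0.2)
    meta: dict = {"expect_alert": False}
    if style == "rough":
        _add_impact(tr, t1, {"hip": 2.2, "chest": 1.15}, sigma=0.03)
        meta["expect_forwarded"] = True
    if style == "inclined":
        meta.update(expect_alert=True, expected_candidates=("tilt",))
    return meta


def _build_fall_unhampered(tr: _Tracks, spec: ScenarioSpec) -> dict:
    t0, t1 = 3.0, 3.5
    for node in PLACEMENTS:
        tr.theta[node] += np.deg2rad(90.0) * _smoothstep((tr.t - t0) / (t1 - t0))
        tr.aw[node][:, 2] += -0.8 * STANDARD_GRAVITY * _env(tr.t, t0 + 0.02, t1 - 0.08, edge=0.1)
    peak = spec.impact_peak_g
    _add_impact(tr, t1, {"chest": peak, "hip": peak, "leg": max(1.0, peak - 0.8)})
    _add_transition_jitter(tr, t0, t1 + 0.2)
    tr.mark_moving(t0, t1 + 0.2)
    return {
        "expect_alert": True,
        "fall_interval": (t0, t1 + 0.2),
        "fall_type": "unhampered",
        "expected_candidates": ("accel_mag", "tilt"),
    }


#: Hampered-fall variants:
#: (free-fall dip in g, wall peaks, ground peaks, final tilt deg per node).
_HAMPERED_VARIANTS = [
    (0.35, {"hip": 1.6}, {"hip": 2.4, "chest": 2.2}, {"chest": 90, "hip": 90, "leg": 90}),
    (0.35, {}, {"hip": 2.1}, {"chest": 90, "hip": 90, "leg": 90}),
    (0.35, {"chest": 1.2}, {"hip": 1.3, "chest": 1.2}, {"chest": 90, "hip": 90, "leg": 90}),
    (0.30, {}, {"hip": 1.9}, {"chest": 45, "hip": 3, "leg": 90}),
    (0.15, {}, {}, {"chest": 40, "hip": 3, "leg": 90}),
]


def _build_fall_hampered(tr: _Tracks, spec: ScenarioSpec) -> dict:
    t = tr.t
    if spec.fall_distance < HARMLESS_FALL_DISTANCE_M:
        # Too-small drop: brief lean against the wall, gentle bump, back to
        # standing -- every screened quantity stays in its normal band.
        t0, t1 = 3.0, 3.6
        for node in ("chest", "hip"):
            tr.theta[node] += np.deg2rad(3.0) * _env(t, t0, t1 + 1.0, edge=0.5)
        _add_vertical_bump(tr, t0, t1, amp_ms2=0.8)
        _add_impact(tr, t1, {"chest": 1.12, "hip": 1.15}, sigma=0.05)
        _add_transition_jitter(tr, t0, t1 + 0.2)
        tr.mark_moving(t0, t1 + 0.2)
        return {
            "expect_alert": False,
            "fall_interval": (t0, t1 + 0.2),
            "fall_type": "hampered_harmless",
        }

    dip_g, wall_peaks, ground_peaks, final_tilt = _HAMPERED_VARIANTS[
        spec.variant % len(_HAMPERED_VARIANTS)
    ]
    ta0, ta1 = 3.0, 3.7    # lean + wall contact
    tb0, tb1 = 3.9, 4.5    # slide + ground impact
    for node in PLACEMENTS:
        mid = min(40.0, final_tilt[node])
        tr.theta[node] += np.deg2rad(mid) * _smoothstep((t - ta0) / (ta1 - ta0))
        tr.theta[node] += np.deg2rad(final_tilt[node] - mid) * _smoothstep((t - tb0) / (tb1 - tb0))
        tr.aw[node][:, 2] += -dip_g * STANDARD_GRAVITY * _env(t, ta0 + 0.1, ta1 - 0.05, edge=0.15)
    if wall_peaks:
        _add_impact(tr, ta1, wall_peaks, sigma=0.04)
    if ground_peaks:
        _add_impact(tr, tb1, ground_peaks, sigma=0.03)
    _add_transition_jitter(tr, ta0, tb1 + 0.2)
    tr.mark_moving(ta0, tb1 + 0.2)
    return {
        "expect_alert": True,
        "fall_interval": (ta0, tb1 + 0.2),
        "fall_type": "hampered",
        "expected_candidates": ("tilt",),
    }


# ---------------------------------------------------------------------------
# Assembly


def _quat_arrays(theta: np.ndarray, yaw: np.ndarray) -> np.ndarray:
    """q = rot_z(yaw) * rot_x(theta), vectorized, shape (n, 4) wxyz."""
    cz, sz = np.cos(yaw / 2), np.sin(yaw / 2)
    cx, sx = np.cos(theta / 2), np.sin(theta / 2)
    # (cz,0,0,sz) * (cx,sx,0,0)
    return np.stack(
        [cz * cx, cz * sx, sz * sx, sz * cx],
        axis=1,
    )


def _rotate_inverse(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """R(q)^T v for arrays of quaternions (n,4) and vectors (n,3) or (3,)."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    if v.ndim == 1:
        v = np.broadcast_to(v, (q.shape[0], 3))
    vx, vy, vz = v[:, 0], v[:, 1], v[:, 2]
    # conjugate rotation: use q* = (w, -x, -y, -z)
    tx = 2.0 * (-y * vz + z * vy)
    ty = 2.0 * (-z * vx + x * vz)
    tz = 2.0 * (-x * vy + y * vx)
    return np.stack(
        [
            vx + w * tx + (-y * tz + z * ty),
            vy + w * ty + (-z * tx + x * tz),
            vz + w * tz + (-x * ty + y * tx),
        ],
        axis=1,
    )


def _body_rates(q: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular rate from consecutive quaternions (small-angle)."""
    n = q.shape[0]
    omega = np.zeros((n, 3))
    if n < 2:
        return omega
    q1, q2 = q[:-1], q[1:]
    # vec(q1^-1 * q2) * 2/dt
    w1, x1, y1, z1 = q1[:, 0], -q1[:, 1], -q1[:, 2], -q1[:, 3]
    w2, x2, y2, z2 = q2[:, 0], q2[:, 1], q2[:, 2], q2[:, 3]
    vx = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    vy = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    vz = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    omega[:-1] = np.stack([vx, vy, vz], axis=1) * (2.0 / dt)
    omega[-1] = omega[-2]
    return omega


def _truth_orientation_states(tilt_deg_arr: np.ndarray, cfg: PipelineConfig) -> List[str]:
    states = []
    state = VERTICAL
    for tv in tilt_deg_arr:
        lo, hi = cfg.vertical_transition if state == VERTICAL else cfg.horizontal_transition
        if lo <= tv <= hi:
            state = HORIZONTAL if state == VERTICAL else VERTICAL
        states.append(state)
    return states


def simulate_scenario(
    spec: ScenarioSpec,
    cfg: Optional[PipelineConfig] = None,
    table: Optional[ConversionTable] = None,
) -> SimResult:
    """Generate raw traces, external reference orientations and ground truth."""
    cfg = cfg or PipelineConfig()
    table = table or default_conversion_table()
    dt = cfg.dt
    n = int(round(spec.total_duration / dt))
    t = np.arange(n) * dt
    tr = _Tracks.zeros(t)

    builders = {
        "stand_still": lambda: _build_stand(tr, spec, fidget=False),
        "rest": lambda: _build_stand(tr, spec, fidget=False),
        "stand_fidget": lambda: _build_stand(tr, spec, fidget=True),
        "walk_L": lambda: _build_walk(tr, spec, "L"),
        "walk_hump": lambda: _build_walk(tr, spec, "hump"),
        "walk_cadence_change": lambda: _build_walk(tr, spec, "cadence"),
        "sit_correct": lambda: _build_sit(tr, spec, "correct"),
        "sit_inclined": lambda: _build_sit(tr, spec, "inclined"),
        "sit_rough": lambda: _build_sit(tr, spec, "rough"),
        "fall_unhampered": lambda: _build_fall_unhampered(tr, spec),
        "fall_hampered": lambda: _build_fall_hampered(tr, spec),
    }
    meta = builders[spec.scenario]()

    rng = np.random.default_rng(spec.seed)
    traces: Dict[str, List[RawSample]] = {}
    inertial: Dict[str, List[InertialSample]] = {}
    external_ref: Dict[str, List[Quaternion]] = {}
    node_tilt: Dict[str, np.ndarray] = {}
    node_orient: Dict[str, List[str]] = {}

    for node in PLACEMENTS:
        q = _quat_arrays(tr.theta[node], tr.yaw[node])
        accel = _rotate_inverse(q, np.array([0.0, 0.0, 1.0]) + tr.aw[node] / STANDARD_GRAVITY)
        gyro = _body_rates(q, dt)
        mag = _rotate_inverse(q, WORLD_MAG_FIELD)
        accel = accel + rng.normal(0.0, spec.accel_noise_g, accel.shape)
        gyro = gyro + rng.normal(0.0, spec.gyro_noise, gyro.shape)
        mag = mag + rng.normal(0.0, spec.mag_noise, mag.shape)

        node_samples: List[InertialSample] = []
        raw: List[RawSample] = []
        for i in range(n):
            s = InertialSample(t=float(t[i]), accel=accel[i], gyro=gyro[i], mag=mag[i])
            node_samples.append(s)
            raw.append(inertial_to_raw(s, table))
        inertial[node] = node_samples
        traces[node] = raw
        external_ref[node] = [Quaternion.from_array(q[i]).normalized() for i in range(n)]
        tilt = np.degrees(np.abs(tr.theta[node]))
        node_tilt[node] = tilt
        node_orient[node] = _truth_orientation_states(tilt, cfg)

    body_movement = [MOVING if m else STATIONARY for m in tr.moving["hip"]]
    body_orientation = [
        _derive_orientation(node_orient["chest"][i], node_orient["leg"][i]) for i in range(n)
    ]

    truth = GroundTruth(
        t=t,
        body_movement=body_movement,
        body_orientation=body_orientation,
        node_orientation=node_orient,
        node_tilt=node_tilt,
        step_times=np.array(sorted(tr.step_times)),
        fall_interval=meta.get("fall_interval"),
        fall_type=meta.get("fall_type"),
        expect_alert=meta.get("expect_alert"),
        expect_forwarded=meta.get("expect_forwarded", False),
        expected_candidates=tuple(meta.get("expected_candidates", ())),
        scenario=spec.scenario,
    )
    return SimResult(spec=spec, traces=traces, inertial=inertial, external_ref=external_ref, truth=truth)


def write_sim(out_dir, sim: SimResult) -> None:
    """Persist one simulated trial as plain-text files.

    Layout: ``<node>.csv`` + sidecars (raw traces), ``ref_<node>.csv``
    (external reference quaternions: t, qw, qx, qy, qz), ``truth.json``.
    """
    import pandas as pd
    from pathlib import Path

    from .sensor_model import write_trace_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = sim.truth.t
    for node in PLACEMENTS:
        write_trace_csv(out / f"{node}.csv", sim.traces[node], node, units="raw")
        rows = [[t[i], q.w, q.x, q.y, q.z] for i, q in enumerate(sim.external_ref[node])]
        pd.DataFrame(rows, columns=["t", "qw", "qx", "qy", "qz"]).to_csv(
            out / f"ref_{node}.csv", index=False
        )
    sim.truth.to_json(out / "truth.json")


def read_sim_inputs(in_dir):
    """Load the (traces, external_ref) pair written by :func:`write_sim`."""
    import pandas as pd
    from pathlib import Path

    from .sensor_model import read_trace_csv

    src = Path(in_dir)
    traces = {}
    external_ref = {}
    for node in PLACEMENTS:
        samples, placement, _ = read_trace_csv(src / f"{node}.csv")
        if placement != node:
            raise ValueError(f"trace {node}.csv declares placement {placement!r}")
        traces[node] = samples
        df = pd.read_csv(src / f"ref_{node}.csv")
        external_ref[node] = [
            Quaternion(float(r.qw), float(r.qx), float(r.qy), float(r.qz)).normalized()
            for r in df.itertuples(index=False)
        ]
    return traces, external_ref


# ---------------------------------------------------------------------------
# Profile building


def calibration_suite(seed: int = 1000, cfg: Optional[PipelineConfig] = None) -> List[SimResult]:
    """The default normal-ADL runs used to derive a user profile."""
    specs = [
        ScenarioSpec("stand_still", seed=seed),
        ScenarioSpec("walk_L", seed=seed + 1),
        ScenarioSpec("walk_cadence_change", cadence=1.8, seed=seed + 2),
        ScenarioSpec("sit_correct", seed=seed + 3),
    ]
    return [simulate_scenario(s, cfg) for s in specs]


def hampered_fall_suite(seed: int = 0) -> List[ScenarioSpec]:
    """Six hampered-fall variants; the last has a harmlessly small drop."""
    specs = [
        ScenarioSpec("fall_hampered", wall_contact=True, variant=v, seed=seed + v)
        for v in range(5)
    ]
    specs.append(
        ScenarioSpec(
            "fall_hampered", wall_contact=True, fall_distance=0.1, variant=5, seed=seed + 5
        )
    )
    return specs


_FALLBACK_INTERVALS = {
    "accel_mag": (0.5, 1.5),
    "tilt": (0.0, 60.0),
    "step_cadence": (0.5, 3.0),
    "step_force": (0.0, 2000.0),
}

#: Minimum half-widths so a constant quantity still yields a usable interval.
_INTERVAL_FLOORS = {
    "accel_mag": 0.05,
    "tilt": 4.0,
    "step_cadence": 0.1,
    "step_force": 50.0,
}


def make_profile(
    runs: Sequence[SimResult],
    k_sigma: float = 3.0,
    cfg: Optional[PipelineConfig] = None,
) -> UserProfile:
    """Derive per-user normal intervals (mean +- k_sigma * sd) from runs.

    The runs are pushed through fusion and per-node state evaluation, and
    the screened quantities are pooled per node across all runs.
    """
    from .pipeline import process_nodes  # deferred: pipeline imports synth types
    from .state_evaluator import SCREENED_QUANTITIES

    if len(runs) < 2:
        raise InsufficientDataError("profile building needs at least 2 calibration runs")
    cfg = cfg or PipelineConfig()
    base = UserProfile(
        height_m=runs[0].spec.height_m,
        weight_kg=runs[0].spec.weight_kg,
        amvd_gamma=cfg.amvd_gamma,
        amvd_window=cfg.amvd_window,
    )
    pooled: Dict[str, Dict[str, List[float]]] = {
        node: {q: [] for q in SCREENED_QUANTITIES[node]} for node in PLACEMENTS
    }
    for run in runs:
        node_results, _ = process_nodes(run.inertial, run.external_ref, base, cfg)
        for node, res in node_results.items():
            for s in res.inferred:
                if s.t < cfg.warmup_s:
                    continue
                for qname in SCREENED_QUANTITIES[node]:
                    val = s.quantity(qname)
                    if val is not None:
                        pooled[node][qname].append(val)

    intervals: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for node in PLACEMENTS:
        intervals[node] = {}
        for qname, values in pooled[node].items():
            if len(values) < 2:
                intervals[node][qname] = _FALLBACK_INTERVALS[qname]
                continue
            arr = np.asarray(values)
            mean, sd = float(arr.mean()), float(arr.std())
            half = max(k_sigma * sd, _INTERVAL_FLOORS[qname], cfg.interval_floor)
            intervals[node][qname] = (mean - half, mean + half)
    return replace(base, normal_intervals=intervals)
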