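"""Per-node state evaluation: kinematic inference and the movement /
orientation state machines.

Continuous quantities derived from each fused sample:

* dynamic acceleration ``a_dyn = a_prop - g`` (world frame, m/s^2),
* velocity by trapezoidal integration with zero-velocity updates at every
  stationary-labelled sample (the integral diverges otherwise),
* the moving-variance activity statistic (AMVD) of the acceleration
  magnitude, ``(1/N) sum_k (a_k - abar)^2`` compared against ``gamma``,
* step events from peak-to-peak excursions of |a_dyn| and the derived gait
  metrics (step length, walking distance, cadence, step force).

State machines: movement in {moving, stationary} driven by AMVD;
orientation in {vertical, horizontal} with per-user hysteresis bands on the
tilt angle (the state flips only when the tilt enters the *current* state's
transition interval).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import STANDARD_GRAVITY, PLACEMENTS, PipelineConfig
from .fusion import FusedSample
from .quatmath import Quaternion, quat_rotate_vector, tilt_deg
from .sensor_model import g_to_ms2

__all__ = [
    "MOVING",
    "STATIONARY",
    "VERTICAL",
    "HORIZONTAL",
    "SCREENED_QUANTITIES",
    "InferredSample",
    "NodeStates",
    "UserProfile",
    "StepEvent",
    "TransitionEvent",
    "NodeResult",
    "InsufficientDataError",
    "dynamic_acceleration",
    "integrate_velocity",
    "amvd",
    "amvd_stream",
    "detect_steps",
    "gait_metrics",
    "step_force",
    "update_orientation_state",
    "update_movement_state",
    "evaluate_node",
]

MOVING = "moving"
STATIONARY = "stationary"
VERTICAL = "vertical"
HORIZONTAL = "horizontal"

#: Quantities screened against profile intervals, per node placement.
SCREENED_QUANTITIES: Dict[str, Tuple[str, ...]] = {
    "chest": ("accel_mag", "tilt"),
    "hip": ("accel_mag", "tilt", "step_cadence"),
    "leg": ("accel_mag", "tilt", "step_force"),
}


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class InferredSample:
    """Derived quantities for one sample of one node."""

    t: float
    a_dyn: np.ndarray            # m/s^2, world frame
    v: np.ndarray                # m/s
    activity: float              # AMVD statistic, g^2
    accel_mag: float             # |proper accel|, g
    tilt: float                  # degrees from world vertical
    step_length: Optional[float] = None    # m, set at step impacts (hip)
    walk_distance: Optional[float] = None  # m, cumulative (hip)
    step_cadence: Optional[float] = None   # steps/s, set in established bouts
    step_force: Optional[float] = None     # N, set at step impacts (leg)

    def quantity(self, name: str) -> Optional[float]:
        """Look up a screened quantity by name; None when not applicable."""
        return getattr(self, name)


@dataclass(frozen=True)
class NodeStates:
    movement: str
    orientation: str

    def __post_init__(self) -> None:
        if self.movement not in (MOVING, STATIONARY):
            raise ValueError(f"bad movement state {self.movement!r}")
        if self.orientation not in (VERTICAL, HORIZONTAL):
            raise ValueError(f"bad orientation state {self.orientation!r}")


@dataclass(frozen=True)
class StepEvent:
    t_start: float
    t_impact: float
    peak_accel: float  # m/s^2, |a_dyn| at impact
    length: float = 0.0

    def __post_init__(self) -> None:
        if self.t_impact < self.t_start:
            raise ValueError("t_impact must be >= t_start")
        if self.peak_accel < 0:
            raise ValueError("peak_accel must be >= 0")


@dataclass(frozen=True)
class TransitionEvent:
    """One state-machine transition of one node (JSON-lines loggable)."""

    t: float
    node: str
    dimension: str  # "movement" or "orientation"
    from_state: str
    to_state: str


@dataclass
class UserProfile:
    """Physical characteristics plus per-user normal-value intervals.

    ``normal_intervals[node][quantity] = (lo, hi)`` holds the ranges used by
    the anomaly detector; ``transition_intervals[node][state]`` holds the
    tilt bands that trigger orientation-state changes.
    """

    height_m: float = 1.73
    weight_kg: float = 75.0
    transition_intervals: Dict[str, Dict[str, Tuple[float, float]]] = field(default_factory=dict)
    normal_intervals: Dict[str, Dict[str, Tuple[float, float]]] = field(default_factory=dict)
    amvd_gamma: float = 0.0013
    amvd_window: int = 20

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be > 0")
        for per_node in (self.transition_intervals, self.normal_intervals):
            for node, quantities in per_node.items():
                for name, (lo, hi) in quantities.items():
                    if not lo < hi:
                        raise ValueError(f"interval {node}/{name} must satisfy min < max")

    def transition_interval(self, node: str, state: str, cfg: PipelineConfig) -> Tuple[float, float]:
        default = cfg.vertical_transition if state == VERTICAL else cfg.horizontal_transition
        return self.transition_intervals.get(node, {}).get(state, default)

    def interval(self, node: str, quantity: str) -> Tuple[float, float]:
        try:
            return self.normal_intervals[node][quantity]
        except KeyError as exc:
            raise KeyError(f"profile has no interval for {node}/{quantity}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "UserProfile":
        data = json.loads(Path(path).read_text())
        for key in ("transition_intervals", "normal_intervals"):
            data[key] = {
                node: {q: tuple(iv) for q, iv in qs.items()}
                for node, qs in data.get(key, {}).items()
            }
        return cls(**data)


# ---------------------------------------------------------------------------
# Kinematic inference


def dynamic_acceleration(f: FusedSample) -> np.ndarray:
    """World-frame dynamic acceleration (m/s^2): rotate, drop gravity, scale."""
    a_world_g = quat_rotate_vector(f.q, f.accel)
    a_world_g[2] -= 1.0
    return g_to_ms2(a_world_g)


def integrate_velocity(
    a_dyn: np.ndarray, states: Sequence[str], dt: float
) -> np.ndarray:
    """Trapezoidal velocity with a zero-velocity update at stationary samples."""
    a = np.atleast_2d(np.asarray(a_dyn, dtype=float))
    n = a.shape[0]
    if len(states) != n:
        raise ValueError("a_dyn and states must be aligned")
    v = np.zeros_like(a)
    for i in range(1, n):
        if states[i] == STATIONARY:
            continue  # v stays 0 (ZUPT)
        v[i] = v[i - 1] + 0.5 * (a[i - 1] + a[i]) * dt
    return v


def amvd(window: Sequence[float], gamma: float, N: int) -> Tuple[float, bool]:
    """Moving-variance activity statistic over the last ``N`` magnitudes (g).

    Returns ``(statistic, moving)`` where ``moving`` is True when the
    statistic reaches the threshold ``gamma`` (below-threshold means
    stationary).
    """
    w = np.asarray(window, dtype=float)
    if w.shape[0] != N:
        raise InsufficientDataError(f"AMVD window needs exactly {N} values, got {w.shape[0]}")
    abar = w.mean()
    stat = float(np.mean((w - abar) ** 2))
    return stat, stat >= gamma


def amvd_stream(mags: np.ndarray, gamma: float, N: int) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample AMVD over a trailing window; the first N-1 samples (warm-up
    padding) are labelled stationary with statistic 0."""
    mags = np.asarray(mags, dtype=float)
    n = mags.shape[0]
    stats = np.zeros(n)
    moving = np.zeros(n, dtype=bool)
    if n >= N:
        # vectorized trailing-window variance
        csum = np.concatenate([[0.0], np.cumsum(mags)])
        csq = np.concatenate([[0.0], np.cumsum(mags**2)])
        s = csum[N:] - csum[:-N]
        sq = csq[N:] - csq[:-N]
        var = sq / N - (s / N) ** 2
        var = np.maximum(var, 0.0)
        stats[N - 1 :] = var
        moving[N - 1 :] = var >= gamma
    return stats, moving


def update_movement_state(amvd_moving: Sequence[bool]) -> List[str]:
    """Map the AMVD boolean stream one-to-one onto movement states."""
    return [MOVING if m else STATIONARY for m in amvd_moving]


def update_orientation_state(
    tilt: float, current: str, profile: UserProfile, node: str, cfg: Optional[PipelineConfig] = None
) -> str:
    """Hysteresis rule: flip only when the tilt enters the current state's
    transition interval."""
    if not 0.0 <= tilt <= 180.0:
        raise ValueError("tilt must be within [0, 180] degrees")
    cfg = cfg or PipelineConfig()
    lo, hi = profile.transition_interval(node, current, cfg)
    if lo <= tilt <= hi:
        return HORIZONTAL if current == VERTICAL else VERTICAL
    return current


def detect_steps(
    t: np.ndarray,
    adyn_vertical: np.ndarray,
    dt: float,
    moving: Optional[np.ndarray] = None,
    window_s: float = 1.0,
    p2p_threshold_g: float = 0.3,
    refractory_s: float = 0.25,
) -> List[StepEvent]:
    """Step events from peak-to-peak excursions of the vertical dynamic
    acceleration (m/s^2, signed — the magnitude rectifies the gait cycle
    and doubles the peak count).

    A sample qualifies as a step impact when (i) it is a local positive peak
    in the upper half of the current window's excursion, (ii) the window's
    peak-to-peak excursion exceeds the threshold, (iii) the refractory
    period since the previous step has elapsed, (iv) the node is in the
    moving state, and (v) the detector has re-armed — the signal dropped
    below the mid-excursion line since the previous step (otherwise ripple
    riding on a broad crest double-counts slow steps).
    """
    t = np.asarray(t, dtype=float)
    mag = np.asarray(adyn_vertical, dtype=float)
    n = mag.shape[0]
    if n == 0:
        return []
    if moving is None:
        moving = np.ones(n, dtype=bool)
    w = max(2, int(round(window_s / dt)))
    refr = max(1, int(round(refractory_s / dt)))
    thr = p2p_threshold_g * STANDARD_GRAVITY
    steps: List[StepEvent] = []
    last_idx = -(10 * n)
    armed = True
    for i in range(1, n - 1):
        if not moving[i]:
            continue
        lo = max(0, i - w + 1)
        win = mag[lo : i + 1]
        p2p = float(win.max() - win.min())
        if p2p < thr:
            continue
        mid = float(win.min()) + 0.5 * p2p
        if not armed and mag[i] < mid - 0.05 * p2p:
            armed = True
        if not (mag[i] >= mag[i - 1] and mag[i] > mag[i + 1]):
            continue
        if i - last_idx < refr or not armed:
            continue
        if mag[i] < mid:
            continue  # peak not in the upper half of the excursion
        t_start = t[last_idx] if steps and last_idx >= 0 else t[lo]
        steps.append(
            StepEvent(t_start=float(t_start), t_impact=float(t[i]), peak_accel=float(max(mag[i], 0.0)))
        )
        last_idx = i
        armed = False
    return steps


def gait_metrics(
    steps: Sequence[StepEvent],
    v_mag: np.ndarray,
    t: np.ndarray,
    bout: Tuple[float, float],
    dt: float,
) -> Tuple[List[float], float, float]:
    """(per-step lengths, walking distance, cadence) for one walking bout.

    Step length integrates |v| over the step's duration; the walking
    distance adds the step lengths; cadence is steps per bout duration.
    """
    t0, t1 = bout
    if t1 <= t0:
        raise ValueError("bout duration must be positive")
    t = np.asarray(t, dtype=float)
    v_mag = np.asarray(v_mag, dtype=float)
    lengths: List[float] = []
    for s in steps:
        mask = (t >= s.t_start) & (t <= s.t_impact)
        if mask.sum() >= 2:
            lengths.append(float(np.trapezoid(v_mag[mask], t[mask])))
        else:
            lengths.append(0.0)
    distance = float(sum(lengths))
    cadence = len(steps) / (t1 - t0)
    return lengths, distance, cadence


def step_force(weight_kg: float, peak_accel: float) -> float:
    """Impact force: user mass times the step's acceleration peak."""
    if weight_kg <= 0:
        raise ValueError("weight must be > 0")
    return weight_kg * peak_accel


# ---------------------------------------------------------------------------
# Node-level orchestration


@dataclass
class NodeResult:
    """Everything the downstream stages need from one node's trace."""

    node: str
    t: np.ndarray
    inferred: List[InferredSample]
    movement: List[str]
    orientation: List[str]
    transitions: List[TransitionEvent]
    steps: List[StepEvent]
    bouts: List[Tuple[float, float]]

    def states(self, i: int) -> NodeStates:
        return NodeStates(movement=self.movement[i], orientation=self.orientation[i])


def _moving_bouts(t: np.ndarray, moving: Sequence[bool]) -> List[Tuple[int, int]]:
    """Index ranges [i0, i1) of contiguous moving segments."""
    bouts = []
    start = None
    for i, m in enumerate(moving):
        if m and start is None:
            start = i
        elif not m and start is not None:
            bouts.append((start, i))
            start = None
    if start is not None:
        bouts.append((start, len(moving)))
    return bouts


def evaluate_node(
    fused: Sequence[FusedSample],
    profile: UserProfile,
    node: str,
    cfg: Optional[PipelineConfig] = None,
) -> NodeResult:
    """Run the full per-node evaluation over a fused stream."""
    if node not in PLACEMENTS:
        raise ValueError(f"unknown node placement {node!r}")
    cfg = cfg or PipelineConfig()
    n = len(fused)
    t = np.array([f.t for f in fused])
    accel_mag = np.array([float(np.linalg.norm(f.accel)) for f in fused])
    tilts = np.array([tilt_deg(f.q) for f in fused])

    stats, moving_flags = amvd_stream(accel_mag, profile.amvd_gamma, profile.amvd_window)
    movement = update_movement_state(moving_flags)

    orientation: List[str] = []
    state = VERTICAL
    for tv in tilts:
        state = update_orientation_state(float(tv), state, profile, node, cfg)
        orientation.append(state)

    a_dyn = np.array([dynamic_acceleration(f) for f in fused]) if n else np.zeros((0, 3))
    v = integrate_velocity(a_dyn, movement, cfg.dt) if n else np.zeros((0, 3))
    v_mag = np.linalg.norm(v, axis=1) if n else np.zeros(0)

    transitions: List[TransitionEvent] = []
    for i in range(1, n):
        if movement[i] != movement[i - 1]:
            transitions.append(TransitionEvent(float(t[i]), node, "movement", movement[i - 1], movement[i]))
        if orientation[i] != orientation[i - 1]:
            transitions.append(TransitionEvent(float(t[i]), node, "orientation", orientation[i - 1], orientation[i]))

    # Gait metrics on the locomotion-bearing nodes; brief AMVD drop-outs
    # inside a walking bout are bridged so the cadence clock keeps running
    steps: List[StepEvent] = []
    bouts_idx = _moving_bouts(t, moving_flags) if node in ("hip", "leg") else []
    merged: List[Tuple[int, int]] = []
    for i0, i1 in bouts_idx:
        if merged and t[i0] - t[merged[-1][1] - 1] < cfg.bout_merge_gap_s:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    bouts_idx = merged
    bouts = [(float(t[i0]), float(t[i1 - 1])) for i0, i1 in bouts_idx]
    step_length_arr: List[Optional[float]] = [None] * n
    walk_distance_arr: List[Optional[float]] = [None] * n
    cadence_arr: List[Optional[float]] = [None] * n
    force_arr: List[Optional[float]] = [None] * n

    total_distance = 0.0
    for (i0, i1), (bt0, bt1) in zip(bouts_idx, bouts):
        # gait metrics only make sense on an established walking bout;
        # short motion bursts (posture transitions, falls) are skipped
        if bt1 - bt0 < cfg.min_cadence_bout_s or i1 - i0 < 2:
            continue
        bout_moving = np.zeros(n, dtype=bool)
        bout_moving[i0:i1] = True
        bout_steps = detect_steps(
            t,
            a_dyn[:, 2],
            cfg.dt,
            moving=bout_moving,
            window_s=cfg.step_window_s,
            p2p_threshold_g=cfg.step_p2p_threshold_g,
            refractory_s=cfg.step_refractory_s,
        )
        if not bout_steps:
            continue
        lengths, distance, _ = gait_metrics(bout_steps, v_mag, t, (bt0, bt1), cfg.dt)
        bout_steps = [
            StepEvent(s.t_start, s.t_impact, s.peak_accel, length=l)
            for s, l in zip(bout_steps, lengths)
        ]
        steps.extend(bout_steps)
        for s in bout_steps:
            idx = int(np.searchsorted(t, s.t_impact))
            idx = min(idx, n - 1)
            total_distance += s.length
            if node == "hip":
                step_length_arr[idx] = s.length
                walk_distance_arr[idx] = total_distance
            if node == "leg":
                force_arr[idx] = step_force(profile.weight_kg, s.peak_accel)
        if node == "hip":
            # running cadence once the bout is established
            impacts = np.array([s.t_impact for s in bout_steps])
            for i in range(i0, i1):
                elapsed = t[i] - bt0
                k = int(np.searchsorted(impacts, t[i], side="right"))
                if elapsed >= cfg.min_cadence_bout_s and k >= cfg.min_cadence_steps:
                    cadence_arr[i] = k / elapsed

    inferred = [
        InferredSample(
            t=float(t[i]),
            a_dyn=a_dyn[i],
            v=v[i],
            activity=float(stats[i]),
            accel_mag=float(accel_mag[i]),
            tilt=float(tilts[i]),
            step_length=step_length_arr[i],
            walk_distance=walk_distance_arr[i],
            step_cadence=cadence_arr[i],
            step_force=force_arr[i],
        )
        for i in range(n)
    ]
    return NodeResult(
        node=node,
        t=t,
        inferred=inferred,
        movement=movement,
        orientation=orientation,
        transitions=transitions,
        steps=steps,
        bouts=bouts,
    )
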