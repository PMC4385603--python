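"""Two-stage anomaly handling: per-node interval screening and full-body
validation with server escalation.

Screening is deliberately light — any sample whose screened quantity falls
outside the user's normal interval becomes a candidate; the intervals are
used as-is because they already carry the per-user tolerance.

Validation consults the other nodes and the body-state timeline:

a. the same quantity above its interval on two or more nodes in the same
   window confirms the anomaly (two or more high values from different
   sources);
b. a single-node acceleration event followed by a full window of body
   movement is rejected (the user kept moving);
c. an acceleration event followed by a lying orientation — or a seated one
   with an out-of-interval chest inclination — is confirmed;
d. an acceleration event that resembles a sit-down (final orientation
   consistent with normal sitting) is rejected but the data is still
   forwarded to the server; a subject still upright at the horizon likewise
   rejects the event;
e. anything else stays pending for one more sampling period, after which
   continued immobility escalates to the server (so hampered falls without
   a decisive impact are never silently dropped) and resumed movement
   rejects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .body_state import LYING, SEATED, STANDING, BodyStateTimeline
from .config import PipelineConfig
from .state_evaluator import (
    MOVING,
    STATIONARY,
    SCREENED_QUANTITIES,
    InferredSample,
    UserProfile,
)

__all__ = [
    "CONFIRMED",
    "REJECTED",
    "PENDING",
    "ESCALATED",
    "AnomalyCandidate",
    "ValidationResult",
    "ConfigurationError",
    "detect_anomalies",
    "validate_anomaly",
    "resolve_pending",
]

CONFIRMED = "confirmed"
REJECTED = "rejected"
PENDING = "pending"
ESCALATED = "escalated"


class ConfigurationError(RuntimeError):
    """Profile lacks an interval for a screened quantity."""


@dataclass(frozen=True)
class AnomalyCandidate:
    t: float
    node: str
    quantity: str
    value: float
    interval: Tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if lo <= self.value <= hi:
            raise ValueError("candidate value must lie outside its interval")


@dataclass
class ValidationResult:
    decision: str
    t_decided: float
    window: Tuple[float, float]
    evidence: Dict[str, object] = field(default_factory=dict)
    forwarded: bool = False
    deadline: Optional[float] = None
    extensions: int = 0
    candidates: Tuple[AnomalyCandidate, ...] = ()


def detect_anomalies(
    samples: Sequence[InferredSample], profile: UserProfile, node: str
) -> List[AnomalyCandidate]:
    """One candidate per (sample, screened quantity) outside its interval."""
    out: List[AnomalyCandidate] = []
    for qname in SCREENED_QUANTITIES[node]:
        try:
            lo, hi = profile.interval(node, qname)
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        for s in samples:
            val = s.quantity(qname)
            if val is None:
                continue
            if not lo <= val <= hi:
                out.append(AnomalyCandidate(t=s.t, node=node, quantity=qname, value=val, interval=(lo, hi)))
    out.sort(key=lambda c: (c.t, c.node, c.quantity))
    return out


def _out_of_interval(
    peers: Mapping[str, Sequence[InferredSample]],
    profile: UserProfile,
    t0: float,
    t1: float,
) -> Dict[str, Dict[str, float]]:
    """Worst out-of-interval value per (node, quantity) within [t0, t1]."""
    out: Dict[str, Dict[str, float]] = {}
    for node, samples in peers.items():
        for qname in SCREENED_QUANTITIES[node]:
            lo, hi = profile.interval(node, qname)
            worst = None
            for s in samples:
                if not t0 <= s.t <= t1:
                    continue
                val = s.quantity(qname)
                if val is None or lo <= val <= hi:
                    continue
                dev = max(lo - val, val - hi)
                if worst is None or dev > worst[1]:
                    worst = (val, dev)
            if worst is not None:
                out.setdefault(node, {})[qname] = worst[0]
    return out


def _chest_tilt_abnormal(
    peers: Mapping[str, Sequence[InferredSample]],
    profile: UserProfile,
    around_t: float,
    halfwidth: float = 0.3,
) -> Optional[bool]:
    lo, hi = profile.interval("chest", "tilt")
    vals = [
        s.tilt for s in peers.get("chest", []) if abs(s.t - around_t) <= halfwidth
    ]
    if not vals:
        return None
    mean = sum(vals) / len(vals)
    return not lo <= mean <= hi


def validate_anomaly(
    c: AnomalyCandidate,
    peers: Mapping[str, Sequence[InferredSample]],
    body: BodyStateTimeline,
    profile: UserProfile,
    cfg: Optional[PipelineConfig] = None,
    window: Optional[Tuple[float, float]] = None,
) -> ValidationResult:
    """Decide on one candidate using all three nodes and the body state.

    ``peers`` must cover the candidate's window plus the look-ahead horizon
    for every node; missing nodes leave the result pending with a data
    request noted in the evidence.
    """
    cfg = cfg or PipelineConfig()
    batch_dur = cfg.batch_size * cfg.dt
    if window is None:
        k = int(c.t // batch_dur)
        window = (k * batch_dur, (k + 1) * batch_dur)
    t0, t1 = window

    missing = [n for n in SCREENED_QUANTITIES if n not in peers or not peers[n]]
    if missing:
        return ValidationResult(
            decision=PENDING,
            t_decided=t1,
            window=window,
            deadline=t1 + batch_dur,
            evidence={"missing_nodes": missing},
            candidates=(c,),
        )

    out = _out_of_interval(peers, profile, t0, t1)
    evidence: Dict[str, object] = {"out_of_interval": out}

    # (a) agreement between sources: the same quantity *above* its normal
    # interval on two or more nodes ("two or more high values")
    high_by_quantity: Dict[str, List[str]] = {}
    for node, qs in out.items():
        for qname, val in qs.items():
            if val > profile.interval(node, qname)[1]:
                high_by_quantity.setdefault(qname, []).append(node)
    for qname, nodes in sorted(high_by_quantity.items()):
        if len(nodes) >= 2:
            evidence["rule"] = "multi_source"
            evidence["quantity"] = qname
            evidence["nodes"] = sorted(nodes)
            return ValidationResult(CONFIRMED, t1, window, evidence, candidates=(c,))

    accel_event = any("accel_mag" in qs for qs in out.values())
    out_quantities = {qname for qs in out.values() for qname in qs}
    if not accel_event and out_quantities and out_quantities <= {"step_cadence", "step_force"}:
        # gait-statistic deviations alone cannot indicate a fall or posture
        # problem; they are logged but never escalate
        evidence["rule"] = "gait_only"
        return ValidationResult(REJECTED, t1, window, evidence, candidates=(c,))
    te = t1
    horizon = te + cfg.lookahead_s
    movement = body.movement_in(te, horizon)
    orients = body.orientations_in(te, horizon)
    end_state = body.state_at(horizon)
    evidence["body"] = {
        "movement": movement,
        "orientations": orients,
        "end_orientation": end_state.orientation,
    }

    if accel_event:
        if movement == [MOVING]:
            evidence["rule"] = "kept_moving"
            return ValidationResult(REJECTED, horizon, window, evidence, candidates=(c,))
        if LYING in orients:
            evidence["rule"] = "impact_then_lying"
            return ValidationResult(CONFIRMED, horizon, window, evidence, candidates=(c,))
        if end_state.orientation == SEATED:
            abnormal = _chest_tilt_abnormal(peers, profile, horizon)
            if abnormal:
                evidence["rule"] = "impact_then_bad_sitting"
                return ValidationResult(CONFIRMED, horizon, window, evidence, candidates=(c,))
            if abnormal is False:
                evidence["rule"] = "sit_down_like"
                return ValidationResult(
                    REJECTED, horizon, window, evidence, forwarded=True, candidates=(c,)
                )
        if end_state.orientation == STANDING:
            # the subject is upright at the horizon: whatever the excursion
            # was, it did not put them down
            evidence["rule"] = "still_standing"
            return ValidationResult(REJECTED, horizon, window, evidence, candidates=(c,))

    evidence["rule"] = "inconclusive"
    return ValidationResult(
        PENDING, t1, window, evidence, deadline=t1 + batch_dur, candidates=(c,)
    )


def resolve_pending(
    p: ValidationResult,
    peers: Mapping[str, Sequence[InferredSample]],
    body: BodyStateTimeline,
    profile: UserProfile,
    cfg: Optional[PipelineConfig] = None,
) -> ValidationResult:
    """Resolve a pending result after one more sampling period.

    Continued immobility escalates to the server (data only); otherwise the
    decision is re-run on the union window.  At most one extension is
    allowed — a still-inconclusive re-run terminates as escalated (if the
    user ended up immobile) or rejected.
    """
    if p.decision != PENDING:
        raise ValueError("resolve_pending requires a pending result")
    cfg = cfg or PipelineConfig()
    batch_dur = cfg.batch_size * cfg.dt
    deadline = p.deadline if p.deadline is not None else p.window[1] + batch_dur

    movement = body.movement_in(p.window[1], deadline)
    if movement == [STATIONARY]:
        return replace(
            p,
            decision=ESCALATED,
            t_decided=deadline,
            evidence={**p.evidence, "rule": "no_movement_followup"},
            extensions=p.extensions + 1,
        )

    if not p.candidates:
        return replace(
            p,
            decision=REJECTED,
            t_decided=deadline,
            evidence={**p.evidence, "rule": "forced_terminal"},
            extensions=p.extensions + 1,
        )
    union = (p.window[0], deadline)
    res = validate_anomaly(p.candidates[0], peers, body, profile, cfg, window=union)
    res = replace(res, extensions=p.extensions + 1, candidates=p.candidates)
    if res.decision == PENDING:
        end_movement = body.state_at(deadline + cfg.lookahead_s).movement
        final = ESCALATED if end_movement == STATIONARY else REJECTED
        res = replace(
            res,
            decision=final,
            t_decided=deadline + cfg.lookahead_s,
            deadline=None,
            evidence={**res.evidence, "rule": "forced_terminal"},
        )
    return res
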