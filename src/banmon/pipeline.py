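"""End-to-end trial orchestration and the evaluation harness.

The data-flow is the batch-synchronous equivalent of the agent message
chain: fusion -> per-node state evaluation -> {body-state fusion, per-node
anomaly screening} -> full-body validation -> server events.  Stages run
sequentially per trial; the event log is deterministic for a fixed input
and configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .anomaly import (
    CONFIRMED,
    ESCALATED,
    PENDING,
    AnomalyCandidate,
    ValidationResult,
    detect_anomalies,
    resolve_pending,
    validate_anomaly,
)
from .body_state import BodyStateTimeline
from .config import PLACEMENTS, PipelineConfig
from .fusion import FilterParams, capture_calibration, fuse_stream
from .quatmath import Calibration, Quaternion
from .sensor_model import (
    ConversionTable,
    InertialSample,
    RawSample,
    default_conversion_table,
    raw_to_inertial,
)
from .state_evaluator import (
    MOVING,
    STATIONARY,
    InferredSample,
    NodeResult,
    UserProfile,
    evaluate_node,
)
from .synth import GroundTruth, SimResult

__all__ = [
    "EventRecord",
    "EventLog",
    "TrialResult",
    "TrialMetrics",
    "AlignmentError",
    "process_nodes",
    "run_trial",
    "run_sim_trial",
    "recognition_correct",
    "evaluate",
]

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Node trace timebases differ by more than one sample."""


@dataclass(frozen=True)
class EventRecord:
    t: float
    stage: str
    kind: str
    payload: Dict[str, object]


STAGES = (
    "data_processor",
    "state_evaluator",
    "body_state_evaluator",
    "anomaly_detector",
    "anomaly_validator",
    "server",
)


@dataclass
class EventLog:
    records: List[EventRecord] = field(default_factory=list)

    def append(self, t: float, stage: str, kind: str, **payload: object) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.records.append(EventRecord(t=float(t), stage=stage, kind=kind, payload=payload))

    def of_kind(self, kind: str) -> List[EventRecord]:
        return [r for r in self.records if r.kind == kind]

    def finalize(self) -> None:
        self.records.sort(key=lambda r: (r.t, STAGES.index(r.stage)))

    def to_json_lines(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    json.dumps({"t": r.t, "stage": r.stage, "kind": r.kind, **r.payload}) + "\n"
                )


@dataclass
class TrialResult:
    """Event log plus the intermediate artefacts of one trial."""

    log: EventLog
    node_results: Dict[str, NodeResult] = field(default_factory=dict)
    calibrations: Dict[str, Calibration] = field(default_factory=dict)
    body: Optional[BodyStateTimeline] = None
    candidates: List[AnomalyCandidate] = field(default_factory=list)
    decisions: List[ValidationResult] = field(default_factory=list)
    scenario: Optional[str] = None

    @property
    def alerts(self) -> List[ValidationResult]:
        return [d for d in self.decisions if d.decision in (CONFIRMED, ESCALATED)]

    @property
    def detected(self) -> bool:
        return len(self.alerts) > 0


def process_nodes(
    inertial: Mapping[str, Sequence[InertialSample]],
    external_ref: Mapping[str, Sequence[Quaternion]],
    profile: UserProfile,
    cfg: PipelineConfig,
) -> Tuple[Dict[str, NodeResult], Dict[str, Calibration]]:
    """Calibrate, fuse and state-evaluate every node stream."""
    params = FilterParams(beta=cfg.beta, dt=cfg.dt)
    node_results: Dict[str, NodeResult] = {}
    calibrations: Dict[str, Calibration] = {}
    for node, samples in inertial.items():
        m = min(cfg.calibration_samples, len(samples), len(external_ref[node]))
        warm = fuse_stream(samples[:m], params)
        cal = capture_calibration([f.q for f in warm], list(external_ref[node])[:m])
        calibrations[node] = cal
        fused = fuse_stream(samples, params, cal=cal, invert_rotation=cfg.invert_rotation)
        node_results[node] = evaluate_node(fused, profile, node, cfg)
    return node_results, calibrations


def _check_alignment(inertial: Mapping[str, Sequence[InertialSample]], cfg: PipelineConfig) -> None:
    lengths = {node: len(s) for node, s in inertial.items()}
    if len(set(lengths.values())) != 1:
        raise AlignmentError(f"node trace lengths differ: {lengths}")
    ref = np.array([s.t for s in next(iter(inertial.values()))])
    for node, samples in inertial.items():
        t = np.array([s.t for s in samples])
        if np.max(np.abs(t - ref)) > cfg.dt:
            raise AlignmentError(f"timebase of node {node} misaligned beyond one sample")


def run_trial(
    traces: Mapping[str, Sequence[RawSample] | Sequence[InertialSample]],
    external_ref: Mapping[str, Sequence[Quaternion]],
    profile: UserProfile,
    cfg: Optional[PipelineConfig] = None,
    table: Optional[ConversionTable] = None,
    scenario: Optional[str] = None,
) -> TrialResult:
    """Execute the full pipeline on one three-node trial."""
    cfg = cfg or PipelineConfig()
    table = table or default_conversion_table()

    missing = [p for p in PLACEMENTS if p not in traces]
    if missing:
        raise AlignmentError(f"missing node traces: {missing}")
    if all(len(s) == 0 for s in traces.values()):
        warnings.warn("empty traces; returning empty event log")
        return TrialResult(log=EventLog(), scenario=scenario)

    inertial: Dict[str, List[InertialSample]] = {}
    for node, samples in traces.items():
        if samples and isinstance(samples[0], RawSample):
            inertial[node] = [raw_to_inertial(r, table) for r in samples]
        else:
            inertial[node] = list(samples)
    _check_alignment(inertial, cfg)

    log = EventLog()
    node_results, calibrations = process_nodes(inertial, external_ref, profile, cfg)

    # Per-node state transitions (post warm-up) drive the body state
    transitions = []
    for node, res in node_results.items():
        for ev in res.transitions:
            if ev.t < cfg.warmup_s:
                continue
            transitions.append(ev)
            log.append(
                ev.t,
                "state_evaluator",
                "state_transition",
                node=ev.node,
                dimension=ev.dimension,
                from_state=ev.from_state,
                to_state=ev.to_state,
            )
    body = BodyStateTimeline(transitions)
    for tr in body.transitions:
        log.append(tr["t"], "body_state_evaluator", "body_transition", **{
            k: v for k, v in tr.items() if k != "t"
        })

    # Per-node anomaly screening
    candidates: List[AnomalyCandidate] = []
    for node, res in node_results.items():
        post = [s for s in res.inferred if s.t >= cfg.warmup_s]
        found = detect_anomalies(post, profile, node)
        candidates.extend(found)
        for c in found:
            log.append(
                c.t,
                "anomaly_detector",
                "anomaly_candidate",
                node=c.node,
                quantity=c.quantity,
                value=c.value,
                interval=list(c.interval),
            )

    # Full-body validation, one decision per batch window with candidates
    batch_dur = cfg.batch_size * cfg.dt
    by_batch: Dict[int, List[AnomalyCandidate]] = {}
    for c in candidates:
        by_batch.setdefault(int(c.t // batch_dur), []).append(c)

    decisions: List[ValidationResult] = []
    for k in sorted(by_batch):
        window = (k * batch_dur, (k + 1) * batch_dur)
        horizon = window[1] + cfg.lookahead_s + 2 * batch_dur
        peers = {
            node: [s for s in res.inferred if window[0] - batch_dur <= s.t <= horizon]
            for node, res in node_results.items()
        }
        rep = by_batch[k][0]
        if len(by_batch[k]) < cfg.min_cluster:
            # anomalies not maintained for more than a few samples trigger no
            # node-to-node communication
            result = ValidationResult(
                decision="rejected",
                t_decided=window[1],
                window=window,
                evidence={"rule": "transient"},
                candidates=tuple(by_batch[k]),
            )
        else:
            result = validate_anomaly(rep, peers, body, profile, cfg, window=window)
            if result.decision == PENDING:
                result = resolve_pending(result, peers, body, profile, cfg)
        result.evidence["n_candidates"] = len(by_batch[k])
        decisions.append(result)
        log.append(
            result.t_decided,
            "anomaly_validator",
            "validation",
            decision=result.decision,
            window=list(result.window),
            rule=result.evidence.get("rule"),
            n_candidates=len(by_batch[k]),
            forwarded=result.forwarded,
        )
        if result.decision in (CONFIRMED, ESCALATED):
            log.append(
                result.t_decided,
                "server",
                "server_alert",
                decision=result.decision,
                window=list(result.window),
            )
        elif result.forwarded:
            log.append(
                result.t_decided,
                "server",
                "server_data",
                window=list(result.window),
            )

    log.finalize()
    return TrialResult(
        log=log,
        node_results=node_results,
        calibrations=calibrations,
        body=body,
        candidates=candidates,
        decisions=decisions,
        scenario=scenario,
    )


def run_sim_trial(
    sim: SimResult, profile: UserProfile, cfg: Optional[PipelineConfig] = None
) -> TrialResult:
    """Convenience wrapper: run a simulated trial through the pipeline."""
    return run_trial(
        sim.traces,
        sim.external_ref,
        profile,
        cfg=cfg,
        scenario=sim.spec.scenario,
    )


# ---------------------------------------------------------------------------
# Evaluation harness


def _state_match_fraction(
    predicted_at,
    truth_states: Sequence[str],
    t: np.ndarray,
    cfg: PipelineConfig,
    tol_s: float = 0.5,
) -> float:
    """Fraction of post-warm-up samples whose predicted state matches the
    truth at some instant within ±tol_s (transition-lag tolerance)."""
    k = int(round(tol_s / cfg.dt))
    n = len(truth_states)
    idx = [i for i in range(n) if t[i] >= cfg.warmup_s]
    if not idx:
        return 1.0
    good = 0
    for i in idx:
        pred = predicted_at(float(t[i]))
        lo, hi = max(0, i - k), min(n, i + k + 1)
        if any(pred == truth_states[j] for j in range(lo, hi)):
            good += 1
    return good / len(idx)


def recognition_correct(
    result: TrialResult, truth: GroundTruth, cfg: Optional[PipelineConfig] = None
) -> bool:
    """Did the pipeline recognise this trial correctly?

    Requires (i) >= 95% agreement of body movement and orientation with the
    ground truth (with half-second transition tolerance), (ii) the presence
    or absence of a server alert matching the expectation when one is
    stated, and (iii) every expected candidate quantity actually flagged.
    """
    cfg = cfg or PipelineConfig()
    body = result.body
    if body is None:
        return False
    move_frac = _state_match_fraction(
        lambda tt: body.state_at(tt).movement, truth.body_movement, truth.t, cfg
    )
    orient_frac = _state_match_fraction(
        lambda tt: body.state_at(tt).orientation, truth.body_orientation, truth.t, cfg
    )
    if move_frac < 0.95 or orient_frac < 0.95:
        return False
    if truth.expect_alert is not None and result.detected != truth.expect_alert:
        return False
    flagged = {c.quantity for c in result.candidates}
    if any(q not in flagged for q in truth.expected_candidates):
        return False
    return True


@dataclass
class TrialMetrics:
    """Aggregate recognition/fall metrics over a trial set."""

    recognition_accuracy: Dict[str, float]       # % per scenario
    fall_accuracy: Optional[float]               # % of fall trials detected
    false_state_changes: float                   # per trial (node level)
    internal_false_anomalies: float              # rejected decisions per trial
    false_anomalies_adl: float                   # rejected decisions per ADL trial
    false_anomalies_resting: float               # candidates per rest trial
    events_per_accident: Optional[float]         # server contacts per fall trial

    def __post_init__(self) -> None:
        for v in self.recognition_accuracy.values():
            if not 0.0 <= v <= 100.0:
                raise ValueError("accuracy must be within [0, 100]")


def _count_immediate_reverts(states: Sequence[str]) -> int:
    n = len(states)
    return sum(
        1
        for i in range(1, n - 1)
        if states[i] != states[i - 1] and states[i + 1] == states[i - 1]
    )


def evaluate(
    results: Sequence[TrialResult],
    truths: Sequence[GroundTruth],
    cfg: Optional[PipelineConfig] = None,
) -> TrialMetrics:
    """Score a trial set against its ground truths."""
    if len(results) != len(truths):
        raise ValueError("one truth per result is required")
    cfg = cfg or PipelineConfig()

    per_scenario: Dict[str, List[bool]] = {}
    fall_hits: List[bool] = []
    reverts: List[int] = []
    rejected_counts: List[int] = []
    adl_rejected: List[int] = []
    resting_candidates: List[int] = []
    accident_events: List[int] = []

    for res, truth in zip(results, truths):
        scenario = res.scenario or "unknown"
        per_scenario.setdefault(scenario, []).append(recognition_correct(res, truth, cfg))
        n_rejected = sum(1 for d in res.decisions if d.decision == "rejected")
        rejected_counts.append(n_rejected)
        if truth.fall_type is not None:
            # every fall trial counts; an undetected harmless fall is still a
            # miss in the detection-rate denominator
            fall_hits.append(res.detected)
            accident_events.append(
                len(res.log.of_kind("server_alert")) + len(res.log.of_kind("server_data"))
            )
        else:
            adl_rejected.append(n_rejected)
        if scenario == "rest":
            resting_candidates.append(len(res.candidates))
        total = 0
        for nr in res.node_results.values():
            total += _count_immediate_reverts(nr.movement) + _count_immediate_reverts(nr.orientation)
        reverts.append(total)

    return TrialMetrics(
        recognition_accuracy={
            s: 100.0 * sum(v) / len(v) for s, v in per_scenario.items()
        },
        fall_accuracy=(100.0 * sum(fall_hits) / len(fall_hits)) if fall_hits else None,
        false_state_changes=float(np.mean(reverts)) if reverts else 0.0,
        internal_false_anomalies=float(np.mean(rejected_counts)) if rejected_counts else 0.0,
        false_anomalies_adl=float(np.mean(adl_rejected)) if adl_rejected else 0.0,
        false_anomalies_resting=float(np.mean(resting_candidates)) if resting_candidates else 0.0,
        events_per_accident=float(np.mean(accident_events)) if accident_events else None,
    )
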