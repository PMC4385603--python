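"""Full-body state fusion from per-node state reports.

Movement: the body mirrors the hip node only.  Orientation: when the leg
is horizontal the body is lying if the last chest report was horizontal,
seated otherwise; a vertical leg means standing.  Hip orientation reports
only refresh the stored report.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .state_evaluator import (
    HORIZONTAL,
    MOVING,
    STATIONARY,
    VERTICAL,
    TransitionEvent,
)

__all__ = ["STANDING", "LYING", "SEATED", "BodyState", "BodyStateTracker", "BodyStateTimeline"]

logger = logging.getLogger(__name__)

STANDING = "standing"
LYING = "lying"
SEATED = "seated"


@dataclass(frozen=True)
class BodyState:
    movement: str = STATIONARY
    orientation: str = STANDING
    node_orientation: Tuple[Tuple[str, str, float], ...] = ()  # (node, state, t)

    def __post_init__(self) -> None:
        if self.orientation not in (STANDING, LYING, SEATED):
            raise ValueError(f"bad body orientation {self.orientation!r}")
        if self.movement not in (MOVING, STATIONARY):
            raise ValueError(f"bad body movement {self.movement!r}")


def _derive_orientation(chest: str, leg: str) -> str:
    if leg == VERTICAL:
        return STANDING
    return LYING if chest == HORIZONTAL else SEATED


class BodyStateTracker:
    """Replays node state reports into a body-state timeline.

    The body orientation is a pure function of the last (chest, leg)
    orientation pair, so replay order of interleaved hip reports cannot
    change it.
    """

    def __init__(self, initial: Optional[BodyState] = None) -> None:
        self.state = initial or BodyState()
        self._last: Dict[str, Tuple[str, float]] = {
            "chest": (VERTICAL, 0.0),
            "hip": (VERTICAL, 0.0),
            "leg": (VERTICAL, 0.0),
        }
        self.transitions: List[dict] = []

    def _log(self, t: float, dimension: str, old: str, new: str, source: TransitionEvent) -> None:
        self.transitions.append(
            {
                "t": t,
                "dimension": dimension,
                "from": old,
                "to": new,
                "trigger_node": source.node,
                "trigger": f"{source.dimension}:{source.from_state}->{source.to_state}",
            }
        )

    def update_body_movement(self, change: TransitionEvent) -> BodyState:
        """Body movement follows hip movement changes; others are ignored."""
        if change.node != "hip":
            logger.info("movement change from %s ignored (hip-only rule)", change.node)
            return self.state
        old = self.state.movement
        if change.to_state != old:
            self.state = replace(self.state, movement=change.to_state)
            self._log(change.t, "movement", old, change.to_state, change)
        return self.state

    def update_body_orientation(self, change: TransitionEvent) -> BodyState:
        """Recompute body orientation from the stored (chest, leg) pair."""
        self._last[change.node] = (change.to_state, change.t)
        chest, _ = self._last["chest"]
        leg, _ = self._last["leg"]
        new = _derive_orientation(chest, leg)
        old = self.state.orientation
        if new != old:
            self.state = replace(
                self.state,
                orientation=new,
                node_orientation=tuple((n, s, tt) for n, (s, tt) in self._last.items()),
            )
            self._log(change.t, "orientation", old, new, change)
        return self.state

    def apply(self, change: TransitionEvent) -> BodyState:
        if change.dimension == "movement":
            return self.update_body_movement(change)
        if change.dimension == "orientation":
            return self.update_body_orientation(change)
        raise ValueError(f"unknown transition dimension {change.dimension!r}")


class BodyStateTimeline:
    """Time-indexed view over the tracked body state ("supply state" service)."""

    def __init__(self, transitions: List[TransitionEvent], initial: Optional[BodyState] = None):
        tracker = BodyStateTracker(initial)
        self._times: List[float] = [float("-inf")]
        self._states: List[BodyState] = [tracker.state]
        for ev in sorted(transitions, key=lambda e: e.t):
            before = tracker.state
            after = tracker.apply(ev)
            if after != before:
                self._times.append(ev.t)
                self._states.append(after)
        self.transitions = tracker.transitions

    def state_at(self, t: float) -> BodyState:
        idx = bisect.bisect_right(self._times, t) - 1
        return self._states[max(idx, 0)]

    def movement_in(self, t0: float, t1: float) -> List[str]:
        """Distinct movement states holding anywhere in [t0, t1]."""
        out = {self.state_at(t0).movement}
        for tt, st in zip(self._times, self._states):
            if t0 < tt <= t1:
                out.add(st.movement)
        return sorted(out)

    def orientations_in(self, t0: float, t1: float) -> List[str]:
        out = {self.state_at(t0).orientation}
        for tt, st in zip(self._times, self._states):
            if t0 < tt <= t1:
                out.add(st.orientation)
        return sorted(out)
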