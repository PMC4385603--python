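"""Shared constants and pipeline configuration.

One config object travels through the whole pipeline so the sampling rate,
batch size, filter gain and detector constants are guaranteed consistent
between the simulator, the fusion filter and the state machines.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

#: Conversion constant between the accelerometer's g unit and m/s^2.
STANDARD_GRAVITY = 9.812865328

#: Node placements recognised throughout the package.
PLACEMENTS = ("chest", "hip", "leg")


@dataclass
class PipelineConfig:
    """Tunable parameters for the full processing chain.

    Defaults follow the prototype values where those are fixed (AMVD
    threshold/window) and documented engineering choices everywhere else.
    """

    # Sampling / batching
    sample_rate: float = 50.0          # Hz
    batch_size: int = 20               # samples per processing batch

    # Orientation fusion
    beta: float = 0.1                  # Madgwick gain
    warmup_s: float = 2.0              # excluded from state/anomaly evaluation
    calibration_samples: int = 100     # averaging window for frame alignment
    invert_rotation: bool = True       # apply q_cv * q_rot^-1 (as specified)

    # Activity detection (moving-variance of |accel| in g)
    amvd_gamma: float = 0.0013         # g^2
    amvd_window: int = 20

    # Step detection on |a_dyn| (hip / leg nodes)
    step_window_s: float = 1.0
    step_p2p_threshold_g: float = 0.3
    step_refractory_s: float = 0.25

    # Cadence is only screened once a walking bout is established; brief
    # AMVD drop-outs inside a bout are bridged for gait purposes
    min_cadence_bout_s: float = 3.0
    min_cadence_steps: int = 4
    bout_merge_gap_s: float = 1.0

    # Orientation hysteresis: state flips when tilt enters the *current*
    # state's transition interval (degrees from world vertical)
    vertical_transition: Tuple[float, float] = (60.0, 180.0)
    horizontal_transition: Tuple[float, float] = (0.0, 30.0)

    # Profile building
    k_sigma: float = 3.0
    interval_floor: float = 1e-6       # minimum half-width of an interval

    # Anomaly validation
    lookahead_s: float = 1.0           # horizon for final-orientation checks
    min_cluster: int = 3               # candidates per window below which the
                                       # cluster is dismissed as transient

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def warmup_samples(self) -> int:
        return int(round(self.warmup_s * self.sample_rate))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        for key in ("vertical_transition", "horizontal_transition"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
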