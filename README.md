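# banmon

Deterministic re-implementation of a wireless body-area-network movement
monitoring pipeline for healthcare: three body-worn inertial nodes (chest,
hip, leg) are fused into per-node and full-body movement/posture states, and
a two-stage anomaly chain detects falls and posture problems. A synthetic
IMU trace simulator with per-sample ground truth stands in for the human
trials and the external (vision-based) calibration system.

## Pipeline

```
raw counts ──► unit conversion ──► Madgwick AHRS fusion ──► state evaluation
 (per node)    (conversion table)   + referential calibration │
                                                              ▼
          server ◄── anomaly validation ◄── anomaly screening + body-state fusion
```

* **`sensor_model`** — raw-count ↔ physical-unit conversion (accel in g with
  1 g = 9.812865328 m/s², gyro in rad/s, mag in gauss); CSV trace I/O.
* **`quatmath`** — quaternion algebra, averaging, and the calibration
  transforms `q_rot = q·q_wn⁻¹`, `q_norm = q_cv·q_rot⁻¹` between internal
  and external referentials.
* **`fusion`** — Madgwick MARG gradient-descent filter plus calibration
  capture (averaged initial orientations of both systems).
* **`state_evaluator`** — dynamic acceleration (`a_dyn = a_prop − g`),
  velocity integration with zero-velocity updates, the AMVD moving-variance
  activity detector (γ = 0.0013, N = 20), peak-to-peak step detection, gait
  metrics (step length/walking distance/cadence/step force), and the
  per-node movement and orientation (tilt-hysteresis) state machines.
* **`body_state`** — full-body state fusion: movement follows the hip node;
  leg+chest orientations decide standing / seated / lying.
* **`anomaly`** — per-node interval screening against a user profile and
  multi-node validation with pending/escalation logic (server events).
* **`synth`** — scenario simulator (standing, fidgeting, L-walk, hump walk,
  cadence change, three sitting styles, unhampered/hampered falls, resting)
  with ground truth, plus profile building (mean ± kσ intervals).
* **`pipeline`** — end-to-end trial orchestration, event log, and the
  evaluation harness (recognition/fall accuracy, false-anomaly counters).

## CLI

```bash
banmon simulate --scenario fall_unhampered --seed 3 --out trial/
banmon make-profile --out profile.json
banmon run --traces trial/ --profile profile.json --out events.jsonl
banmon evaluate --traces trial/ --profile profile.json
banmon report --seed 1 --trials 10     # accuracy tables + operation counters
```

`simulate` writes one raw CSV per node (with JSON sidecars), external
reference quaternion CSVs and a ground-truth JSON; `run` replays them
through the full pipeline and emits a JSON-lines event log.

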