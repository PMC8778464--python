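# pigdsense

Gait analysis from a single thigh-worn IMU. The package simulates
timed-up-and-go (TUG) recordings with known ground truth, fuses raw
accelerometer/gyroscope data into a thigh-pitch angle with a two-state
Kalman filter, detects walking bouts with a Morse-wavelet CWT, segments
strides at initial/final contacts, extracts a 102-entry per-stride feature
vector (see `FEATURES.md`), and predicts a 0–20 gait-difficulty score with
nested leave-one-subject-out support vector regression.

## Library quick start

```python
from pigdsense import (
    SimulationConfig, simulate_subject, kalman_orientation,
    segment_recording, extract_all,
)

config = SimulationConfig(n_subjects=1, severity=5.0, seed=42)
recording, truth = simulate_subject(config, 0)
trace = kalman_orientation(recording)          # pitch + band-passed channels
bouts, strides = segment_recording(trace)      # CWT bouts, IC->IC windows
vectors = extract_all(strides)                 # 102 named features per stride
```

Cohort-level modelling lives in `pigdsense.study_runner`
(`cohort_feature_table`, `run_group`, `transfer_evaluate`,
`compare_groups`) and `pigdsense.pigd_regression`
(`nested_loso_optimize` with the kernel/box-constraint grid).

## CLI

```bash
pigdsense simulate --config config.yaml --out data/ --seed 1
pigdsense segment  --in data/S000_ON.csv --out segments.json
pigdsense extract  --in data/ --out features.csv
pigdsense fit      --in features.csv --out fit/ --config fit.yaml
pigdsense study    --config study.yaml --out study/
```

`config.yaml` can set any `SimulationConfig` field under a `simulate:` key,
e.g.

```yaml
simulate:
  n_subjects: 30
  conditions: [ON, OFF]
  fog_enabled: true
```

Recordings are one CSV per test (`t,ax,ay,az,gx,gy,gz`; g and deg/s) plus a
`subjects.csv` table (`subject_id,condition,pigd,updrs3,fog_status`).

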