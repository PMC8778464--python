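import numpy as np
import pytest

from pigdsense.gait_segmentation import StrideWindow
from pigdsense.orientation_estimation import kalman_orientation
from pigdsense.tug_simulator import SimulationConfig, simulate_subject


@pytest.fixture(scope="session")
def noiseless_walk():
    """One clean 20-s walk at exactly 1.0 s stride time (known ground truth)."""
    cfg = SimulationConfig(
        n_subjects=1,
        severity=0.0,
        stride_time_mean=1.0,
        stride_time_sd=0.0,
        gyro_bias=0.0,
        noise_sd_accel=0.0,
        noise_sd_gyro=0.0,
        amp_jitter_base=0.0,
        phase_plan=[("quiet-stand", 2.0), ("walk", 20.0), ("quiet-stand", 2.0)],
    )
    rec, gt = simulate_subject(cfg, 0)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def default_recording():
    """Moderate severity, default noise levels: the realistic pipeline input."""
    cfg = SimulationConfig(n_subjects=1, severity=5.0, seed=42)
    rec, gt = simulate_subject(cfg, 0)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def default_trace(default_recording):
    _, rec, _ = default_recording
    return kalman_orientation(rec)


@pytest.fixture
def make_stride():
    """Factory for hand-built stride windows.

    ``channels`` maps a subset of {ay, az, wx, tx} to arrays; unspecified
    channels default to a 1 Hz sinusoid so correlations stay defined.
    """

    def _make(channels=None, fs=60.0, duration=1.0, ic_start=0.0, fc=None):
        n = round(duration * fs)
        t = np.arange(n) / fs
        default = np.sin(2 * np.pi * 1.0 * t)
        signals = {c: default.copy() for c in ("ay", "az", "wx", "tx")}
        if channels:
            for name, values in channels.items():
                signals[name] = np.asarray(values, dtype=float)
        if fc is None:
            fc = ic_start + 0.6 * duration
        return StrideWindow(ic_start, fc, ic_start + duration, fs, signals)

    return _make


def interval_iou(a, b):
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


def event_precision_recall(detected, truth, tol=0.3):
    """Greedy one-to-one matching of event times within ``tol`` seconds."""
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for d in detected:
        if len(truth) == 0:
            break
        free = np.flatnonzero(~used)
        if free.size == 0:
            break
        i = free[np.argmin(np.abs(truth[free] - d))]
        if abs(truth[i] - d) <= tol:
            used[i] = True
            tp += 1
    precision = tp / len(detected) if len(detected) else 0.0
    recall = tp / len(truth) if len(truth) else 0.0
    return precision, recall
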