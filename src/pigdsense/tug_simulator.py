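"""Synthetic thigh-IMU timed-up-and-go recordings with ground truth.

The generator is angle-first: it synthesises the thigh pitch trace
``theta(t)`` for a full stand-walk-turn-walk-sit sequence, then derives the
gyroscope channel as its time derivative (plus bias and noise) and the
accelerometer channels as the gravity projection through the angle plus a
small motion term.  Because the true angle, walking-bout intervals and
initial/final-contact times are all known by construction, every downstream
stage (orientation fusion, bout detection, stride segmentation, feature
extraction, regression) can be tested against exact labels.

Severity is a score on a 0-20 scale and acts on the signal in fixed
directions: higher severity shrinks the pitch oscillation amplitude (and
with it signal RMS and the dominant-harmonic height) and increases
stride-time variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sensor_io import ImuRecording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_subject",
    "simulate_cohort",
]

#: deg per radian
_RAD2DEG = 180.0 / math.pi

#: Phase names accepted in a phase plan.
PHASE_NAMES = ("quiet-sit", "quiet-stand", "stand-up", "walk", "turn", "sit-down")


def default_phase_plan(walk_length_s: float = 8.0, turn_s: float = 3.0) -> list[tuple[str, float]]:
    """Stand up, walk out, turn, walk back, sit down — with quiet bookends."""
    return [
        ("quiet-sit", 2.0),
        ("stand-up", 2.0),
        ("walk", walk_length_s),
        ("turn", turn_s),
        ("walk", walk_length_s),
        ("sit-down", 2.0),
        ("quiet-sit", 2.0),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic TUG generator.

    ``severity`` may be a scalar applied to all subjects or a per-subject
    sequence on the 0-20 scale; ``None`` spreads subjects evenly over the
    scale.
    """

    n_subjects: int = 1
    severity: float | Sequence[float] | None = None
    stride_time_mean: float = 1.13
    stride_time_sd: float = 0.21
    walk_lengths: float = 8.0
    phase_plan: list[tuple[str, float]] | None = None
    gyro_bias: float = 0.5  # deg/s, constant per recording
    noise_sd_accel: float = 0.02  # g
    noise_sd_gyro: float = 1.0  # deg/s
    fog_enabled: bool = False
    fog_rate: float = 1.0  # expected episodes per walking bout
    sample_rate: float = 60.0
    seed: int = 0
    # signal-shape parameters (free parameters of the generator)
    base_amplitude: float = 0.35  # rad, severity-0 pitch oscillation amplitude
    amp_slope: float = 0.03  # fractional amplitude loss per severity point
    amp_jitter_base: float = 0.02  # relative per-stride amplitude jitter at severity 0
    amp_jitter_slope: float = 0.004  # extra relative jitter per severity point
    stride_sd_slope: float = 0.05  # stride-time sd inflation per severity point
    stride_time_slope: float = 0.0  # s of extra mean stride time per severity point
    theta_sit: float = 1.4  # rad, thigh pitch when seated
    lever_arm_m: float = 0.08  # IMU distance from hip joint, drives motion accel
    conditions: tuple[str, ...] = ("ON",)
    off_severity_boost: float = 2.0  # severity added in the OFF condition
    off_amplitude_factor: float = 0.9  # extra amplitude shrink in OFF
    fog_severity_threshold: float = 12.0  # subjects at/above are labelled FOG+

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.sample_rate <= 40.0:
            raise ValueError("sample_rate must exceed 40 Hz (2 x 20 Hz band edge)")
        if self.stride_time_mean <= 0.5:
            raise ValueError("stride_time_mean must exceed 0.5 s (IC spacing rule)")
        if self.stride_time_sd < 0:
            raise ValueError("stride_time_sd must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.phase_plan is None:
            self.phase_plan = default_phase_plan(self.walk_lengths)
        for name, dur in self.phase_plan:
            if name not in PHASE_NAMES:
                raise ValueError(f"unknown phase {name!r}; valid: {PHASE_NAMES}")
            if dur <= 0:
                raise ValueError(f"non-positive duration for phase {name!r}")
        if not 0 <= self.amp_slope * 20 < 1:
            raise ValueError("amp_slope too large: amplitude must stay positive at severity 20")

    def severity_of(self, subject_index: int) -> float:
        if self.severity is None:
            if self.n_subjects == 1:
                return 0.0
            return 20.0 * subject_index / (self.n_subjects - 1)
        if np.isscalar(self.severity):
            return float(self.severity)  # type: ignore[arg-type]
        return float(self.severity[subject_index])  # type: ignore[index]


@dataclass
class GroundTruth:
    """Construction-time labels for one synthetic recording."""

    bout_intervals: list[tuple[float, float]]
    ic_times: np.ndarray
    fc_times: np.ndarray
    severity: float
    fog_intervals: list[tuple[float, float]]
    theta: np.ndarray  # true pitch per sample, rad
    stride_periods: np.ndarray  # drawn stride durations, s

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        if self.ic_times.size and np.any(np.diff(self.ic_times) <= 0):
            raise ValueError("ic_times must be strictly increasing")
        for interval in self.bout_intervals:
            if interval[1] <= interval[0]:
                raise ValueError(f"degenerate bout interval {interval}")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _draw_stride_periods(
    rng: np.random.Generator, duration: float, mean: float, sd: float
) -> np.ndarray:
    """Stride periods that exactly tile ``duration`` (rescaled after drawing)."""
    if sd == 0.0:
        n = max(1, round(duration / mean))
        return np.full(n, duration / n)
    periods: list[float] = []
    total = 0.0
    while total < duration:
        p = rng.normal(mean, sd)
        p = float(np.clip(p, max(0.55, 0.5 * mean), 1.8 * mean))
        periods.append(p)
        total += p
    out = np.asarray(periods)
    return out * (duration / out.sum())


def _walk_bout(
    rng: np.random.Generator,
    duration: float,
    fs: float,
    stride_mean: float,
    stride_sd: float,
    amplitude: float,
    amp_jitter: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (theta, ic_times, fc_times, periods) local to the bout.

    The oscillation is ``A_k sin(2 pi phase)`` with phase advancing one unit
    per stride, so it starts and ends at zero (continuous with the flat
    baseline) and each stride's positive peak (IC) sits at phase k + 1/4,
    the negative peak (FC) at phase k + 3/4.
    """
    periods = _draw_stride_periods(rng, duration, stride_mean, stride_sd)
    n_strides = len(periods)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    n = round(duration * fs)
    tau = np.arange(n) / fs
    phase = np.interp(tau, bounds, np.arange(n_strides + 1, dtype=float))
    amps = amplitude * np.maximum(0.1, 1.0 + amp_jitter * rng.standard_normal(n_strides))
    stride_idx = np.minimum(np.floor(phase).astype(int), n_strides - 1)
    theta = amps[stride_idx] * np.sin(2.0 * math.pi * phase)
    ic_times = bounds[:-1] + 0.25 * periods
    fc_all = bounds[:-1] + 0.75 * periods
    # an FC is only defined between two consecutive ICs
    fc_times = fc_all[:-1] if n_strides >= 2 else np.empty(0)
    return theta, ic_times, fc_times, periods


def _inject_fog(
    rng: np.random.Generator,
    theta: np.ndarray,
    fs: float,
    rate: float,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Replace locomotor content with low-amplitude 3-8 Hz trembling."""
    duration = len(theta) / fs
    n_episodes = rng.poisson(rate)
    intervals: list[tuple[float, float]] = []
    if n_episodes == 0:
        return theta, intervals
    tau = np.arange(len(theta)) / fs
    mask = np.zeros(len(theta))
    for _ in range(n_episodes):
        dur = rng.uniform(1.0, 3.0)
        start = rng.uniform(0.0, max(duration - dur, 0.0))
        intervals.append((start, start + dur))
        ramp = 0.2  # s, smooth on/off
        env = _smoothstep((tau - start) / ramp) * _smoothstep((start + dur - tau) / ramp)
        mask = np.maximum(mask, env)
    f_tremble = rng.uniform(3.0, 8.0)
    tremble = 0.05 * np.sin(2.0 * math.pi * f_tremble * tau + rng.uniform(0, 2 * math.pi))
    out = theta * (1.0 - mask) + mask * tremble
    return out, _merge_intervals(intervals)


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _subject_rng(config: SimulationConfig, subject_index: int, condition: str) -> np.random.Generator:
    cond_code = 0 if condition == "ON" else 1
    seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_index, cond_code))
    return np.random.default_rng(seq)


def simulate_subject(
    config: SimulationConfig,
    subject_index: int,
    condition: str = "ON",
) -> tuple[ImuRecording, GroundTruth]:
    """Generate one TUG recording plus its construction labels.

    Deterministic: the same (config, subject_index, condition) triple always
    produces bit-identical output.
    """
    if subject_index >= config.n_subjects:
        raise ValueError(f"subject_index {subject_index} >= n_subjects {config.n_subjects}")
    rng = _subject_rng(config, subject_index, condition)
    fs = config.sample_rate
    dt = 1.0 / fs

    severity = config.severity_of(subject_index)
    if condition == "OFF":
        severity = min(20.0, severity + config.off_severity_boost)
    amplitude = config.base_amplitude * (1.0 - config.amp_slope * severity)
    if condition == "OFF":
        amplitude *= config.off_amplitude_factor
    stride_sd = config.stride_time_sd * (1.0 + config.stride_sd_slope * severity)
    stride_mean = config.stride_time_mean + config.stride_time_slope * severity
    amp_jitter = config.amp_jitter_base + config.amp_jitter_slope * severity

    segments: list[np.ndarray] = []
    bout_intervals: list[tuple[float, float]] = []
    ic_times: list[float] = []
    fc_times: list[float] = []
    fog_intervals: list[tuple[float, float]] = []
    stride_periods: list[float] = []
    t0 = 0.0
    baseline = config.theta_sit  # start seated

    for name, dur in config.phase_plan:
        n = round(dur * fs)
        tau = np.arange(n) / fs
        if name == "quiet-sit":
            seg = np.full(n, baseline)
        elif name == "quiet-stand":
            baseline = 0.0
            seg = np.full(n, baseline)
        elif name == "stand-up":
            seg = baseline + (0.0 - baseline) * _smoothstep(tau / dur)
            baseline = 0.0
        elif name == "sit-down":
            seg = baseline + (config.theta_sit - baseline) * _smoothstep(tau / dur)
            baseline = config.theta_sit
        elif name == "turn":
            # slow sub-band wobble around the standing baseline
            baseline = 0.0
            seg = baseline + 0.05 * amplitude * np.sin(2.0 * math.pi * 0.3 * tau)
        elif name == "walk":
            baseline = 0.0  # walking is upright by construction
            osc, ics, fcs, periods = _walk_bout(
                rng, dur, fs, stride_mean, stride_sd, amplitude, amp_jitter
            )
            if config.fog_enabled:
                osc, fog_local = _inject_fog(rng, osc, fs, config.fog_rate)
                fog_intervals.extend((a + t0, b + t0) for a, b in fog_local)
                keep = np.ones(len(ics), dtype=bool)
                keep_fc = np.ones(len(fcs), dtype=bool)
                for a, b in fog_local:
                    keep &= ~((ics > a) & (ics < b))
                    keep_fc &= ~((fcs > a) & (fcs < b))
                ics, fcs = ics[keep], fcs[keep_fc]
            seg = baseline + osc
            bout_intervals.append((t0, t0 + dur))
            ic_times.extend(ics + t0)
            fc_times.extend(fcs + t0)
            stride_periods.extend(periods)
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(name)
        segments.append(seg)
        t0 += n * dt

    theta = np.concatenate(segments)
    n_total = len(theta)
    t = np.arange(n_total) * dt

    # gyroscope: angle derivative + constant bias + white noise (deg/s)
    omega = np.gradient(theta, dt)  # rad/s
    gyro = np.empty((n_total, 3))
    gyro[:, 0] = omega * _RAD2DEG + config.gyro_bias + config.noise_sd_gyro * rng.standard_normal(n_total)
    gyro[:, 1] = 0.2 * omega * _RAD2DEG * 0.05 + config.noise_sd_gyro * rng.standard_normal(n_total)
    gyro[:, 2] = config.noise_sd_gyro * rng.standard_normal(n_total)

    # accelerometer: gravity projection + joint-rotation motion terms (g)
    g0 = 9.81
    alpha_dot = np.gradient(omega, dt)  # rad/s^2
    tangential = config.lever_arm_m * alpha_dot / g0
    centripetal = config.lever_arm_m * omega**2 / g0
    accel = np.empty((n_total, 3))
    accel[:, 0] = config.noise_sd_accel * rng.standard_normal(n_total)
    accel[:, 1] = np.cos(theta) - centripetal + config.noise_sd_accel * rng.standard_normal(n_total)
    accel[:, 2] = np.sin(theta) + tangential + config.noise_sd_accel * rng.standard_normal(n_total)

    rec = ImuRecording(
        subject_id=f"S{subject_index:03d}",
        condition=condition,
        sample_rate=fs,
        t=t,
        accel=accel,
        gyro=gyro,
    )
    truth = GroundTruth(
        bout_intervals=bout_intervals,
        ic_times=np.asarray(ic_times),
        fc_times=np.asarray(fc_times),
        severity=severity,
        fog_intervals=fog_intervals,
        theta=theta,
        stride_periods=np.asarray(stride_periods),
    )
    return rec, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[tuple[ImuRecording, GroundTruth]], pd.DataFrame]:
    """Generate one recording per subject per condition plus the subject table.

    The OFF condition re-uses each subject with an amplified severity effect
    (extra severity points and an additional amplitude shrink), so a
    subject's OFF recording always oscillates less than its ON recording.
    """
    if config.n_subjects < 2:
        raise ValueError("simulate_cohort needs n_subjects >= 2")
    recordings: list[tuple[ImuRecording, GroundTruth]] = []
    rows = []
    table_rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0xC0, 0)))
    for i in range(config.n_subjects):
        base_severity = config.severity_of(i)
        fog_status = "FOG+" if base_severity >= config.fog_severity_threshold else "FOG-"
        for condition in config.conditions:
            rec, truth = simulate_subject(config, i, condition)
            recordings.append((rec, truth))
            pigd = truth.severity  # identity map onto the 0-20 scale
            updrs3 = float(np.clip(2.0 * pigd + 10.0 + 3.0 * table_rng.standard_normal(), 0, 132))
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "condition": condition,
                    "pigd": pigd,
                    "updrs3": updrs3,
                    "fog_status": fog_status,
                }
            )
    table = pd.DataFrame(rows)
    return recordings, table
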