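"""Thigh-pitch estimation by gyro/accelerometer fusion, plus zero-phase filters.

A two-state Kalman filter tracks ``[pitch, gyro_bias]``: the prediction step
integrates the bias-corrected x-axis angular velocity, the correction step
uses the accelerometer-derived inclination ``atan2(az, ay)`` as the pitch
measurement.  The accelerometer only measures gravity when the sensor is
quasi-static, so the measurement-noise variance is inflated whenever the
acceleration norm departs from 1 g.

All signals are then band-passed with a second-order zero-lag (forward and
backward) Butterworth filter, 0.5-20 Hz by default, which removes the mean,
slow posture trends and high-frequency noise without phase distortion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .sensor_io import ImuRecording

__all__ = ["OrientationTrace", "kalman_orientation", "bandpass", "lowpass"]

_DEG2RAD = math.pi / 180.0


@dataclass
class OrientationTrace:
    """Estimated pitch aligned sample-to-sample with the filtered signals."""

    t: np.ndarray
    sample_rate: float
    theta_x: np.ndarray  # rad, fused pitch estimate
    theta_cov: np.ndarray  # per-sample pitch estimate variance
    filtered_accel: np.ndarray  # (n, 3) band-passed, g
    filtered_gyro: np.ndarray  # (n, 3) band-passed, deg/s
    filtered_theta: np.ndarray  # band-passed pitch, rad

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (
            len(self.theta_x) == len(self.theta_cov) == len(self.filtered_theta) == n
            and self.filtered_accel.shape == (n, 3)
            and self.filtered_gyro.shape == (n, 3)
        ):
            raise ValueError("trace channels must share the recording length")


def _check_band(low: float, high: float, fs: float) -> None:
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(f"high corner {high} Hz must stay below Nyquist {nyq} Hz")


def bandpass(x: np.ndarray, low: float, high: float, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    _check_band(low, high, fs)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def lowpass(x: np.ndarray, cutoff: float, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass."""
    if not 0 < cutoff < fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def kalman_orientation(
    rec: ImuRecording,
    q_gyro: float | None = None,
    r_accel: float = 0.05**2,
    band: tuple[float, float] = (0.5, 20.0),
    filter_order: int = 2,
) -> OrientationTrace:
    """Fuse the recording into a pitch trace and band-pass all channels.

    Parameters
    ----------
    rec : ImuRecording
        Uniformly sampled recording (validated at construction).
    q_gyro : float, optional
        Process-noise variance of the pitch state per step; defaults to
        ``(0.01 rad/s)^2 * dt``.
    r_accel : float
        Measurement-noise variance of the accelerometer inclination, rad^2.
        Inflated 100x on samples where ``| ||a|| - 1 g | > 0.1 g``.
    """
    n = rec.n_samples
    if n == 0:
        raise ValueError("empty recording")
    fs = rec.sample_rate
    dt = 1.0 / fs
    if q_gyro is None:
        q_gyro = (0.01) ** 2 * dt
    q_bias = (2e-4) ** 2 * dt  # rad/s random-walk of the gyro bias

    gyro_x = rec.gyro[:, 0] * _DEG2RAD  # rad/s
    ay, az = rec.accel[:, 1], rec.accel[:, 2]
    z_meas = np.arctan2(az, ay)  # accelerometer inclination, rad
    accel_norm = np.linalg.norm(rec.accel, axis=1)
    r_eff = np.where(np.abs(accel_norm - 1.0) > 0.1, 100.0 * r_accel, r_accel)

    # init: pitch from the first 0.5 s of accelerometer data, bias 0
    n_init = max(1, min(n, round(0.5 * fs)))
    x = np.array([float(np.median(z_meas[:n_init])), 0.0])
    P = np.diag([r_accel, (0.05) ** 2])  # generous initial bias uncertainty

    F = np.array([[1.0, -dt], [0.0, 1.0]])
    Q = np.diag([q_gyro, q_bias])
    H = np.array([1.0, 0.0])

    theta = np.empty(n)
    theta_cov = np.empty(n)
    for k in range(n):
        if k > 0:
            # predict: integrate bias-corrected angular velocity
            x = np.array([x[0] + (gyro_x[k] - x[1]) * dt, x[1]])
            P = F @ P @ F.T + Q
        # correct with the accelerometer inclination
        innov = z_meas[k] - x[0]
        s = P[0, 0] + r_eff[k]
        K = P[:, 0] / s
        x = x + K * innov
        P = P - np.outer(K, P[0, :])
        theta[k] = x[0]
        theta_cov[k] = P[0, 0]

    if n > 3 * filter_order * 10:
        f_acc = bandpass(rec.accel, band[0], band[1], fs, filter_order)
        f_gyr = bandpass(rec.gyro, band[0], band[1], fs, filter_order)
        f_theta = bandpass(theta, band[0], band[1], fs, filter_order)
    else:  # too short to filter stably; keep mean-removed raw channels
        f_acc = rec.accel - rec.accel.mean(axis=0)
        f_gyr = rec.gyro - rec.gyro.mean(axis=0)
        f_theta = theta - theta.mean()

    return OrientationTrace(
        t=rec.t,
        sample_rate=fs,
        theta_x=theta,
        theta_cov=theta_cov,
        filtered_accel=f_acc,
        filtered_gyro=f_gyr,
        filtered_theta=f_theta,
    )
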