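"""Walking-bout detection via a Morse-wavelet CWT, and stride segmentation.

The continuous wavelet transform uses an analytic generalized Morse wavelet
defined directly in the frequency domain,

    psi_hat(w) = a * w**beta * exp(-w**gamma)   for w > 0, else 0,

with the amplitude ``a`` chosen so that the wavelet response peaks at 2:
at the matched scale a unit-amplitude sinusoid then yields a coefficient
magnitude of ~1, which makes the intensity profile directly comparable to
the signal's oscillation amplitude.  Scales are chosen so the wavelet
pseudo-frequencies tile the locomotor band (0.5-2 Hz by default).

Bouts are the maximal time runs where the scale-averaged |CWT| profile
exceeds its own standard deviation; initial contacts (ICs) are the positive
peaks of the 2 Hz low-passed pitch inside a bout (height above the bout's
standard deviation, at least 0.5 s apart) and the final contact (FC) of a
stride is the most negative local minimum between its two ICs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .orientation_estimation import OrientationTrace, lowpass

__all__ = [
    "WalkingBout",
    "StrideWindow",
    "morse_wavelet_ft",
    "cwt_scalogram",
    "detect_bouts",
    "detect_contacts",
    "cut_strides",
    "segment_recording",
]

logger = logging.getLogger(__name__)

#: Components a stride window carries (acceleration y/z in g, angular
#: velocity x in deg/s, pitch in rad), in canonical order.
STRIDE_CHANNELS = ("ay", "az", "wx", "tx")


@dataclass(frozen=True)
class WalkingBout:
    start: float
    end: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bout end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StrideWindow:
    """One IC-to-IC slice of all signals with its contact timestamps."""

    ic_start: float
    fc: float
    ic_end: float
    sample_rate: float
    signals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ic_start < self.fc < self.ic_end:
            raise ValueError(
                f"contacts out of order: IC {self.ic_start} < FC {self.fc} < IC {self.ic_end} required"
            )
        if self.ic_end - self.ic_start < 0.5 - 1e-9:
            raise ValueError("stride shorter than the 0.5 s peak-spacing floor")

    @property
    def t_stride(self) -> float:
        return self.ic_end - self.ic_start

    @property
    def t_stance(self) -> float:
        return self.fc - self.ic_start

    @property
    def t_swing(self) -> float:
        return self.ic_end - self.fc


def morse_wavelet_ft(omega: np.ndarray, gamma: float = 3.0, beta: float = 20.0) -> np.ndarray:
    """Frequency-domain generalized Morse wavelet, peak value 2.

    ``omega`` is angular frequency in rad/sample; negative frequencies get
    zero (analytic wavelet).
    """
    omega = np.asarray(omega, dtype=float)
    peak = (beta / gamma) ** (1.0 / gamma)
    out = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    # evaluate in log space for numerical stability at large beta
    log_psi = beta * np.log(w) - w**gamma - (beta * np.log(peak) - peak**gamma)
    out[pos] = 2.0 * np.exp(log_psi)
    return out


def morse_pseudo_frequencies(freq_lo: float, freq_hi: float, n_scales: int) -> np.ndarray:
    """Log-spaced pseudo-frequencies (Hz) covering [freq_lo, freq_hi]."""
    return np.geomspace(freq_lo, freq_hi, n_scales)


def cwt_scalogram(
    theta: np.ndarray,
    fs: float,
    freq_lo: float = 0.5,
    freq_hi: float = 2.0,
    n_scales: int = 32,
    gamma: float = 3.0,
    beta: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """|CWT| of ``theta`` over scales tiling [freq_lo, freq_hi].

    Returns ``(scalogram, freqs)`` where ``scalogram[i, j]`` is the
    coefficient magnitude at pseudo-frequency ``freqs[i]`` and sample ``j``.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1:
        raise ValueError("theta must be one-dimensional")
    nyq = fs / 2.0
    if not 0 < freq_lo < freq_hi:
        raise ValueError("need 0 < freq_lo < freq_hi")
    if freq_hi >= nyq:
        raise ValueError(f"freq_hi {freq_hi} Hz must stay below Nyquist {nyq} Hz")
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    n = len(theta)
    freqs = morse_pseudo_frequencies(freq_lo, freq_hi, n_scales)
    peak = (beta / gamma) ** (1.0 / gamma)
    xf = np.fft.fft(theta)
    omega = 2.0 * math.pi * np.fft.fftfreq(n)  # rad/sample
    scalogram = np.empty((n_scales, n))
    for i, f in enumerate(freqs):
        scale = peak * fs / (2.0 * math.pi * f)  # samples
        psi = morse_wavelet_ft(scale * omega, gamma=gamma, beta=beta)
        scalogram[i] = np.abs(np.fft.ifft(xf * psi))
    return scalogram, freqs


def detect_bouts(
    scalogram: np.ndarray,
    t: np.ndarray,
    min_duration_s: float = 2.0,
    merge_gap_s: float = 0.5,
    squared: bool = False,
) -> list[WalkingBout]:
    """Threshold the scale-averaged intensity profile into walking bouts.

    The profile is the mean over scales of |CWT| (or |CWT|^2 when
    ``squared``); runs where it exceeds its own standard deviation are
    selected, runs separated by less than ``merge_gap_s`` merged, and runs
    shorter than ``min_duration_s`` dropped.
    """
    scalogram = np.asarray(scalogram, dtype=float)
    if scalogram.size == 0:
        raise ValueError("empty scalogram")
    profile = (scalogram**2 if squared else scalogram).mean(axis=0)
    threshold = float(profile.std())
    if threshold == 0.0:
        return []
    above = profile > threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])
    runs = list(zip(run_starts, run_ends))

    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    merged: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if (a - merged[-1][1]) * dt < merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    bouts = []
    for a, b in merged:
        start, end = float(t[a]), float(t[b]) + dt
        if end - start >= min_duration_s:
            bouts.append(WalkingBout(start, end, float(profile[a : b + 1].mean())))
    return bouts


def detect_contacts(
    theta: np.ndarray,
    fs: float,
    t0: float = 0.0,
    min_spacing_s: float = 0.5,
    lowpass_hz: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """IC/FC times from the pitch signal of one bout.

    ICs are positive peaks of the 2 Hz low-passed pitch, higher than the
    signal standard deviation and at least ``min_spacing_s`` apart (the
    higher peak wins a spacing conflict).  The FC of stride i is the most
    negative local minimum strictly between IC_i and IC_{i+1}.
    """
    theta = np.asarray(theta, dtype=float)
    if len(theta) < fs:  # bout shorter than 1 s
        raise ValueError("bout must be at least 1 s long")
    theta_lp = lowpass(theta, lowpass_hz, fs) if len(theta) > 30 else theta - theta.mean()
    sd = float(theta_lp.std())
    if sd == 0.0:
        return np.empty(0), np.empty(0)
    ic_idx, _ = sps.find_peaks(theta_lp, height=sd, distance=max(1, round(min_spacing_s * fs)))
    if len(ic_idx) < 2:
        return t0 + ic_idx / fs, np.empty(0)
    trough_idx, _ = sps.find_peaks(-theta_lp)
    fc_idx = []
    keep_ic = []
    for i, j in zip(ic_idx[:-1], ic_idx[1:]):
        between = trough_idx[(trough_idx > i) & (trough_idx < j)]
        if between.size == 0:
            interior = np.arange(i + 1, j)
            if interior.size == 0:
                continue
            fc_idx.append(int(interior[np.argmin(theta_lp[interior])]))
        else:
            fc_idx.append(int(between[np.argmin(theta_lp[between])]))
    return t0 + ic_idx / fs, t0 + np.asarray(fc_idx, dtype=float) / fs


def cut_strides(
    trace: OrientationTrace,
    bouts: list[WalkingBout],
    ic_times: np.ndarray,
    fc_times: np.ndarray,
) -> list[StrideWindow]:
    """One window per consecutive IC pair with its enclosed FC.

    Strides whose FC does not fall strictly between the two ICs are dropped
    with a logged warning; windows carry the band-passed channel slices.
    """
    ic_times = np.asarray(ic_times, dtype=float)
    fc_times = np.asarray(fc_times, dtype=float)
    fs = trace.sample_rate
    t_start = float(trace.t[0])
    strides: list[StrideWindow] = []
    for bout in bouts:
        in_bout = ic_times[(ic_times >= bout.start) & (ic_times <= bout.end)]
        for ic_a, ic_b in zip(in_bout[:-1], in_bout[1:]):
            candidates = fc_times[(fc_times > ic_a) & (fc_times < ic_b)]
            if candidates.size != 1:
                logger.warning(
                    "stride [%0.2f, %0.2f]s dropped: %d FCs inside", ic_a, ic_b, candidates.size
                )
                continue
            fc = float(candidates[0])
            a = round((ic_a - t_start) * fs)
            b = round((ic_b - t_start) * fs)
            signals = {
                "ay": trace.filtered_accel[a:b, 1].copy(),
                "az": trace.filtered_accel[a:b, 2].copy(),
                "wx": trace.filtered_gyro[a:b, 0].copy(),
                "tx": trace.filtered_theta[a:b].copy(),
            }
            try:
                strides.append(StrideWindow(float(ic_a), fc, float(ic_b), fs, signals))
            except ValueError as exc:
                logger.warning("stride [%0.2f, %0.2f]s dropped: %s", ic_a, ic_b, exc)
    return strides


def segment_recording(
    trace: OrientationTrace,
    freq_range: tuple[float, float] = (0.5, 2.0),
    n_scales: int = 32,
    min_bout_s: float = 2.0,
    merge_gap_s: float = 0.5,
) -> tuple[list[WalkingBout], list[StrideWindow]]:
    """Full segmentation: CWT bout detection, contacts, stride windows."""
    scalogram, _ = cwt_scalogram(
        trace.filtered_theta, trace.sample_rate, freq_range[0], freq_range[1], n_scales
    )
    bouts = detect_bouts(scalogram, trace.t, min_duration_s=min_bout_s, merge_gap_s=merge_gap_s)
    all_ics, all_fcs = [], []
    fs = trace.sample_rate
    t_start = float(trace.t[0])
    for bout in bouts:
        a = round((bout.start - t_start) * fs)
        b = round((bout.end - t_start) * fs)
        if b - a < fs:
            continue
        try:
            ics, fcs = detect_contacts(trace.filtered_theta[a:b], fs, t0=bout.start)
        except ValueError:
            continue
        all_ics.append(ics)
        all_fcs.append(fcs)
    ic_times = np.concatenate(all_ics) if all_ics else np.empty(0)
    fc_times = np.concatenate(all_fcs) if all_fcs else np.empty(0)
    strides = cut_strides(trace, bouts, ic_times, fc_times)
    return bouts, strides
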