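"""Per-stride feature vector: 3 temporal + 51 time-domain + 48 spectral = 102.

Single-channel features are computed on the four components carried by a
stride window — acceleration y and z, angular velocity x, and pitch
(``ay, az, wx, tx``).  The canonical ordering (documented in FEATURES.md) is
time-domain features x components, the 7 correlation features, spectral
features x components, the 24 band-energy fractions, and finally the three
stride timings.

Spectra are one-sided FFT amplitude spectra on a fixed number of points
``n_fft = round(mean_stride_time * fs)`` (68 at 60 Hz for a 1.13 s mean
stride): shorter strides are linearly interpolated up to ``n_fft``, longer
strides keep their own length and simply lose a little spectral resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .gait_segmentation import STRIDE_CHANNELS, StrideWindow

__all__ = [
    "FEATURE_NAMES",
    "MEAN_STRIDE_TIME_S",
    "SubjectFeatureRow",
    "time_features",
    "spectral_features",
    "extract_features",
    "extract_all",
    "aggregate_subject",
    "features_table",
]

logger = logging.getLogger(__name__)

_EPS = 1e-5

#: Population mean stride time (s) used to fix the FFT length.
MEAN_STRIDE_TIME_S = 1.13

#: Band edges (Hz) for the six binEnergy fractions per component: the
#: locomotor band, two low bands straddling the 4-8 Hz freeze band, and
#: three higher bands up to the 20 Hz filter corner.
BIN_EDGES = ((0.5, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 16.0), (16.0, 20.0))

#: Search band (Hz) for the dominant harmonic.
DH_BAND = (0.5, 20.0)

_TIME_IDS = ("Min", "Max", "Mean", "Std", "RMS", "Range", "Entropy", "nPeaks", "hPeaks", "vPeaks", "Zc")
_SPEC_IDS = ("DHfrequency", "DHheight", "DHwidth", "Etot", "DHratio", "sEntropy")
_CORR_NAMES = (
    "Corr_ay_az",
    "Corr_ay_wx",
    "Corr_ay_tx",
    "Corr_az_wx",
    "Corr_az_tx",
    "Corr_wx_tx",
    "Corr_tx_lag",
)


def _canonical_names() -> list[str]:
    names = [f"{fid}_{c}" for fid in _TIME_IDS for c in STRIDE_CHANNELS]
    names += list(_CORR_NAMES)
    names += [f"{fid}_{c}" for fid in _SPEC_IDS for c in STRIDE_CHANNELS]
    names += [f"binEnergy{b + 1}_{c}" for b in range(len(BIN_EDGES)) for c in STRIDE_CHANNELS]
    names += ["Tstride", "Tstance", "Tswing"]
    return names


FEATURE_NAMES: list[str] = _canonical_names()
assert len(FEATURE_NAMES) == 102, f"feature contract broken: {len(FEATURE_NAMES)}"


def _entropy(x: np.ndarray) -> float:
    """Shannon entropy of the normalized absolute-amplitude distribution."""
    total = np.sum(np.abs(x))
    if total == 0:
        return 0.0
    p = np.abs(x) / total
    return float(-np.sum(p * np.log(p + _EPS)))


def _zero_crossing_rate(x: np.ndarray, fs: float) -> float:
    centered = x - x.mean()
    crossings = int(np.sum(np.signbit(centered[:-1]) != np.signbit(centered[1:])))
    return crossings * fs / len(x)


def _safe_corr(a: np.ndarray, b: np.ndarray, label: str) -> float:
    if a.std() == 0 or b.std() == 0:
        logger.warning("constant channel in correlation %s; reporting 0", label)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def time_features(stride: StrideWindow) -> dict[str, float]:
    """Time-domain block: 11 statistics per component plus 7 correlations."""
    out: dict[str, float] = {}
    fs = stride.sample_rate
    for comp in STRIDE_CHANNELS:
        x = stride.signals[comp]
        if len(x) < 2:
            raise ValueError(f"stride channel {comp} needs >= 2 samples")
        std = float(x.std())  # population form, divisor N
        out[f"Min_{comp}"] = float(x.min())
        out[f"Max_{comp}"] = float(x.max())
        out[f"Mean_{comp}"] = float(x.mean())
        out[f"Std_{comp}"] = std
        out[f"RMS_{comp}"] = float(np.sqrt(np.mean(x**2)))
        out[f"Range_{comp}"] = float(x.max() - x.min())
        out[f"Entropy_{comp}"] = _entropy(x)
        if std > 0:
            peaks, props = sps.find_peaks(x, height=std)
            heights = props["peak_heights"]
        else:
            heights = np.empty(0)
        out[f"nPeaks_{comp}"] = float(len(heights))
        out[f"hPeaks_{comp}"] = float(heights.mean()) if len(heights) else 0.0
        out[f"vPeaks_{comp}"] = float(heights.std()) if len(heights) > 1 else 0.0
        out[f"Zc_{comp}"] = _zero_crossing_rate(x, fs)

    pairs = [("ay", "az"), ("ay", "wx"), ("ay", "tx"), ("az", "wx"), ("az", "tx"), ("wx", "tx")]
    for a, b in pairs:
        out[f"Corr_{a}_{b}"] = _safe_corr(stride.signals[a], stride.signals[b], f"{a}/{b}")
    tx = stride.signals["tx"]
    lag = len(tx) // 2  # half-stride lag autocorrelation of the pitch
    if lag >= 1 and len(tx) - lag >= 2:
        out["Corr_tx_lag"] = _safe_corr(tx[:-lag], tx[lag:], "tx lag")
    else:
        out["Corr_tx_lag"] = 0.0
    return out


def _fwhm(freqs: np.ndarray, mag: np.ndarray, peak_idx: int) -> float:
    """Full width at half maximum around a spectral peak, interpolated in Hz."""
    half = mag[peak_idx] / 2.0
    left = freqs[0]
    for i in range(peak_idx, 0, -1):
        if mag[i - 1] < half:
            # linear interpolation of the crossing
            frac = (mag[i] - half) / (mag[i] - mag[i - 1])
            left = freqs[i] - frac * (freqs[i] - freqs[i - 1])
            break
    right = freqs[-1]
    for i in range(peak_idx, len(mag) - 1):
        if mag[i + 1] < half:
            frac = (mag[i] - half) / (mag[i] - mag[i + 1])
            right = freqs[i] + frac * (freqs[i + 1] - freqs[i])
            break
    return float(max(right - left, freqs[1] - freqs[0]))


def _amplitude_spectrum(x: np.ndarray, fs: float, n_fft: int) -> tuple[np.ndarray, np.ndarray]:
    if len(x) < n_fft:
        # pad by linear interpolation onto the fixed grid
        src = np.linspace(0.0, 1.0, len(x))
        dst = np.linspace(0.0, 1.0, n_fft)
        x = np.interp(dst, src, x)
    n = len(x)
    mag = 2.0 * np.abs(np.fft.rfft(x)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, mag


def spectral_features(stride: StrideWindow, n_fft: int | None = None) -> dict[str, float]:
    """Spectral block: dominant-harmonic descriptors, totals, band fractions."""
    fs = stride.sample_rate
    if n_fft is None:
        n_fft = round(MEAN_STRIDE_TIME_S * fs)
    out: dict[str, float] = {}
    for comp in STRIDE_CHANNELS:
        x = stride.signals[comp]
        if len(x) < 3:
            raise ValueError(f"stride channel {comp} too short for a spectrum")
        freqs, mag = _amplitude_spectrum(x, fs, n_fft)
        etot = float(mag[1:].sum())  # all non-DC one-sided bins
        band = (freqs >= DH_BAND[0]) & (freqs <= DH_BAND[1])
        if etot == 0 or not band.any():
            for fid in _SPEC_IDS:
                out[f"{fid}_{comp}"] = 0.0
            for b in range(len(BIN_EDGES)):
                out[f"binEnergy{b + 1}_{comp}"] = 0.0
            continue
        band_idx = np.flatnonzero(band)
        peak_idx = int(band_idx[np.argmax(mag[band_idx])])
        dh_freq = float(freqs[peak_idx])
        dh_height = float(mag[peak_idx])
        dh_width = _fwhm(freqs, mag, peak_idx)
        in_dh = (freqs >= dh_freq - dh_width / 2.0) & (freqs <= dh_freq + dh_width / 2.0) & (freqs > 0)
        # energy fraction: squared magnitudes, so the main lobe dominates
        dh_ratio = float(np.clip((mag[in_dh] ** 2).sum() / (mag[1:] ** 2).sum(), 0.0, 1.0))
        p = mag[1:] / etot
        s_entropy = float(-np.sum(p * np.log(p + _EPS)))
        out[f"DHfrequency_{comp}"] = dh_freq
        out[f"DHheight_{comp}"] = dh_height
        out[f"DHwidth_{comp}"] = dh_width
        out[f"Etot_{comp}"] = etot
        out[f"DHratio_{comp}"] = dh_ratio
        out[f"sEntropy_{comp}"] = s_entropy
        for b, (lo, hi) in enumerate(BIN_EDGES):
            sel = (freqs >= lo) & (freqs < hi)
            out[f"binEnergy{b + 1}_{comp}"] = float(np.clip(mag[sel].sum() / etot, 0.0, 1.0))
    return out


def extract_features(stride: StrideWindow, n_fft: int | None = None) -> dict[str, float]:
    """Full 102-entry vector for one stride, in canonical order."""
    values = time_features(stride)
    values.update(spectral_features(stride, n_fft))
    values["Tstride"] = stride.t_stride
    values["Tstance"] = stride.t_stance
    values["Tswing"] = stride.t_swing
    ordered = {name: values[name] for name in FEATURE_NAMES}
    if len(ordered) != 102:  # pragma: no cover - contract guard
        raise RuntimeError(f"feature vector has {len(ordered)} entries, expected 102")
    return ordered


def extract_all(strides: list[StrideWindow], n_fft: int | None = None) -> list[dict[str, float]]:
    """Per-stride vectors; strides too short for a spectrum are skipped."""
    if not strides:
        raise ValueError("no strides to extract features from")
    vectors = []
    for k, stride in enumerate(strides):
        try:
            vectors.append(extract_features(stride, n_fft))
        except ValueError as exc:
            logger.warning("stride %d skipped: %s", k, exc)
    if not vectors:
        raise ValueError("all strides were skipped during feature extraction")
    return vectors


@dataclass
class SubjectFeatureRow:
    """Stride features averaged over one subject-condition."""

    subject_id: str
    condition: str
    fog_status: str
    n_strides: int
    pigd: float
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("a subject row needs at least one stride")


def aggregate_subject(
    vectors: list[dict[str, float]],
    subject_id: str,
    condition: str = "ON",
    fog_status: str = "FOG-",
    pigd: float = 0.0,
) -> SubjectFeatureRow:
    """Arithmetic mean over strides for every feature."""
    if not vectors:
        raise ValueError("need at least one stride vector")
    matrix = np.array([[v[name] for name in FEATURE_NAMES] for v in vectors])
    means = matrix.mean(axis=0)
    return SubjectFeatureRow(
        subject_id=subject_id,
        condition=condition,
        fog_status=fog_status,
        n_strides=len(vectors),
        pigd=pigd,
        features=dict(zip(FEATURE_NAMES, means.tolist())),
    )


def features_table(rows: list[SubjectFeatureRow]) -> pd.DataFrame:
    """Stack subject rows into a DataFrame (metadata columns first)."""
    records = []
    for row in rows:
        rec = {
            "subject_id": row.subject_id,
            "condition": row.condition,
            "fog_status": row.fog_status,
            "n_strides": row.n_strides,
            "pigd": row.pigd,
        }
        rec.update(row.features)
        records.append(rec)
    return pd.DataFrame(records)
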