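# Stride feature vector (102 entries)

Single-channel features are computed on four components of every stride
window (one initial contact to the next):

| code | signal | units |
| ---- | ------ | ----- |
| `ay` | acceleration, y axis (anti-gravity when standing) | g |
| `az` | acceleration, z axis | g |
| `wx` | angular velocity, x axis (thigh pitch rate) | deg/s |
| `tx` | estimated thigh pitch angle | rad |

All channels are band-passed (0.5–20 Hz, second-order zero-lag Butterworth)
before feature extraction, so means are near zero and slow posture trends
are removed.

## Canonical order

1. **Time-domain block — 44 features.** For each statistic, the four
   components in the order `ay, az, wx, tx`:
   `Min`, `Max`, `Mean`, `Std` (population), `RMS`, `Range`,
   `Entropy` (Shannon entropy of the normalized absolute-amplitude
   distribution, −Σ p·log(p+ε), ε = 1e−5),
   `nPeaks` (strict local maxima higher than Std),
   `hPeaks` (mean height of those peaks), `vPeaks` (sd of the heights),
   `Zc` (zero crossings per second of the mean-removed signal).
   Names: `Min_ay`, `Min_az`, …, `Zc_tx`.

2. **Correlation block — 7 features.** The six pairwise Pearson
   correlations `Corr_ay_az`, `Corr_ay_wx`, `Corr_ay_tx`, `Corr_az_wx`,
   `Corr_az_tx`, `Corr_wx_tx`, plus `Corr_tx_lag`: the half-window-lag
   autocorrelation of the pitch channel (a within-stride regularity
   measure). A constant channel yields 0 with a warning.

3. **Spectral block — 24 features.** One-sided FFT amplitude spectrum on
   `n_fft = round(1.13 s × Fs)` points (68 at 60 Hz); shorter strides are
   linearly interpolated up to `n_fft`, longer strides keep their own
   length. Per statistic, the four components:
   `DHfrequency` (bin of the largest magnitude in 0.5–20 Hz, Hz),
   `DHheight` (that magnitude), `DHwidth` (full width at half maximum, Hz),
   `Etot` (sum of non-DC magnitudes), `DHratio` (power fraction inside the
   DH width band), `sEntropy` (Shannon entropy of the normalized magnitude
   spectrum).

4. **Band-energy block — 24 features.** `binEnergy{1..6}_{comp}`: the
   fraction of `Etot` inside six contiguous bands
   `[0.5–2]`, `[2–4]`, `[4–8]` (freeze band), `[8–12]`, `[12–16]`,
   `[16–20]` Hz; band-major, components inner.

5. **Temporal block — 3 features.** `Tstride`, `Tstance`, `Tswing`
   (seconds), with `Tstance + Tswing = Tstride` exactly.

Total: 44 + 7 + 24 + 24 + 3 = **102**. The authoritative list is
`pigdsense.feature_extraction.FEATURE_NAMES`.
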