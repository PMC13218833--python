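"""Raw EEG -> cleaned aEEG at the oximeter rate; SctO2 cleaning/detrending.

The chain for EEG follows standard neonatal amplitude-integrated EEG (aEEG)
practice: equiripple linear-phase band-pass (2–15 Hz), full-wave
rectification with a short moving-average envelope, percentile (P90-P10)
downsampling to the SctO2 rate, artifact replacement (25 uV ceiling, +-5 uV
deviation from the linear trend), and second-order polynomial detrending.
SctO2 gets the +-20%-of-trend replacement rule and the same detrending.

Replacement is last-valid-value carry-forward (a leading invalid run takes
the first valid value): the rule is "replace with adjacent values", which a
causal carry-forward realizes deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

AEEG_CLIP_UV = 25.0          # aEEG ceiling above which samples are artifacts
AEEG_TREND_DEV_UV = 5.0      # max |deviation| from linear trend, aEEG
SCTO2_TREND_DEV_FRAC = 0.20  # max |deviation| as fraction of trend, SctO2
ENVELOPE_SMOOTH_S = 0.5      # moving-average window for the rectified envelope


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Equiripple FIR band-pass design (Parks-McClellan)."""

    fs: float
    passband: tuple[float, float]
    stopband: tuple[float, float]      # lower and upper stopband edges (Hz)
    numtaps: int
    coefficients: np.ndarray

    def attenuation_db(self, freq: float) -> float:
        """Magnitude response at ``freq`` relative to the passband center, dB."""
        w, h = sps.freqz(self.coefficients, worN=[freq, np.mean(self.passband)],
                         fs=self.fs)
        return -20.0 * np.log10(np.abs(h[0]) / np.abs(h[1]))


@dataclass
class AEEGSeries:
    """Artifact-cleaned aEEG envelope, one value per SctO2 sampling window."""

    values: np.ndarray          # microvolts, >= 0 before detrending
    rate: float                 # Hz (the SctO2 rate)
    time_h: np.ndarray          # hours, window centers
    cleaning_log: list = field(default_factory=list)   # (index, reason, original)


@dataclass
class CleanSeries:
    """Detrended series (aEEG in uV or SctO2 in percent)."""

    values: np.ndarray
    rate: float
    time_h: np.ndarray
    detrend_order: int = 2
    replaced_indices: list = field(default_factory=list)


def design_bandpass(
    fs: float = 256.0,
    passband: tuple[float, float] = (2.0, 15.0),
    stopband: tuple[float, float] = (1.0, 20.0),
    atten_db: float = 60.0,
    numtaps: int | None = None,
) -> FilterSpec:
    """Design the asymmetric equiripple band-pass (Parks-McClellan).

    Transition bands are asymmetric by construction (1->2 Hz below, 15->20 Hz
    above by default).  The order, when not given, comes from Kaiser's
    estimate on the narrower transition band.
    """
    lo_stop, hi_stop = stopband
    lo_pass, hi_pass = passband
    if not (0 < lo_stop < lo_pass < hi_pass < hi_stop < fs / 2):
        raise PreprocessError("band edges must satisfy 0 < stop < pass < pass < stop < fs/2")
    bands = [0.0, lo_stop, lo_pass, hi_pass, hi_stop, fs / 2]
    desired = [0.0, 1.0, 0.0]
    # weight stopbands for the attenuation target relative to 1% passband ripple
    delta_p, delta_s = 0.01, 10 ** (-atten_db / 20.0)
    weight = [delta_p / delta_s, 1.0, delta_p / delta_s]
    if numtaps is not None:
        candidates = [numtaps | 1]
    else:
        # Herrmann-style estimate on the narrower transition; the exchange
        # algorithm loses convergence just above the required order, so probe
        # downward from the estimate and keep the best validated design.
        trans = min(lo_pass - lo_stop, hi_stop - hi_pass)
        est = int(np.ceil((-20.0 * np.log10(np.sqrt(delta_p * delta_s)) - 13.0)
                          / (14.6 * trans / fs))) | 1
        step = max(2, (est // 20) & ~1)
        candidates = [max(15, est - k * step) | 1 for k in range(6)]
    best: FilterSpec | None = None
    best_att = -np.inf
    center = 0.5 * (lo_pass + hi_pass)
    for nt in candidates:
        try:
            taps = sps.remez(nt, bands, desired, weight=weight, fs=fs)
        except Exception:
            continue
        _, h = sps.freqz(taps, worN=[lo_stop, center, hi_stop], fs=fs)
        gain = np.abs(h[1])
        if not 0.95 <= gain <= 1.05:
            continue  # diverged design
        att = -20.0 * np.log10(np.abs(h[[0, 2]]) / gain)
        spec = FilterSpec(fs=fs, passband=passband, stopband=stopband,
                          numtaps=nt, coefficients=taps)
        if att.min() > best_att:
            best, best_att = spec, att.min()
        if att.min() >= atten_db - 3.0:
            break
    if best is None or best_att < 20.0:
        raise PreprocessError(
            f"equiripple design not meeting 20 dB stopband attenuation at "
            f"fs={fs}; supply a higher numtaps explicitly")
    return best


def apply_bandpass(x: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """Zero-phase application of the linear-phase FIR (group delay removed)."""
    pad = filt.numtaps // 2
    y = sps.fftconvolve(x, filt.coefficients, mode="full")
    return y[pad:pad + len(x)]


def compute_aeeg(filtered_eeg: np.ndarray, fs: float,
                 smooth_s: float = ENVELOPE_SMOOTH_S) -> np.ndarray:
    """Rectified, smoothed amplitude envelope of band-passed EEG (uV, >= 0).

    Full-wave rectification followed by a ``smooth_s``-second moving average.
    This is an envelope approximation in the spirit of clinical aEEG
    processing chains; the percentile downsampler applied next dominates the
    final series.
    """
    rect = np.abs(np.asarray(filtered_eeg, dtype=float))
    win = max(1, int(round(smooth_s * fs)))
    return uniform_filter1d(rect, size=win, mode="nearest")


def envelope_downsample(envelope: np.ndarray, fs_in: float, fs_out: float):
    """P90 - P10 of the envelope per non-overlapping SctO2-interval window.

    Windows are left-aligned with timestamps at window centers; output length
    is floor(duration * fs_out).  Percentiles use linear interpolation
    between order statistics.
    """
    if fs_in <= fs_out:
        raise PreprocessError("fs_in must exceed fs_out")
    n_in = len(envelope)
    n_out = int(np.floor(n_in * fs_out / fs_in))
    if n_out < 1:
        raise PreprocessError("input shorter than one output window")
    bounds = np.floor(np.arange(n_out + 1) * fs_in / fs_out).astype(np.int64)
    lengths = np.diff(bounds)
    if lengths.min() < 4:
        raise PreprocessError("downsampling window shorter than 4 samples")
    env = np.asarray(envelope, dtype=float)
    out = np.empty(n_out)
    # windows come in at most two lengths (non-integer rate ratio); batch each
    for L in np.unique(lengths):
        sel = np.nonzero(lengths == L)[0]
        idx = bounds[sel][:, None] + np.arange(L)[None, :]
        block = env[idx]
        out[sel] = np.percentile(block, 90, axis=1) - np.percentile(block, 10, axis=1)
    time_h = (np.arange(n_out) + 0.5) / fs_out / 3600.0
    return AEEGSeries(values=out, rate=fs_out, time_h=time_h)


def _carry_forward_replace(values: np.ndarray, invalid: np.ndarray):
    """Replace invalid samples with the nearest preceding valid value.

    A leading run of invalid samples takes the first valid value.  Returns
    (new values, list of replaced indices).  All-invalid input is an error.
    """
    if invalid.all():
        raise PreprocessError("no valid samples")
    replaced = np.nonzero(invalid)[0]
    first_valid = int(np.nonzero(~invalid)[0][0])
    pos = np.where(~invalid, np.arange(len(values)), -1)
    filled = np.maximum.accumulate(pos)
    filled[filled < 0] = first_valid
    return values[filled], replaced.tolist()


def clip_aeeg_artifacts(series: AEEGSeries, threshold: float = AEEG_CLIP_UV) -> AEEGSeries:
    """Replace aEEG values above ``threshold`` uV (motion/interference)."""
    invalid = series.values > threshold
    cleaned, replaced = _carry_forward_replace(series.values, invalid)
    log = list(series.cleaning_log)
    log += [(int(i), f">{threshold:g}uV", float(series.values[i])) for i in replaced]
    return AEEGSeries(values=cleaned, rate=series.rate, time_h=series.time_h,
                      cleaning_log=log)


def trend_outlier_replace(values: np.ndarray, time_h: np.ndarray, rate: float,
                          mode: str) -> CleanSeries:
    """Replace points deviating from the least-squares linear trend.

    mode="absolute_5uV": |value - trend| > 5 uV (aEEG rule).
    mode="relative_20pct": |value - trend| > 0.20 * |trend| (SctO2 rule).
    The trend is fitted on all samples, outliers included.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise PreprocessError("series too short for trend fitting")
    t = np.asarray(time_h, dtype=float)
    if np.ptp(t) == 0:
        raise PreprocessError("degenerate (constant) time axis")
    coef = np.polynomial.polynomial.polyfit(t, values, 1)
    trend = np.polynomial.polynomial.polyval(t, coef)
    dev = np.abs(values - trend)
    if mode == "absolute_5uV":
        invalid = dev > AEEG_TREND_DEV_UV
    elif mode == "relative_20pct":
        invalid = dev > SCTO2_TREND_DEV_FRAC * np.abs(trend)
    else:
        raise PreprocessError(f"unknown mode {mode!r}")
    cleaned, replaced = _carry_forward_replace(values, invalid)
    return CleanSeries(values=cleaned, rate=rate, time_h=t,
                       detrend_order=0, replaced_indices=replaced)


def poly_detrend(values: np.ndarray, time_h: np.ndarray, rate: float,
                 order: int = 2) -> CleanSeries:
    """Subtract the least-squares polynomial of the given order."""
    values = np.asarray(values, dtype=float)
    if len(values) <= order + 1:
        raise PreprocessError("series too short for the requested order")
    t = np.asarray(time_h, dtype=float)
    coef = np.polynomial.polynomial.polyfit(t, values, order)
    resid = values - np.polynomial.polynomial.polyval(t, coef)
    return CleanSeries(values=resid, rate=rate, time_h=t, detrend_order=order)


def preprocess_eeg(eeg: np.ndarray, fs: float, scto2_rate: float,
                   filt: FilterSpec | None = None,
                   detrend_order: int = 2) -> CleanSeries:
    """Full EEG chain: band-pass -> envelope -> P90-P10 -> clean -> detrend."""
    if filt is None:
        filt = design_bandpass(fs=fs)
    filtered = apply_bandpass(np.asarray(eeg, dtype=float), filt)
    env = compute_aeeg(filtered, fs)
    series = envelope_downsample(env, fs, scto2_rate)
    series = clip_aeeg_artifacts(series)
    clean = trend_outlier_replace(series.values, series.time_h, series.rate,
                                  mode="absolute_5uV")
    out = poly_detrend(clean.values, clean.time_h, clean.rate, order=detrend_order)
    out.replaced_indices = sorted({i for i, _, _ in series.cleaning_log}
                                  | set(clean.replaced_indices))
    return out


def preprocess_scto2(scto2: np.ndarray, rate: float,
                     detrend_order: int = 2) -> CleanSeries:
    """SctO2 chain: +-20%-of-trend replacement -> polynomial detrend."""
    n = len(scto2)
    time_h = (np.arange(n) + 0.5) / rate / 3600.0
    clean = trend_outlier_replace(np.asarray(scto2, dtype=float), time_h, rate,
                                  mode="relative_20pct")
    out = poly_detrend(clean.values, clean.time_h, rate, order=detrend_order)
    out.replaced_indices = list(clean.replaced_indices)
    return out
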