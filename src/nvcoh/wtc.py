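"""Wavelet transform coherence (WTC) between aEEG and SctO2 series.

Analytic Morlet continuous wavelet transform (center frequency omega0 = 6),
cross-wavelet spectrum Wxy = Wx * conj(Wy), smoothing in time (Gaussian with
standard deviation equal to the scale) and in scale (boxcar over one octave,
i.e. as many voices as voices-per-octave), and magnitude-squared coherence

    R2(s, n) = |S(Wxy / s)|^2 / ( S(|Wx|^2 / s) * S(|Wy|^2 / s) )

bounded in [0, 1].  Without smoothing R2 is identically 1 — the smoothing is
what gives coherence its statistical meaning, and a unit test pins that
degeneracy.  Periods are reported in minutes on a log-uniform grid at
``voices_per_octave`` voices per octave (default 12, i.e. consecutive
periods differ by 2^(1/12)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

OMEGA0 = 6.0
#: Fourier factor: period = FOURIER_FACTOR * scale for the omega0=6 Morlet.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0 ** 2))
#: e-folding time of the Morlet envelope is sqrt(2) * scale.
COI_EFOLD = np.sqrt(2.0)


class WTCError(ValueError):
    pass


@dataclass
class CWTResult:
    """Complex CWT coefficients on a (scale x time) grid."""

    coefficients: np.ndarray    # complex, shape (n_periods, n_times)
    periods_min: np.ndarray     # minutes, strictly increasing, log-uniform
    dt: float                   # seconds
    coi_min: np.ndarray         # per-time maximum valid period, minutes

    @property
    def frequencies_mhz(self) -> np.ndarray:
        return 1000.0 / (self.periods_min * 60.0)

    @property
    def scales_s(self) -> np.ndarray:
        return self.periods_min * 60.0 / FOURIER_FACTOR

    @property
    def time_h(self) -> np.ndarray:
        return np.arange(self.coefficients.shape[1]) * self.dt / 3600.0


@dataclass
class CoherenceMap:
    """Magnitude-squared wavelet coherence on a (period x time) grid.

    ``r2`` may contain NaN where a map does not cover a period (e.g. after
    regridding a coarsely sampled subject onto a finer common grid).
    """

    r2: np.ndarray              # in [0, 1] (or NaN where uncovered)
    periods_min: np.ndarray
    time_h: np.ndarray
    coi_min: np.ndarray
    meta: dict = field(default_factory=dict)


def period_grid(dt: float, n: int, voices_per_octave: int = 12,
                period_limits: tuple[float | None, float | None] = (None, 400.0),
                ) -> np.ndarray:
    """Log-uniform period grid in minutes: ratio exactly 2^(1/vpo).

    The smallest period defaults to 2*dt (Nyquist); the largest to
    min(400 min, half the record length).
    """
    lo, hi = period_limits
    p_min_s = 2.0 * dt if lo is None else lo * 60.0
    p_max_s = n * dt / 2.0 if hi is None else min(hi * 60.0, n * dt / 2.0)
    if p_max_s < p_min_s:
        raise WTCError("record too short for the requested period range")
    n_voices = int(np.floor(voices_per_octave * np.log2(p_max_s / p_min_s))) + 1
    periods_s = p_min_s * 2.0 ** (np.arange(n_voices) / voices_per_octave)
    return periods_s / 60.0


def cone_of_influence(n_samples: int, dt: float) -> np.ndarray:
    """Per-time maximum valid period (minutes), e-folding COI for the Morlet.

    At distance tau from the nearer record edge, coefficients at scales above
    tau / sqrt(2) are contaminated; the valid period is proportional to tau.
    Symmetric about the record midpoint.
    """
    t = np.arange(n_samples) * dt
    tau = np.minimum(t, (n_samples - 1) * dt - t)
    return FOURIER_FACTOR * tau / COI_EFOLD / 60.0


def cwt_analytic_morlet(
    series: np.ndarray,
    dt: float,
    voices_per_octave: int = 12,
    period_limits: tuple[float | None, float | None] = (None, 400.0),
) -> CWTResult:
    """CWT with the analytic Morlet wavelet via FFT convolution.

    The series should already be detrended.  Zero-padding to the next power
    of two keeps wrap-around effects inside the cone of influence.  Wavelets
    are L2-normalized in the frequency domain (Torrence-Compo convention),
    so a sinusoid's |W| ridge sits at the scale whose Fourier period matches
    its period to within one voice.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 32:
        raise WTCError("series shorter than 32 samples")
    periods_min = period_grid(dt, n, voices_per_octave, period_limits)
    if n * dt < 4.0 * periods_min[0] * 60.0:
        raise WTCError("series shorter than 4 cycles of the smallest period")
    scales = periods_min * 60.0 / FOURIER_FACTOR

    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x, n=npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    pos = omega > 0
    W = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi ** -0.25 * np.sqrt(2.0 * np.pi / dt)
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        psi_hat[pos] = norm_const * np.sqrt(s) * np.exp(-0.5 * (s * omega[pos] - OMEGA0) ** 2)
        W[i] = np.fft.ifft(xhat * psi_hat)[:n]
    return CWTResult(coefficients=W, periods_min=periods_min, dt=dt,
                     coi_min=cone_of_influence(n, dt))


def cross_wavelet(Wx: CWTResult, Wy: CWTResult) -> np.ndarray:
    """Cross-wavelet spectrum Wxy = Wx * conj(Wy); |Wxy| is the common power."""
    if Wx.coefficients.shape != Wy.coefficients.shape or not np.allclose(
            Wx.periods_min, Wy.periods_min):
        raise WTCError("CWT grids do not match")
    return Wx.coefficients * np.conj(Wy.coefficients)


def smooth_field(field: np.ndarray, periods_min: np.ndarray, dt: float,
                 voices_per_octave: int = 12) -> np.ndarray:
    """Smooth a (scale x time) field in time then in scale.

    Time: per-scale Gaussian exp(-t^2 / (2 s^2)) (std = the scale, in time
    units).  Scale: boxcar moving average over ``voices_per_octave`` voices
    (one octave).  Both kernels are renormalized at the edges so a constant
    field passes through unchanged.
    """
    scales_samp = periods_min * 60.0 / FOURIER_FACTOR / dt
    out = np.empty_like(field, dtype=complex if np.iscomplexobj(field) else float)
    ones = np.ones(field.shape[1])
    for i, sigma in enumerate(scales_samp):
        half = int(np.ceil(4.0 * sigma))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        kern /= kern.sum()
        norm = fftconvolve(ones, kern, mode="same")
        out[i] = fftconvolve(field[i], kern, mode="same") / norm
    # scale-axis boxcar, renormalized at the edges
    k = int(voices_per_octave)
    norm_s = uniform_filter1d(np.ones(field.shape[0]), size=k, mode="constant")
    if np.iscomplexobj(field):
        sm = (uniform_filter1d(out.real, size=k, axis=0, mode="constant")
              + 1j * uniform_filter1d(out.imag, size=k, axis=0, mode="constant"))
    else:
        sm = uniform_filter1d(out.real, size=k, axis=0, mode="constant")
        sm = sm.astype(out.dtype)
    return sm / norm_s[:, None]


def wavelet_coherence(
    x_series: np.ndarray,
    y_series: np.ndarray,
    dt: float,
    voices_per_octave: int = 12,
    period_limits: tuple[float | None, float | None] = (None, 400.0),
    smoothing: bool = True,
) -> CoherenceMap:
    """Magnitude-squared wavelet coherence between two equal-rate series.

    ``smoothing=False`` exists only to demonstrate the R2 = 1 degeneracy of
    unsmoothed coherence; analyses always smooth.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape:
        raise WTCError("series lengths differ")
    Wx = cwt_analytic_morlet(x, dt, voices_per_octave, period_limits)
    Wy = cwt_analytic_morlet(y, dt, voices_per_octave, period_limits)
    Wxy = cross_wavelet(Wx, Wy)
    s = (Wx.periods_min * 60.0 / FOURIER_FACTOR)[:, None]
    if smoothing:
        S_xy = smooth_field(Wxy / s, Wx.periods_min, dt, voices_per_octave)
        S_xx = smooth_field(np.abs(Wx.coefficients) ** 2 / s, Wx.periods_min, dt,
                            voices_per_octave).real
        S_yy = smooth_field(np.abs(Wy.coefficients) ** 2 / s, Wx.periods_min, dt,
                            voices_per_octave).real
    else:
        S_xy = Wxy / s
        S_xx = np.abs(Wx.coefficients) ** 2 / s
        S_yy = np.abs(Wy.coefficients) ** 2 / s
    denom = S_xx * S_yy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.abs(S_xy) ** 2 / denom
    dead = denom <= 0
    if dead.any():
        logger.warning("zero wavelet power at %d pixels; coherence set to 0",
                       int(dead.sum()))
        r2[dead] = 0.0
    overshoot = np.nanmax(r2) - 1.0
    if overshoot > 1e-6:
        raise WTCError(f"coherence exceeds 1 by {overshoot:.3g}; numerical fault")
    np.clip(r2, 0.0, 1.0, out=r2)
    meta = {
        "wavelet": "analytic Morlet",
        "omega0": OMEGA0,
        "voices_per_octave": voices_per_octave,
        "time_smoothing": "gaussian, std = scale",
        "scale_smoothing": f"boxcar over {voices_per_octave} voices",
        "smoothing": smoothing,
        "dt_s": dt,
        "coi_efold": COI_EFOLD,
    }
    return CoherenceMap(r2=r2, periods_min=Wx.periods_min, time_h=Wx.time_h,
                        coi_min=Wx.coi_min, meta=meta)


def regrid_map(cmap: CoherenceMap, target_time_h: np.ndarray,
               target_periods_min: np.ndarray,
               allow_partial: bool = False) -> CoherenceMap:
    """Bilinear interpolation in (time, log-period) onto a common grid.

    Extrapolation is forbidden: target points outside the source coverage
    raise, unless ``allow_partial`` marks uncovered periods as NaN (the case
    of coarsely sampled subjects lacking short periods).
    """
    from scipy.interpolate import RegularGridInterpolator

    tt = np.asarray(target_time_h, dtype=float)
    tp = np.asarray(target_periods_min, dtype=float)
    t_in = (tt >= cmap.time_h[0] - 1e-12) & (tt <= cmap.time_h[-1] + 1e-12)
    p_in = (tp >= cmap.periods_min[0] * (1 - 1e-12)) & (
        tp <= cmap.periods_min[-1] * (1 + 1e-12))
    if not t_in.all():
        raise WTCError("target time grid outside source coverage")
    if not p_in.all() and not allow_partial:
        raise WTCError("target period grid outside source coverage")
    interp = RegularGridInterpolator(
        (np.log(cmap.periods_min), cmap.time_h), cmap.r2,
        method="linear", bounds_error=False, fill_value=np.nan)
    P, T = np.meshgrid(np.log(np.clip(tp, cmap.periods_min[0], cmap.periods_min[-1])),
                       np.clip(tt, cmap.time_h[0], cmap.time_h[-1]), indexing="ij")
    r2 = interp(np.stack([P.ravel(), T.ravel()], axis=-1)).reshape(len(tp), len(tt))
    r2[~p_in, :] = np.nan
    # COI re-evaluated analytically on the target grid
    span_h = cmap.time_h[-1] - cmap.time_h[0]
    tau = np.minimum(tt - cmap.time_h[0], cmap.time_h[0] + span_h - tt) * 3600.0
    coi = FOURIER_FACTOR * tau / COI_EFOLD / 60.0
    return CoherenceMap(r2=r2, periods_min=tp, time_h=tt, coi_min=coi,
                        meta=dict(cmap.meta, regridded=True))
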