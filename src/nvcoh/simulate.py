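"""Synthetic cohorts of paired EEG / cerebral-oximetry recordings.

The generator emulates the data geometry of a neonatal neurovascular-coupling
(NVC) study: per subject, a broadband EEG carrier (2–15 Hz) whose slow
amplitude modulation is shared — to a controllable degree — with a cerebral
tissue oxygenation (SctO2) series riding on red (AR(1)) noise.  Coupling is
concentrated in a configurable period band (default 25–60 min), so every
downstream stage (aEEG extraction, wavelet coherence, cluster statistics,
trajectory models) can be exercised against known ground truth.

Groups are labelled ``A`` and ``B``; in the clinical setting these correspond
to non-cooled (non-TH, milder encephalopathy, stronger coupling) and cooled
(TH) neonates respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps


class SimulationError(ValueError):
    """Raised when a cohort specification cannot be realized."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    Coupling strength is a unitless knob in [0, 1]: 0 produces independent
    EEG-envelope and SctO2 streams, 1 the strongest shared modulation the
    generator emits.  ``coupling_period_band`` is in minutes.
    """

    n_group_a: int = 10
    n_group_b: int = 10
    duration_h: float = 20.0
    eeg_rate: float = 256.0
    scto2_rate: float = 0.21
    coupling_period_band: tuple[float, float] = (25.0, 60.0)
    coupling_strength_a: float = 1.0
    coupling_strength_b: float = 0.0
    ar1_coeff: float = 0.8
    noise_sd: float = 2.0           # percent SctO2
    carrier_band: tuple[float, float] = (2.0, 15.0)
    baseline_scto2: float = 70.0    # percent
    scto2_swing: float = 3.0        # percent, amplitude of coupled modulation
    modulation_depth: float = 0.5   # fractional EEG envelope modulation at coupling 1
    carrier_rms_uv: float = 15.0    # microvolts
    lag_s: float = 0.0
    artifact_rate: float = 0.0      # events/hour
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.coupling_period_band
        if not (0.0 <= self.coupling_strength_a <= 1.0
                and 0.0 <= self.coupling_strength_b <= 1.0):
            raise SimulationError("coupling strengths must lie in [0, 1]")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise SimulationError("ar1_coeff must lie in [0, 1)")
        if not lo < hi:
            raise SimulationError("coupling_period_band must satisfy min < max")
        max_period = self.duration_h * 60.0 / 4.0
        if hi >= max_period:
            raise SimulationError(
                f"coupling_period_band max {hi} min needs >= 4 cycles; "
                f"minimum duration is {4.0 * hi / 60.0:.2f} h"
            )
        if self.n_group_a < 0 or self.n_group_b < 0:
            raise SimulationError("group sizes must be nonnegative")
        if self.scto2_rate <= 0 or self.eeg_rate <= 0:
            raise SimulationError("sampling rates must be positive")
        if self.eeg_rate <= 2.0 * self.carrier_band[1]:
            raise SimulationError("eeg_rate must exceed twice the carrier band top")


@dataclass
class RawRecording:
    """One subject's paired raw streams plus the injected ground truth."""

    subject_id: str
    group: str                  # "A" or "B"
    eeg: np.ndarray             # microvolts, at eeg_rate
    eeg_rate: float
    scto2: np.ndarray           # percent, at scto2_rate
    scto2_rate: float
    t0: float = 0.0
    truth: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        dur_eeg = len(self.eeg) / self.eeg_rate
        dur_ox = len(self.scto2) / self.scto2_rate
        if abs(dur_eeg - dur_ox) > 1.0 / self.scto2_rate + 1e-9:
            raise SimulationError(
                "EEG and SctO2 durations differ by more than one SctO2 sample"
            )
        if np.any(self.scto2 < 0.0) or np.any(self.scto2 > 100.0):
            raise SimulationError("SctO2 values must lie within [0, 100] percent")


def _subject_rng(master_seed: int, group: str, index: int) -> np.random.Generator:
    # Counter scheme: (master seed, group code, subject index) entropy tuple,
    # so cohorts are reproducible and subjects mutually independent.
    code = {"A": 1, "B": 2}[group]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), code, int(index)]))


def simulate_modulator(
    duration_h: float,
    period_band: tuple[float, float],
    rate: float,
    seed=None,
) -> np.ndarray:
    """Slow stochastic modulator: band-passed Gaussian noise, standardized.

    ``period_band`` is (min_period, max_period) in minutes.  The output is
    zero-mean, unit-variance, with spectral energy confined to
    [1/max_period, 1/min_period].  Band-limited noise is preferred over a
    single drifting oscillator so that energy spans the whole target band.
    """
    n = int(round(duration_h * 3600.0 * rate))
    if n < 64:
        raise SimulationError("rate * duration must yield at least 64 samples")
    lo_min, hi_min = period_band
    if not 0 < lo_min < hi_min:
        raise SimulationError("period band must satisfy 0 < min < max")
    min_duration_h = 4.0 * hi_min / 60.0
    if duration_h < min_duration_h:
        raise SimulationError(
            f"duration {duration_h} h too short for a {hi_min}-min band; "
            f"need at least {min_duration_h:.2f} h"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    f_lo = 1.0 / (hi_min * 60.0)
    f_hi = 1.0 / (lo_min * 60.0)
    spec = np.fft.rfft(white)
    spec[(f < f_lo) | (f > f_hi)] = 0.0
    m = np.fft.irfft(spec, n=n)
    m -= m.mean()
    sd = m.std()
    if sd == 0.0:
        raise SimulationError("degenerate modulator (no spectral support in band)")
    return m / sd


def _carrier(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS broadband carrier confined to ``band`` Hz (FFT brick-wall)."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(white)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def simulate_subject(spec: CohortSpec, group: str, subject_index: int) -> RawRecording:
    """Simulate one subject's paired EEG/SctO2 recording.

    EEG is ``carrier * (1 + depth * kappa * m(t))`` scaled to a 10–50 uV
    envelope regime; SctO2 is ``baseline + swing * kappa * m(t - lag) + AR(1)
    noise``, clipped to the oximeter's working range [15, 95]%.  ``kappa`` is
    the coupling strength of the subject's group.
    """
    if group not in ("A", "B"):
        raise SimulationError(f"group must be 'A' or 'B', got {group!r}")
    rng = _subject_rng(spec.seed, group, subject_index)
    kappa = spec.coupling_strength_a if group == "A" else spec.coupling_strength_b

    n_ox = int(round(spec.duration_h * 3600.0 * spec.scto2_rate))
    n_eeg = int(round(spec.duration_h * 3600.0 * spec.eeg_rate))
    t_ox = np.arange(n_ox) / spec.scto2_rate
    t_eeg = np.arange(n_eeg) / spec.eeg_rate

    m = simulate_modulator(spec.duration_h, spec.coupling_period_band,
                           spec.scto2_rate, rng)
    m_eeg = np.interp(t_eeg, t_ox, m)

    carrier = _carrier(n_eeg, spec.eeg_rate, spec.carrier_band, rng)
    envelope_gain = 1.0 + spec.modulation_depth * kappa * m_eeg
    np.clip(envelope_gain, 0.05, None, out=envelope_gain)
    eeg = spec.carrier_rms_uv * carrier * envelope_gain

    # AR(1) red noise at the oximeter rate, stationary innovation scaling.
    innov = rng.standard_normal(n_ox) * spec.noise_sd * np.sqrt(1.0 - spec.ar1_coeff ** 2)
    ar_noise = sps.lfilter([1.0], [1.0, -spec.ar1_coeff], innov)
    m_lagged = np.interp(t_ox - spec.lag_s, t_ox, m) if spec.lag_s != 0.0 else m
    scto2 = spec.baseline_scto2 + spec.scto2_swing * kappa * m_lagged + ar_noise
    np.clip(scto2, 15.0, 95.0, out=scto2)

    sid = f"{group}{subject_index:03d}"
    truth = {
        "coupling_strength": kappa,
        "coupling_period_band_min": tuple(spec.coupling_period_band),
        "lag_s": spec.lag_s,
        "artifact_times_s": [],
    }
    return RawRecording(subject_id=sid, group=group, eeg=eeg, eeg_rate=spec.eeg_rate,
                        scto2=scto2, scto2_rate=spec.scto2_rate, truth=truth)


def simulate_cohort(spec: CohortSpec) -> list[RawRecording]:
    """Simulate the full two-group cohort described by ``spec``.

    Artifacts are injected at ``spec.artifact_rate`` events/hour (0 disables).
    """
    recs = []
    for i in range(spec.n_group_a):
        recs.append(simulate_subject(spec, "A", i))
    for i in range(spec.n_group_b):
        recs.append(simulate_subject(spec, "B", i))
    if spec.artifact_rate > 0.0:
        recs = [
            inject_artifacts(r, spec.artifact_rate,
                             seed=np.random.SeedSequence(
                                 [int(spec.seed), 3, k]))
            for k, r in enumerate(recs)
        ]
    return recs


def inject_artifacts(rec: RawRecording, rate: float, seed=None) -> RawRecording:
    """Insert motion/interference artifacts at Poisson-distributed times.

    Each event adds a high-amplitude EEG burst lasting one SctO2 sampling
    interval (driving the downsampled aEEG above the 25 uV rejection
    threshold) and a step deviation on SctO2 exceeding 20% of the local
    trend.  Ground-truth event times are recorded in ``truth``.
    """
    if rate < 0:
        raise SimulationError("artifact rate must be >= 0")
    if rate == 0.0:
        return rec
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(seed)
    duration_h = len(rec.eeg) / rec.eeg_rate / 3600.0
    n_events = rng.poisson(rate * duration_h)
    times = np.sort(rng.uniform(0.0, duration_h * 3600.0, size=n_events))

    eeg = rec.eeg.copy()
    scto2 = rec.scto2.copy()
    ox_interval = 1.0 / rec.scto2_rate
    for t in times:
        i0 = int(t * rec.eeg_rate)
        i1 = min(len(eeg), i0 + int(np.ceil(ox_interval * rec.eeg_rate)))
        # burst large enough that the P90-P10 envelope in this window > 25 uV
        eeg[i0:i1] += 120.0 * rng.standard_normal(i1 - i0)
        j0 = int(t * rec.scto2_rate)
        j1 = min(len(scto2), j0 + 3)
        local = float(np.mean(scto2[max(0, j0 - 5):j0 + 1])) if j0 > 0 else float(scto2[0])
        step = 0.3 * abs(local) * (1 if rng.random() < 0.5 else -1)
        scto2[j0:j1] = np.clip(scto2[j0:j1] + step, 0.0, 100.0)

    truth = dict(rec.truth or {})
    truth["artifact_times_s"] = [float(t) for t in times]
    out = replace(rec, eeg=eeg, scto2=np.clip(scto2, 15.0, 95.0), truth=truth)
    return out
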