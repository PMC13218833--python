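"""End-to-end orchestration: preprocess -> WTC -> cluster test -> summaries.

``PipelineConfig`` defaults encode the published analysis settings: 2–15 Hz
equiripple band-pass, 25 uV aEEG ceiling, +-5 uV / +-20% trend-deviation
replacement, second-order detrending, analytic Morlet WTC at 12 voices per
octave on a 1–400 min period grid, first 20 h of recording, cluster-forming
p < 0.05, 1000 permutations, one-tailed inference, Bonferroni over seven
hourly contrasts in the 0–6 h window.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import preprocess as pp
from . import summary as sm
from . import wtc
from .simulate import RawRecording

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # filtering (signal_preprocess)
    passband_hz: tuple[float, float] = (2.0, 15.0)
    stopband_hz: tuple[float, float] = (1.0, 20.0)
    filter_atten_db: float = 60.0
    # aEEG cleaning thresholds
    aeeg_clip_uv: float = 25.0
    aeeg_trend_dev_uv: float = 5.0
    scto2_trend_dev_frac: float = 0.20
    detrend_order: int = 2
    # wavelet coherence
    voices_per_octave: int = 12
    period_limits_min: tuple[float | None, float | None] = (1.0, 400.0)
    # analysis span
    analysis_hours: float = 20.0
    # common grid for group statistics
    grid_time_step_min: float = 10.0
    # cluster test
    n_permutations: int = 1000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    tail: str = "a>b"
    # band selection: "auto" (from the cluster test) or (lo, hi) minutes
    band: object = "auto"
    # trajectory statistics
    contrast_hours: tuple = tuple(range(7))
    window_h: tuple[float, float] = (0.0, 6.0)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    config: PipelineConfig
    band: tuple[float, float] | None
    band_result: cl.BandResult | None
    cluster_result: cl.ClusterTestResult | None
    trajectories: pd.DataFrame
    lme: sm.LMEFit
    contrasts: sm.ContrastSet
    window_t: float
    window_p: float
    subject_means: pd.DataFrame
    maps: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def subject_map(rec: RawRecording, config: PipelineConfig) -> wtc.CoherenceMap:
    """Preprocess one subject's streams and compute the coherence map."""
    keep = int(config.analysis_hours * 3600.0 * rec.eeg_rate)
    eeg = rec.eeg[:keep]
    keep_ox = int(config.analysis_hours * 3600.0 * rec.scto2_rate)
    scto2 = rec.scto2[:keep_ox]
    filt = pp.design_bandpass(fs=rec.eeg_rate, passband=config.passband_hz,
                              stopband=config.stopband_hz,
                              atten_db=config.filter_atten_db)
    aeeg = pp.preprocess_eeg(eeg, rec.eeg_rate, rec.scto2_rate, filt=filt,
                             detrend_order=config.detrend_order)
    ox = pp.preprocess_scto2(scto2, rec.scto2_rate,
                             detrend_order=config.detrend_order)
    n = min(len(aeeg.values), len(ox.values))
    dt = 1.0 / rec.scto2_rate
    lo, hi = config.period_limits_min
    # a subject's native grid cannot resolve periods below 2*dt
    lo_eff = None if lo is None else max(lo, 2.0 * dt / 60.0)
    return wtc.wavelet_coherence(aeeg.values[:n], ox.values[:n], dt,
                                 voices_per_octave=config.voices_per_octave,
                                 period_limits=(lo_eff, hi))


def common_grid(config: PipelineConfig, maps: list[wtc.CoherenceMap]):
    """Shared (time, period) grid covering every subject's map support."""
    t_lo = max(m.time_h[0] for m in maps)
    t_hi = min(m.time_h[-1] for m in maps)
    step_h = config.grid_time_step_min / 60.0
    tt = np.arange(t_lo, t_hi + 1e-9, step_h)
    p_lo = min(m.periods_min[0] for m in maps)
    p_hi = max(m.periods_min[-1] for m in maps)
    vpo = config.voices_per_octave
    n_voices = int(np.floor(vpo * np.log2(p_hi / p_lo))) + 1
    pp_grid = p_lo * 2.0 ** (np.arange(n_voices) / vpo)
    return tt, pp_grid


def analyze_cohort(recordings: list[RawRecording],
                   config: PipelineConfig) -> PipelineReport:
    """Run the full analysis on in-memory recordings."""
    t_start = time.time()
    maps: dict[str, wtc.CoherenceMap] = {}
    groups: dict[str, str] = {}
    try:
        for rec in recordings:
            maps[rec.subject_id] = subject_map(rec, config)
            groups[rec.subject_id] = rec.group
    except Exception as exc:
        raise PipelineError("preprocess/wtc", str(exc)) from exc

    try:
        tt, pgrid = common_grid(config, list(maps.values()))
        regridded = {sid: wtc.regrid_map(m, tt, pgrid, allow_partial=True)
                     for sid, m in maps.items()}
    except Exception as exc:
        raise PipelineError("regrid", str(exc)) from exc

    ids_a = [s for s in regridded if groups[s] == "A"]
    ids_b = [s for s in regridded if groups[s] == "B"]
    maps_a = [regridded[s] for s in ids_a]
    maps_b = [regridded[s] for s in ids_b]

    cluster_result = None
    band_result = None
    if config.band == "auto":
        try:
            cluster_result = cl.cluster_test(
                maps_a, maps_b, n_perm=config.n_permutations,
                alpha=config.alpha, alpha_cluster=config.cluster_alpha,
                tail=config.tail, seed=config.seed)
            band_result = cl.extract_band(cluster_result)
        except Exception as exc:
            raise PipelineError("cluster", str(exc)) from exc
        band = ((band_result.min_period_min, band_result.max_period_min)
                if band_result.found else None)
    else:
        band = tuple(config.band)

    if band is None:
        raise PipelineError(
            "band", "no significant cluster found and no band override given")

    try:
        trajs = [sm.band_mean_timecourse(regridded[s], band, s, groups[s])
                 for s in regridded]
        df = sm.trajectories_frame(trajs)
        hourly = sm.thin_to_hourly(df)
        lme = sm.fit_lme(hourly)
        contrasts = sm.hourly_contrasts(lme, hours=config.contrast_hours)
        t_stat, p_val, means = sm.window_mean_test(df, window=config.window_h,
                                                   tail=config.tail)
    except Exception as exc:
        raise PipelineError("summary", str(exc)) from exc

    provenance = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": config.seed,
        "n_group_a": len(ids_a),
        "n_group_b": len(ids_b),
        "elapsed_s": round(time.time() - t_start, 3),
        "versions": _versions(),
    }
    return PipelineReport(config=config, band=band, band_result=band_result,
                          cluster_result=cluster_result, trajectories=df,
                          lme=lme, contrasts=contrasts, window_t=t_stat,
                          window_p=p_val, subject_means=means,
                          maps=regridded, provenance=provenance)


def run_pipeline(config: PipelineConfig, manifest_path, out_dir) -> PipelineReport:
    """File-based entry point: read a cohort manifest, analyze, write artifacts."""
    from . import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        manifest = nio.read_manifest(manifest_path)
        base = Path(manifest_path).parent
        recordings = [nio.read_streams(row, base, config.analysis_hours)
                      for _, row in manifest.iterrows()]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc

    report = analyze_cohort(recordings, config)
    write_report(report, out)
    return report


def write_report(report: PipelineReport, out_dir) -> None:
    from . import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.trajectories.to_csv(out / "trajectories.csv", index=False)
    report.lme.params.to_csv(out / "lme_coefficients.csv")
    report.contrasts.table.to_csv(out / "hourly_contrasts.csv", index=False)
    report.subject_means.to_csv(out / "window_means.csv", index=False)
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for sid, m in report.maps.items():
        nio.write_map(maps_dir / f"{sid}.csv", m)
    summary = {
        "band_min_period_min": report.band[0],
        "band_max_period_min": report.band[1],
        "window_t": report.window_t,
        "window_p_one_tailed": report.window_p,
        "lme": {k: report.lme.params.loc[k, "estimate"]
                for k in report.lme.params.index},
        "provenance": report.provenance,
    }
    if report.cluster_result is not None:
        res = report.cluster_result
        summary["clusters"] = [
            {"mass": c.mass, "p_perm": c.p_perm, "sign": c.sign,
             "coi_fraction": c.coi_fraction, "n_pixels": int(c.pixels.sum())}
            for c in res.clusters]
        np.savetxt(out / "z_map.csv", res.z_map, delimiter=",")
        np.savetxt(out / "significant_mask.csv",
                   res.significant_mask.astype(int), delimiter=",", fmt="%d")
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=float))


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {"nvcoh": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "statsmodels": statsmodels.__version__}
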