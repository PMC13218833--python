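"""File formats: EDF (EEG), CSV (SctO2, manifests, maps, trajectories).

EEG is exchanged as single- or multi-channel EDF; reading goes through MNE.
Writing uses a minimal EDF encoder (256-byte header blocks, int16 records)
sufficient for the single bipolar channel the pipeline consumes.  SctO2 is a
two-column CSV ``time_s,scto2_pct``.  A cohort manifest CSV ties subjects to
files and group labels ("non-TH" = group A reference, "TH" = group B).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RawRecording
from .wtc import CoherenceMap

GROUP_LABELS = {"A": "non-TH", "B": "TH"}
GROUP_CODES = {v: k for k, v in GROUP_LABELS.items()}


class IOError_(ValueError):
    pass


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise IOError_(f"EDF field too wide: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(path, signal_uv: np.ndarray, fs: float,
              channel="C3-C4") -> None:
    """Write EEG (microvolts) as EDF with 1-s data records.

    ``signal_uv`` is 1-D (one channel) or (n_channels, n_samples) with
    ``channel`` a matching list of labels.  The sampling rate must be an
    integer (samples per 1-s record).  Signals are truncated to whole
    records; int16 quantization spans each channel's physical range
    symmetrically.
    """
    fs_i = int(round(fs))
    if abs(fs - fs_i) > 1e-9 or fs_i <= 0:
        raise IOError_("EDF writer requires an integer sampling rate")
    x = np.atleast_2d(np.asarray(signal_uv, dtype=float))
    labels = [channel] if isinstance(channel, str) else list(channel)
    if len(labels) != x.shape[0]:
        raise IOError_("channel labels do not match signal shape")
    ns = x.shape[0]
    n_rec = x.shape[1] // fs_i
    if n_rec == 0:
        raise IOError_("signal shorter than one EDF record")
    x = x[:, : n_rec * fs_i]
    phys = np.maximum(1e-6, np.max(np.abs(x), axis=1))
    dig_min, dig_max = -32768, 32767
    digital = np.clip(np.round(x * (dig_max / phys[:, None])),
                      dig_min, dig_max).astype("<i2")

    header = [
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate 01-JAN-2000 X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(ns, 4),
    ]
    # per-signal fields: each field is written for every signal in turn
    header += [_ascii(lbl, 16) for lbl in labels]
    header += [_ascii("", 80)] * ns
    header += [_ascii("uV", 8)] * ns
    header += [_ascii(f"{-p:.6g}"[:8], 8) for p in phys]
    header += [_ascii(f"{p:.6g}"[:8], 8) for p in phys]
    header += [_ascii(dig_min, 8)] * ns
    header += [_ascii(dig_max, 8)] * ns
    header += [_ascii("", 80)] * ns
    header += [_ascii(fs_i, 8)] * ns
    header += [_ascii("", 32)] * ns
    records = digital.reshape(ns, n_rec, fs_i).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(b"".join(header))
        fh.write(records.tobytes())


def read_edf_channel(path, channels=("C3-C4",), fallback_pair=("C3", "C4")):
    """Read the bipolar EEG series (microvolts) and its rate from an EDF.

    If a pre-derived bipolar channel (first of ``channels``) is present it is
    used directly; otherwise the difference of ``fallback_pair`` is formed.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = raw.ch_names
    fs = float(raw.info["sfreq"])
    for ch in channels:
        if ch in names:
            data = raw.get_data(picks=[ch])[0] * 1e6
            return data, fs
    a, b = fallback_pair
    if a in names and b in names:
        data = (raw.get_data(picks=[a])[0] - raw.get_data(picks=[b])[0]) * 1e6
        return data, fs
    raise IOError_(
        f"EDF {path} has none of channels {channels} nor pair {fallback_pair}; "
        f"found {names}")


def write_scto2_csv(path, scto2_pct: np.ndarray, rate: float) -> None:
    t = np.arange(len(scto2_pct)) / rate
    pd.DataFrame({"time_s": t, "scto2_pct": scto2_pct}).to_csv(path, index=False)


def read_scto2_csv(path):
    """Returns (values percent, rate Hz) from a time_s,scto2_pct CSV."""
    df = pd.read_csv(path)
    if not {"time_s", "scto2_pct"} <= set(df.columns):
        raise IOError_(f"{path}: expected columns time_s,scto2_pct")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise IOError_(f"{path}: fewer than 2 samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or np.any(np.abs(dts - dt) > 0.01 * dt):
        raise IOError_(f"{path}: unparseable or irregular sampling rate")
    return df["scto2_pct"].to_numpy(dtype=float), 1.0 / dt


def write_cohort(recordings: list[RawRecording], out_dir, seed=None) -> Path:
    """Write a cohort to disk (EDF + CSV per subject) plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        edf = out / f"{rec.subject_id}.edf"
        csv = out / f"{rec.subject_id}_scto2.csv"
        write_edf(edf, rec.eeg, rec.eeg_rate)
        write_scto2_csv(csv, rec.scto2, rec.scto2_rate)
        rows.append({
            "subject_id": rec.subject_id,
            "group": GROUP_LABELS[rec.group],
            "edf_path": edf.name,
            "scto2_path": csv.name,
            "scto2_rate_hz": rec.scto2_rate,
            "seed": seed if seed is not None else "",
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "edf_path", "scto2_path"}
    if not required <= set(df.columns):
        raise IOError_(f"manifest missing columns {required - set(df.columns)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise IOError_(f"duplicate subject_id in manifest: {dupes}")
    bad = set(df["group"]) - set(GROUP_CODES)
    if bad:
        raise IOError_(f"unknown group labels {bad}; expected {set(GROUP_CODES)}")
    return df


def read_streams(row, base_dir=".", analysis_hours: float = 20.0,
                 channels=("C3-C4",), fallback_pair=("C3", "C4")) -> RawRecording:
    """Load one manifest row into a RawRecording, cropped to the first
    ``analysis_hours`` hours of joint coverage."""
    base = Path(base_dir)
    eeg, fs = read_edf_channel(base / row["edf_path"], channels, fallback_pair)
    scto2, ox_rate = read_scto2_csv(base / row["scto2_path"])
    overlap_s = min(len(eeg) / fs, len(scto2) / ox_rate)
    if overlap_s < 3600.0:
        raise IOError_(f"{row['subject_id']}: less than 1 h of stream overlap")
    keep_s = min(overlap_s, analysis_hours * 3600.0)
    eeg = eeg[: int(keep_s * fs)]
    scto2 = scto2[: int(keep_s * ox_rate)]
    return RawRecording(subject_id=str(row["subject_id"]),
                        group=GROUP_CODES[row["group"]],
                        eeg=eeg, eeg_rate=fs, scto2=scto2, scto2_rate=ox_rate)


def write_map(path, cmap: CoherenceMap) -> None:
    """Serialize a coherence map: columnar CSV plus a JSON metadata block."""
    path = Path(path)
    n_p, n_t = cmap.r2.shape
    df = pd.DataFrame(cmap.r2,
                      index=pd.Index(cmap.periods_min, name="period_min"),
                      columns=np.round(cmap.time_h, 9))
    df.to_csv(path)
    side = {"time_h": cmap.time_h.tolist(), "coi_min": cmap.coi_min.tolist(),
            "meta": {k: v for k, v in cmap.meta.items()}}
    Path(str(path) + ".json").write_text(json.dumps(side, default=float))


def read_map(path) -> CoherenceMap:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    side = json.loads(Path(str(path) + ".json").read_text())
    return CoherenceMap(r2=df.to_numpy(dtype=float),
                        periods_min=df.index.to_numpy(dtype=float),
                        time_h=np.asarray(side["time_h"], dtype=float),
                        coi_min=np.asarray(side["coi_min"], dtype=float),
                        meta=side.get("meta", {}))
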