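"""Readers and writers: EDF recordings, marking CSV, feature tables, config.

EDF (European Data Format) is the clinical standard for EEG exchange.
Reading goes through :mod:`mne`; writing is implemented here directly
against the EDF specification (256-byte fixed header, 256 bytes per
signal, 16-bit little-endian samples in 1-second data records) since the
environment provides no EDF writer.  Markings and interval features
travel as plain CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureSeries
from .preprocess import Segmentation
from .recording import Interval, Marking, Recording


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    Physical ranges are symmetric per channel; quantization error is at
    most one part in 2**15 of the channel's peak amplitude.  The sampling
    rate must be a whole number of samples per second.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    ns = rec.n_channels

    pmax = np.maximum(np.abs(rec.signal).max(axis=1), 1e-6)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [_pad(lbl, 16) for lbl in rec.channel_labels],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{-p:.6g}"[:8], 8) for p in pmax],
        [_pad(f"{p:.6g}"[:8], 8) for p in pmax],
        [_pad("-32768", 8)] * ns,
        [_pad("32767", 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(spr), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    sig_header = b"".join(b"".join(f) for f in fields)

    # digital conversion: EDF maps [phys_min, phys_max] onto [dig_min, dig_max]
    scale = (32767 - (-32768)) / (2 * pmax)
    digital = np.clip(
        np.round((rec.signal[:, : n_rec * spr] + pmax[:, None]) * scale[:, None]) - 32768,
        -32768, 32767,
    ).astype("<i2")
    # records: for each second, all samples of signal 0, then signal 1, ...
    records = digital.reshape(ns, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(records.tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValueError("mixed sampling rates are not supported")
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def write_marking(marking: Marking, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.label) for iv in marking],
        columns=["start_s", "end_s", "label"],
    )
    df.to_csv(path, index=False)
    return path


def read_marking(path: str | Path) -> Marking:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"marking CSV must have columns {sorted(required)}")
    return Marking(tuple(Interval(r.start_s, r.end_s, r.label) for r in df.itertuples()))


def write_features(fs: FeatureSeries, path: str | Path, *, store_E: bool = False) -> Path:
    """Interval-level features as CSV; optionally the dense E(t) as .npy."""
    path = Path(path)
    bounds = fs.segmentation.interval_bounds
    df = pd.DataFrame(
        {
            "interval_index": np.arange(fs.segmentation.M),
            "start_s": [b[0] for b in bounds],
            "end_s": [b[1] for b in bounds],
            "e_m": fs.e,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    if store_E:
        np.save(path.with_suffix(".E.npy"), fs.E)
    return path


def read_features(path: str | Path) -> FeatureSeries:
    path = Path(path)
    df = pd.read_csv(path)
    M = len(df)
    interval_s = float(df["end_s"].iloc[0] - df["start_s"].iloc[0])
    seg = Segmentation(M=M, interval_s=interval_s)
    e_path = path.with_suffix(".E.npy")
    E = np.load(e_path) if e_path.exists() else np.repeat(df["e_m"].to_numpy(), 1)
    return FeatureSeries(E=E, e=df["e_m"].to_numpy(), fs=float("nan"), segmentation=seg)


def write_detections(results, subjects, path: str | Path) -> Path:
    """Detections CSV: subject, interval_index, start_s, end_s, score, flag."""
    rows = []
    for subj, res in zip(subjects, results):
        bounds = subj.features.segmentation.interval_bounds
        for m, (score, flag) in enumerate(zip(res.scores, res.flags)):
            rows.append(dict(subject=subj.name, interval_index=m,
                             start_s=bounds[m][0], end_s=bounds[m][1],
                             score=score, flag=bool(flag)))
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.10g")
    return Path(path)


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return cls(**d)


def load_config(path: str | Path):
    """Load a pipeline config from YAML; unknown keys are rejected."""
    from .pipeline import PipelineConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)
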