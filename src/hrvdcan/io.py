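"""Readers and writers for the pipeline's plain-text interchange formats.

CSV carries all series (ECG, beats, NN, blood pressure, cohort tables),
JSON carries test annotations, YAML carries configuration (Ewing
thresholds, run settings).  EDF input is supported through mne when it is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autonomic_tests import TestThreshold
from .series import BeatSeries, ECGRecord, EvenSeries, NNSeries


# ---------------------------------------------------------------- ECG

def read_ecg_csv(path: str | Path, fs: float | None = None) -> ECGRecord:
    """Two-column CSV (t_s, mV); the sampling rate is inferred when omitted."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        dt = np.diff(t)
        if dt.size == 0 or np.ptp(dt) > 1e-6 * dt.mean():
            raise ValueError("cannot infer fs from non-uniform time column")
        fs = 1.0 / dt.mean()
    return ECGRecord(x, fs=fs, start_time=float(t[0]) if t.size else 0.0)


def write_ecg_csv(path: str | Path, ecg: ECGRecord) -> None:
    pd.DataFrame({"t_s": ecg.times, "mV": ecg.samples}).to_csv(path, index=False)


def read_ecg_edf(path: str | Path, channel: int | str = 0) -> ECGRecord:
    """Read one ECG channel from an EDF file (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, int):
        channel = raw.ch_names[channel]
    data = raw.get_data(picks=[channel])[0]
    return ECGRecord(data, fs=float(raw.info["sfreq"]), label=channel)


# ---------------------------------------------------------------- beats / NN

def write_beats_csv(path: str | Path, beats: BeatSeries) -> None:
    pd.DataFrame({"t_s": beats.r_times, "amplitude": beats.r_amplitudes,
                  "label": beats.labels}).to_csv(path, index=False)


def read_beats_csv(path: str | Path) -> BeatSeries:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy(dtype=object) if "label" in df else None
    return BeatSeries(df["t_s"].to_numpy(dtype=float),
                      df["amplitude"].to_numpy(dtype=float), labels)


def write_nn_csv(path: str | Path, nn: NNSeries) -> None:
    pd.DataFrame({"onset_s": nn.onset_times, "nn_ms": nn.intervals,
                  "contiguous": nn.contiguous.astype(int)}).to_csv(path, index=False)


def read_nn_csv(path: str | Path) -> NNSeries:
    df = pd.read_csv(path)
    contig = (df["contiguous"].to_numpy(dtype=bool)
              if "contiguous" in df else None)
    return NNSeries(df["nn_ms"].to_numpy(dtype=float),
                    df["onset_s"].to_numpy(dtype=float), contig)


# ---------------------------------------------------------------- even series

def write_even_csv(path: str | Path, series: EvenSeries,
                   value_name: str = "value") -> None:
    pd.DataFrame({"t_s": series.times,
                  value_name: series.values}).to_csv(path, index=False)


def read_even_csv(path: str | Path) -> EvenSeries:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.ptp(dt) > 1e-6 * abs(dt.mean()):
        raise ValueError("time column is not uniformly sampled")
    return EvenSeries(df.iloc[:, 1].to_numpy(dtype=float), fs=1.0 / dt.mean(),
                      start_time=float(t[0]))


# ---------------------------------------------------------------- annotations / config

def read_annotations_json(path: str | Path) -> dict:
    """Test annotations: {"test": ..., "windows": {name: [start_s, end_s]}, ...}."""
    with open(path) as fh:
        return json.load(fh)


def read_ewing_thresholds_yaml(path: str | Path) -> dict[str, TestThreshold]:
    """Ewing threshold table: {test: {normal_min: x, abnormal_max: y}, ...}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {test: TestThreshold(**vals) for test, vals in raw.items()}


def write_ewing_thresholds_yaml(path: str | Path,
                                thresholds: dict[str, TestThreshold]) -> None:
    raw = {test: {"normal_min": th.normal_min, "abnormal_max": th.abnormal_max}
           for test, th in thresholds.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "condition", "index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
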