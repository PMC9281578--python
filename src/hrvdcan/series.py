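"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* times are seconds from record start,
* intervals are milliseconds,
* blood pressures are mmHg,
* all analysis windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: beat labels
NORMAL = "normal"
PREMATURE = "premature"
ARTIFACT = "artifact"
BEAT_LABELS = (NORMAL, PREMATURE, ARTIFACT)


class UndefinedResultWarning(UserWarning):
    """A quantity is mathematically undefined for this input (reported as NaN)."""


@dataclass
class ECGRecord:
    """Single-lead ECG: uniformly sampled voltage."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    label: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class BeatSeries:
    """Detected R peaks: occurrence times, refined amplitudes, per-beat labels."""

    r_times: np.ndarray
    r_amplitudes: np.ndarray
    labels: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.r_amplitudes = np.asarray(self.r_amplitudes, dtype=float)
        if self.labels is None:
            self.labels = np.full(self.r_times.size, NORMAL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.r_times.size != self.r_amplitudes.size:
            raise ValueError("r_times and r_amplitudes must have equal length")
        if self.labels.size != self.r_times.size:
            raise ValueError("labels must have one entry per beat")
        if self.r_times.size > 1 and not np.all(np.diff(self.r_times) > 0):
            raise ValueError("r_times must be strictly increasing")
        bad = set(self.labels) - set(BEAT_LABELS)
        if bad:
            raise ValueError(f"unknown beat labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.r_times.size


@dataclass
class NNSeries:
    """Normal-to-normal intervals with onset times and contiguity flags.

    ``contiguous[i]`` is True when interval ``i`` immediately follows
    interval ``i-1`` (no rejected beat in between); ``contiguous[0]`` is
    always False.  Successive-difference statistics (pNN50, RMSSD) only use
    pairs whose second member is contiguous.
    """

    intervals: np.ndarray
    onset_times: np.ndarray
    contiguous: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.contiguous is None:
            c = np.ones(self.intervals.size, dtype=bool)
            if c.size:
                c[0] = False
            self.contiguous = c
        else:
            self.contiguous = np.asarray(self.contiguous, dtype=bool)
        if self.intervals.size != self.onset_times.size:
            raise ValueError("intervals and onset_times must have equal length")
        if self.contiguous.size != self.intervals.size:
            raise ValueError("contiguous flags must have one entry per interval")
        if np.any(self.intervals <= 0):
            raise ValueError("NN intervals must be positive")
        if self.onset_times.size > 1 and not np.all(np.diff(self.onset_times) > 0):
            raise ValueError("onset_times must be strictly increasing")
        if self.contiguous.size:
            self.contiguous[0] = False

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration(self) -> float:
        """Seconds spanned from first interval onset to last interval end."""
        if not len(self):
            return 0.0
        return float(self.onset_times[-1] + self.intervals[-1] / 1000.0 - self.onset_times[0])

    def successive_diffs(self) -> np.ndarray:
        """NN(i) - NN(i-1) over contiguous pairs only (ms)."""
        idx = np.flatnonzero(self.contiguous)
        return self.intervals[idx] - self.intervals[idx - 1]

    def slice(self, start: float, end: float) -> "NNSeries":
        """Intervals whose onset falls in ``[start, end)``; flags preserved."""
        mask = (self.onset_times >= start) & (self.onset_times < end)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no NN intervals in window [{start}, {end})")
        contig = self.contiguous[idx].copy()
        contig[0] = False
        return NNSeries(self.intervals[idx], self.onset_times[idx], contig)


@dataclass
class EvenSeries:
    """Uniformly sampled series (resampled tachogram, SBP, EDR amplitude)."""

    values: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.fs


@dataclass
class MultiscaleProfile:
    """(tau seconds, value) pairs of a multiscale statistic, MSE(tau) or alpha(tau)."""

    tau: np.ndarray
    values: np.ndarray
    beat_scales: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.beat_scales is None:
            self.beat_scales = np.arange(1, self.tau.size + 1)
        else:
            self.beat_scales = np.asarray(self.beat_scales)
        if self.tau.size != self.values.size:
            raise ValueError("tau and values must have equal length")
        if self.tau.size > 1 and not np.all(np.diff(self.tau) > 0):
            raise ValueError("tau grid must be ascending")

    def band_mean(self, lo: float, hi: float,
                  closed: str = "left") -> float:
        """Unweighted mean of values with tau in the band.

        ``closed``: 'left' for [lo, hi), 'both' for [lo, hi], 'neither'
        for (lo, hi).  Returns NaN (with a warning) if no point falls in
        the band.
        """
        if closed == "left":
            mask = (self.tau >= lo) & (self.tau < hi)
        elif closed == "both":
            mask = (self.tau >= lo) & (self.tau <= hi)
        elif closed == "neither":
            mask = (self.tau > lo) & (self.tau < hi)
        else:
            raise ValueError("closed must be 'left', 'both' or 'neither'")
        vals = self.values[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(
                f"no profile points with tau in ({lo}, {hi}); band mean undefined",
                UndefinedResultWarning, stacklevel=2)
            return float("nan")
        return float(vals.mean())
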