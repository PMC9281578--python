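"""From raw ECG to a clean NN series, plus ECG-derived respiration.

R peaks are found with a derivative-and-threshold detector and refined to
sub-sample resolution by parabolic interpolation; premature beats and
artifacts are removed by a deterministic running-median rule (with an
optional manual-override list standing in for the interactive review step);
ECG-derived respiration reads the breathing rate off the respiratory
amplitude modulation of the QRS complexes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from . import spectral
from .series import (ARTIFACT, NORMAL, PREMATURE, BeatSeries, ECGRecord,
                     EvenSeries, NNSeries, UndefinedResultWarning)


def _parabolic_vertex(y_m1: float, y_0: float, y_p1: float) -> tuple[float, float]:
    """Vertex (offset in samples from the middle point, height) of the parabola
    through three equally spaced samples."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom == 0:
        return 0.0, y_0
    delta = 0.5 * (y_m1 - y_p1) / denom
    height = y_0 - 0.25 * (y_m1 - y_p1) * delta
    return float(delta), float(height)


def detect_r_peaks(ecg: ECGRecord, threshold_factor: float = 0.3,
                   refractory_s: float = 0.25) -> BeatSeries:
    """Derivative-and-threshold R-peak detection with parabolic refinement.

    The squared, smoothed derivative is compared against an adaptive
    threshold (``threshold_factor`` times its local 3-s running maximum, so
    slow amplitude modulation does not drop beats); candidates closer than
    ``refractory_s`` are merged.  Each surviving peak is moved to the local
    ECG maximum and refined by fitting a parabola to the 3 samples around
    it, giving sub-sample peak times and heights.  Assumes upright
    (positive) R waves.
    """
    x, fs = ecg.samples, ecg.fs
    if x.size / fs < 10:
        raise ValueError("ECG must be at least 10 s long")
    if np.ptp(x) == 0:
        warnings.warn("constant ECG signal: no beats detected", UserWarning,
                      stacklevel=2)
        return BeatSeries(np.empty(0), np.empty(0))

    deriv = np.gradient(x) * fs
    feat = deriv ** 2
    smooth_n = max(1, int(round(0.03 * fs)))
    feat = np.convolve(feat, np.ones(smooth_n) / smooth_n, mode="same")

    local_max = ndimage.maximum_filter1d(feat, size=int(round(3.0 * fs)),
                                         mode="nearest")
    thresh = threshold_factor * local_max
    # guard against triggering on numerical noise in beat-free stretches
    floor = 1e-6 * feat.max()
    candidates, _ = sps.find_peaks(feat, height=np.maximum(thresh, floor),
                                   distance=max(1, int(round(refractory_s * fs))))
    if candidates.size == 0:
        warnings.warn("no R peaks found above threshold", UserWarning,
                      stacklevel=2)
        return BeatSeries(np.empty(0), np.empty(0))

    # refine: local ECG maximum within +-50 ms, then parabolic vertex
    half = int(round(0.05 * fs))
    times, amps = [], []
    for c in candidates:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        i0 = lo + int(np.argmax(x[lo:hi]))
        if 0 < i0 < x.size - 1:
            delta, height = _parabolic_vertex(x[i0 - 1], x[i0], x[i0 + 1])
        else:
            delta, height = 0.0, x[i0]
        times.append(ecg.start_time + (i0 + delta) / fs)
        amps.append(height)
    times = np.asarray(times)
    amps = np.asarray(amps)
    # de-duplicate refined peaks that collapsed onto the same maximum
    keep = np.concatenate(([True], np.diff(times) > refractory_s / 2))
    return BeatSeries(times[keep], amps[keep])


def clean_to_nn(beats: BeatSeries, premature_frac: float = 0.75,
                long_frac: float = 1.5, median_window: int = 11,
                override_labels: dict[int, str] | None = None) -> NNSeries:
    """Label ectopy/artifacts and keep only normal-to-normal intervals.

    An RR interval is non-NN when it is shorter than ``premature_frac`` or
    longer than ``long_frac`` times the running median of the last
    ``median_window`` accepted NN intervals.  A short interval marks its
    terminating beat premature; any interval adjacent to a non-normal beat
    (including beats relabelled through ``override_labels``, the
    reviewable replacement for interactive editing) is excluded, and the
    contiguity flags record the gaps this leaves.
    """
    if len(beats) < 3:
        raise ValueError("need at least 3 beats to form NN intervals")
    labels = beats.labels.copy()
    if override_labels:
        for idx, lab in override_labels.items():
            if lab not in (NORMAL, PREMATURE, ARTIFACT):
                raise ValueError(f"unknown beat label {lab!r}")
            labels[idx] = lab

    rr = np.diff(beats.r_times) * 1000.0  # ms, rr[i] between beats i and i+1
    n_rr = rr.size
    bad_interval = np.zeros(n_rr, dtype=bool)

    accepted: list[float] = []
    bootstrap_med = float(np.median(rr))
    for i in range(n_rr):
        med = (float(np.median(accepted[-median_window:])) if accepted
               else bootstrap_med)
        if rr[i] < premature_frac * med:
            bad_interval[i] = True
            if labels[i + 1] == NORMAL:
                labels[i + 1] = PREMATURE  # beat terminating a short interval
        elif rr[i] > long_frac * med:
            bad_interval[i] = True
            if labels[i + 1] == NORMAL:
                labels[i + 1] = ARTIFACT
        else:
            accepted.append(float(rr[i]))

    beat_ok = labels == NORMAL
    keep = (~bad_interval) & beat_ok[:-1] & beat_ok[1:]
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError(
            f"fewer than 2 NN intervals survive cleaning ({idx.size}); "
            "check signal quality or thresholds")
    contiguous = np.concatenate(([False], np.diff(idx) == 1))
    return NNSeries(rr[idx], beats.r_times[idx], contiguous)


def mean_nn(nn: NNSeries) -> float:
    """Average NN interval, NNI_m (ms)."""
    if len(nn) == 0:
        raise ValueError("empty NN series")
    return float(nn.intervals.mean())


def edr(beats: BeatSeries, resample_fs: float = 5.0,
        highpass_hz: float = 0.05) -> float:
    """ECG-derived respiration: breathing rate (Hz) from QRS amplitudes.

    The R-amplitude series is linearly interpolated to ``resample_fs``,
    high-pass filtered at ``highpass_hz`` (zero-phase 4th-order
    Butterworth, so oscillations too slow to be respiratory are removed
    without phase distortion) and the Welch periodogram's global maximum
    gives the breathing rate.  Returns NaN with a warning when the
    amplitude series carries no modulation.
    """
    mask = beats.labels == NORMAL
    times = beats.r_times[mask]
    amps = beats.r_amplitudes[mask]
    if times.size < 2 or times[-1] - times[0] < 60.0:
        raise ValueError("need at least 60 s of beats with amplitudes")
    n = int(np.floor((times[-1] - times[0]) * resample_fs)) + 1
    grid = times[0] + np.arange(n) / resample_fs
    series = np.interp(grid, times, amps)

    if np.ptp(series) == 0 or series.std() == 0:
        warnings.warn("constant QRS amplitudes: no respiratory peak",
                      UndefinedResultWarning, stacklevel=2)
        return float("nan")

    sos = sps.butter(4, highpass_hz, btype="highpass", fs=resample_fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, series)
    if filtered.std() < 1e-12 * np.abs(series).max():
        warnings.warn("no amplitude modulation above the high-pass cutoff",
                      UndefinedResultWarning, stacklevel=2)
        return float("nan")

    window_s = min(spectral.WINDOW_S, n / resample_fs)
    spec = spectral.welch_psd(EvenSeries(filtered, resample_fs),
                              window_s=window_s)
    psd = spec.psd.copy()
    psd[spec.freqs <= highpass_hz] = 0.0  # exclude DC / sub-cutoff leakage
    if psd.max() <= 0:
        warnings.warn("flat spectrum: no respiratory peak",
                      UndefinedResultWarning, stacklevel=2)
        return float("nan")
    return float(spec.freqs[int(np.argmax(psd))])
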