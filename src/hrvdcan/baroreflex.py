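"""Transfer-function baroreflex sensitivity and SBP-NNI coherency.

The baroreflex loop resonates in the LF band: systolic-pressure
oscillations around 0.1 Hz are mirrored by RR-interval oscillations.  The
transfer-function method estimates the ms/mmHg gain of that coupling as
|S_xy(f)| / S_xx(f) (SBP-NNI cross-spectrum over the SBP auto-spectrum)
averaged over 0.04-0.15 Hz, and the magnitude-squared coherency
|S_xy|^2 / (S_xx * S_yy) quantifies how much of the RR variability is
linearly driven by pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import spectral
from .series import EvenSeries, NNSeries, UndefinedResultWarning


@dataclass
class BaroreflexResult:
    """LF-band BRS (ms/mmHg) and coherency plus the per-frequency curves."""

    brs: float
    lf_coherency: float
    freqs: np.ndarray
    gain: np.ndarray
    coherency: np.ndarray
    n_segments: int


def brs_transfer(sbp: EvenSeries, nni: EvenSeries,
                 window_s: float = spectral.WINDOW_S,
                 overlap: float = spectral.OVERLAP,
                 lf_band: tuple[float, float] = spectral.LF_BAND
                 ) -> BaroreflexResult:
    """Transfer-function BRS and coherency between aligned SBP and NNI series.

    Both series must share the sampling rate and length (time-aligned,
    resampled at 5 Hz beat-domain series).  Welch/CSD settings are the
    spectral module's (120-s Hann windows, 50% overlap); at least 3
    segments are required — the coherency of a single segment is
    identically 1.  Gain uses the cross-spectrum *modulus*, so coupling
    delays do not bias it.
    """
    if sbp.fs != nni.fs:
        raise ValueError("SBP and NNI series must share the sampling rate")
    if len(sbp) != len(nni):
        raise ValueError("SBP and NNI series must have equal length")
    fs = sbp.fs
    duration = len(sbp) / fs
    n_seg = spectral.n_welch_segments(duration, window_s, overlap)
    if n_seg < 3:
        raise ValueError(
            f"need >= 3 Welch segments for coherency ({n_seg} available from "
            f"{duration:.0f} s); shorten the window or lengthen the record")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(nperseg * overlap))
    kw = dict(fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
              detrend="constant")
    f, pxx = sps.welch(sbp.values, **kw)
    _, pyy = sps.welch(nni.values, **kw)
    _, pxy = sps.csd(sbp.values, nni.values, **kw)

    lf = (f >= lf_band[0]) & (f < lf_band[1])
    if not np.any(pxx[lf] > 0):
        warnings.warn("zero SBP variance in the LF band; BRS undefined",
                      UndefinedResultWarning, stacklevel=2)
        nanc = np.full(f.size, np.nan)
        return BaroreflexResult(float("nan"), float("nan"), f, nanc, nanc, n_seg)

    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.abs(pxy) / pxx
        coherency = np.abs(pxy) ** 2 / (pxx * pyy)
    coherency = np.clip(np.nan_to_num(coherency), 0.0, 1.0)

    brs = float(np.nanmean(gain[lf]))
    lf_coh = float(np.mean(coherency[lf]))
    return BaroreflexResult(brs, lf_coh, f, gain, coherency, n_seg)


def brs_from_beats(nn: NNSeries, sbp_values: np.ndarray,
                   fs: float = spectral.RESAMPLE_FS,
                   window_s: float = spectral.WINDOW_S) -> BaroreflexResult:
    """BRS from beat-domain series: SBP values aligned with NN onsets.

    Both are resampled to the uniform 5 Hz grid with the same linear
    interpolation used for the tachogram, then passed to
    :func:`brs_transfer`.
    """
    sbp_values = np.asarray(sbp_values, dtype=float)
    if sbp_values.size != len(nn):
        raise ValueError("need one SBP value per NN interval")
    nni_even = spectral.resample_nn(nn, fs=fs)
    t0, t1 = nn.onset_times[0], nn.onset_times[-1]
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    sbp_even = EvenSeries(np.interp(grid, nn.onset_times, sbp_values),
                          fs=fs, start_time=t0)
    return brs_transfer(sbp_even, nni_even, window_s=window_s)
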