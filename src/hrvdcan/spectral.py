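"""Tachogram resampling, Welch spectra, and spectral band powers.

The tachogram is treated as a step-free signal: each NN interval value is
assigned at its onset time and the series is linearly interpolated onto a
uniform 5 Hz grid.  Spectra use 120-s Hann windows with 50% overlap and an
optional wideband frequency-domain smoothing, and band powers integrate
the one-sided periodogram over VLF (0.005-0.04 Hz), LF (0.04-0.15 Hz),
HF (0.15-0.40 Hz) and the 0-0.5 Hz total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .series import EvenSeries, NNSeries, UndefinedResultWarning

#: study defaults
RESAMPLE_FS = 5.0
WINDOW_S = 120.0
OVERLAP = 0.5
SMOOTH_BW = 0.01  # Hz

#: band edges, Hz (half-open [lo, hi))
VLF_BAND = (0.005, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND = (0.0, 0.5)


@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray
    window_s: float = WINDOW_S
    overlap: float = OVERLAP
    taper: str = "hann"
    smooth_bw: float | None = SMOOTH_BW

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.size != self.psd.size:
            raise ValueError("freqs and psd must have equal length")
        if np.any(self.freqs < 0) or not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be nonnegative ascending")
        if np.any(self.psd < -1e-12):
            raise ValueError("psd must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowers:
    """Band-integrated tachogram powers (ms^2) and the LF/HF ratio."""

    vlf: float
    lf: float
    hf: float
    tot_p: float
    lf_hf: float = field(default=float("nan"))


def resample_nn(nn: NNSeries, fs: float = RESAMPLE_FS) -> EvenSeries:
    """Resample beat-by-beat NN intervals to a uniform grid.

    The interval value sits at the interval onset; the grid spans
    [first onset, last onset] and gaps flagged in the series are bridged
    by the same linear interpolation ("linearly interpolating possibly
    missing beats").
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 NN intervals to resample")
    t0, t1 = nn.onset_times[0], nn.onset_times[-1]
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    vals = np.interp(grid, nn.onset_times, nn.intervals)
    return EvenSeries(vals, fs=fs, start_time=t0)


def _smooth_psd(psd: np.ndarray, df: float, bandwidth: float) -> np.ndarray:
    """Moving-average smoothing over ``bandwidth`` Hz (odd kernel, reflect edges)."""
    k = int(round(bandwidth / df))
    if k <= 1:
        return psd
    if k % 2 == 0:
        k += 1
    pad = k // 2
    padded = np.pad(psd, pad, mode="reflect")
    kernel = np.ones(k) / k
    return np.convolve(padded, kernel, mode="valid")


def welch_psd(series: EvenSeries, window_s: float = WINDOW_S,
              overlap: float = OVERLAP, taper: str = "hann",
              smooth_bw: float | None = SMOOTH_BW) -> Spectrum:
    """Welch periodogram with per-segment mean removal.

    Segments are mean-removed only (no linear detrend) so VLF content down
    to 0.005 Hz is preserved; the one-sided density integrates to the
    series variance (Parseval, up to window leakage).  ``smooth_bw`` applies
    a post-hoc frequency-domain moving average; None disables it.
    """
    n = len(series)
    nperseg = int(round(window_s * series.fs))
    if n < nperseg:
        raise ValueError(
            f"series ({n / series.fs:.0f} s) shorter than one Welch window "
            f"({window_s:.0f} s)")
    noverlap = int(round(nperseg * overlap))
    freqs, psd = sps.welch(series.values, fs=series.fs, window=taper,
                           nperseg=nperseg, noverlap=noverlap,
                           detrend="constant", scaling="density")
    if smooth_bw is not None:
        psd = _smooth_psd(psd, float(freqs[1] - freqs[0]), smooth_bw)
    return Spectrum(freqs, np.maximum(psd, 0.0), window_s=window_s,
                    overlap=overlap, taper=taper, smooth_bw=smooth_bw)


def n_welch_segments(duration_s: float, window_s: float = WINDOW_S,
                     overlap: float = OVERLAP) -> int:
    """Number of overlapped Welch segments fitting a record of given length."""
    step = window_s * (1.0 - overlap)
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / step)) + 1


def integrate_band(spec: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi), with interpolated edges."""
    f, p = spec.freqs, spec.psd
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError(f"spectrum does not cover [{lo}, {hi}] Hz")
    inner = (f > lo) & (f < hi)
    fs_band = np.concatenate(([lo], f[inner], [hi]))
    ps_band = np.concatenate(([np.interp(lo, f, p)], p[inner],
                              [np.interp(hi, f, p)]))
    return float(np.trapezoid(ps_band, fs_band))


def band_powers(spec: Spectrum) -> BandPowers:
    """VLF/LF/HF/total band powers and the LF/HF ratio.

    The total 0-0.5 Hz power excludes the DC bin: the f=0 PSD value is
    replaced by the first interior bin before integration, discarding mean
    (DC) leakage without shrinking the integration interval.
    """
    if spec.freqs[-1] < TOTAL_BAND[1]:
        raise ValueError("spectrum must cover [0, 0.5] Hz")
    vlf = integrate_band(spec, *VLF_BAND)
    lf = integrate_band(spec, *LF_BAND)
    hf = integrate_band(spec, *HF_BAND)
    psd_nodc = spec.psd.copy()
    if spec.freqs[0] == 0.0 and psd_nodc.size > 1:
        psd_nodc[0] = psd_nodc[1]
    tot = integrate_band(Spectrum(spec.freqs, psd_nodc, spec.window_s,
                                  spec.overlap, spec.taper, spec.smooth_bw),
                         *TOTAL_BAND)
    if hf <= 0:
        warnings.warn("HF power is zero; LF/HF ratio undefined",
                      UndefinedResultWarning, stacklevel=2)
        ratio = float("nan")
    else:
        ratio = lf / hf
    return BandPowers(vlf=vlf, lf=lf, hf=hf, tot_p=tot, lf_hf=ratio)


def nn_band_powers(nn: NNSeries, fs: float = RESAMPLE_FS,
                   window_s: float = WINDOW_S,
                   smooth_bw: float | None = SMOOTH_BW) -> BandPowers:
    """Convenience: resample an NN series and integrate its Welch spectrum."""
    series = resample_nn(nn, fs=fs)
    return band_powers(welch_psd(series, window_s=window_s, smooth_bw=smooth_bw))
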