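"""Time-domain HRV indexes: pNN50+/-, RMSSD, and the SDNN index.

pNN50 and RMSSD operate on successive NN differences and therefore use
only contiguous interval pairs — pairs spanning a gap left by a rejected
beat are excluded.  SDNN_i averages the sample standard deviation of NN
intervals over running 5-min windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import NNSeries


@dataclass
class TimeDomainIndexes:
    nni_m: float
    pnn50_plus: float
    pnn50_minus: float
    rmssd: float
    sdnn_i: float


def pnn50(nn: NNSeries, direction: str = "plus", threshold_ms: float = 50.0) -> float:
    """Percentage of successive NN pairs differing by at least 50 ms.

    ``direction="plus"`` counts intervals at least 50 ms *longer* than
    their predecessor, ``"minus"`` at least 50 ms shorter; the comparison
    is inclusive (>= 50 ms) and the denominator is the number of valid
    contiguous pairs.
    """
    diffs = nn.successive_diffs()
    if diffs.size == 0:
        raise ValueError("no contiguous successive NN pairs")
    if direction == "plus":
        count = int(np.count_nonzero(diffs >= threshold_ms))
    elif direction == "minus":
        count = int(np.count_nonzero(diffs <= -threshold_ms))
    else:
        raise ValueError("direction must be 'plus' or 'minus'")
    return 100.0 * count / diffs.size


def rmssd(nn: NNSeries) -> float:
    """Root-mean-square of successive NN differences (ms), contiguous pairs only."""
    diffs = nn.successive_diffs()
    if diffs.size == 0:
        raise ValueError("no contiguous successive NN pairs")
    return float(np.sqrt(np.mean(diffs ** 2)))


def sdnn_index(nn: NNSeries, window_s: float = 300.0, step_s: float = 60.0,
               min_intervals: int = 30) -> float:
    """Mean of per-window NN standard deviations over running 5-min windows (ms).

    Windows are ``[start, start+window_s)`` slid by ``step_s``; windows with
    fewer than ``min_intervals`` intervals are skipped with a warning.  The
    SD uses the n-1 denominator.
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 NN intervals")
    t0, t_end = nn.onset_times[0], nn.onset_times[-1]
    record_len = t_end - t0
    if record_len < window_s:
        raise ValueError(
            f"record ({record_len:.0f} s) shorter than one {window_s:.0f}-s "
            "window; use the plain SDNN instead")
    sds = []
    start = t0
    while start + window_s <= t_end + 1e-9:
        mask = (nn.onset_times >= start) & (nn.onset_times < start + window_s)
        vals = nn.intervals[mask]
        if vals.size < min_intervals:
            warnings.warn(
                f"window starting at {start:.0f} s has only {vals.size} "
                "intervals; skipped", UserWarning, stacklevel=2)
        else:
            sds.append(np.std(vals, ddof=1))
        start += step_s
    if not sds:
        raise ValueError("no window contained enough NN intervals")
    return float(np.mean(sds))


def time_domain_indexes(nn: NNSeries, window_s: float = 300.0,
                        step_s: float = 60.0) -> TimeDomainIndexes:
    """All five time-domain indexes for one condition."""
    return TimeDomainIndexes(
        nni_m=float(nn.intervals.mean()),
        pnn50_plus=pnn50(nn, "plus"),
        pnn50_minus=pnn50(nn, "minus"),
        rmssd=rmssd(nn),
        sdnn_i=sdnn_index(nn, window_s=window_s, step_s=step_s),
    )
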