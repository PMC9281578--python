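"""Traditional autonomic-test outcomes, Ewing's score, and the SCOPA-AUT score.

All test outcomes are extremum-minus-baseline contrasts over annotated
half-open windows: deep-breathing heart-rate range, Valsalva ratio
(phase IV longest over phase II shortest RR), sustained-handgrip diastolic
rise, head-up-tilt 30:15 ratio and systolic fall, and the cold-pressor
pressure/heart-rate rises.  Ewing's method scores each of its five tests
0 / 0.5 / 1 (normal / borderline / abnormal) against a configurable
threshold table — the classic cut-offs ship as editable defaults — and the
SCOPA-AUT questionnaire is scored as a percentage of its maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .series import NNSeries

Window = tuple[float, float]  # (start_s, end_s), half-open


def _window_values(times: np.ndarray, values: np.ndarray, window: Window) -> np.ndarray:
    start, end = window
    mask = (np.asarray(times) >= start) & (np.asarray(times) < end)
    return np.asarray(values, dtype=float)[mask]


def heart_rate(nn: NNSeries) -> np.ndarray:
    """Instantaneous beat-domain heart rate, 60000/NN (bpm)."""
    return 60000.0 / nn.intervals


def deep_breathing_dhr(nn: NNSeries, window: Window) -> float:
    """Deep Breathing ΔHR: max minus min heart rate during paced breathing (bpm)."""
    hr = _window_values(nn.onset_times, heart_rate(nn), window)
    if hr.size == 0:
        raise ValueError("no beats in the deep-breathing window")
    return float(hr.max() - hr.min())


def valsalva_ratio(nn: NNSeries,
                   maneuvers: list[tuple[Window, Window]]) -> float:
    """Largest ratio across maneuvers of longest phase-IV RR to shortest phase-II RR.

    ``maneuvers`` is a list of (phase_II_window, phase_IV_window) pairs;
    maneuvers with an empty phase window are skipped with a warning.
    """
    ratios = []
    for k, (win2, win4) in enumerate(maneuvers):
        rr2 = _window_values(nn.onset_times, nn.intervals, win2)
        rr4 = _window_values(nn.onset_times, nn.intervals, win4)
        if rr2.size == 0 or rr4.size == 0:
            warnings.warn(f"maneuver {k}: empty phase window, skipped",
                          UserWarning, stacklevel=2)
            continue
        ratios.append(rr4.max() / rr2.min())
    if not ratios:
        raise ValueError("no Valsalva maneuver with both phase windows populated")
    return float(max(ratios))


def handgrip_ddbp(dbp_times: np.ndarray, dbp_values: np.ndarray,
                  baseline_window: Window, grip_window: Window) -> float:
    """Handgrip ΔDBP: max diastolic pressure during contraction minus baseline mean."""
    base = _window_values(dbp_times, dbp_values, baseline_window)
    grip = _window_values(dbp_times, dbp_values, grip_window)
    if base.size == 0 or grip.size == 0:
        raise ValueError("empty baseline or grip window")
    return float(grip.max() - base.mean())


def hut_3015(nn: NNSeries, tilt_start: float,
             around_15: tuple[int, int] = (10, 20),
             around_30: tuple[int, int] = (25, 35),
             min_post_tilt_beats: int = 40) -> float:
    """HUT 30:15 ratio: longest RR around the 30th post-tilt beat over the
    shortest around the 15th.

    Beat windows are inclusive 1-based post-tilt beat numbers, defaulting
    to 10-20 and 25-35.
    """
    post = nn.intervals[nn.onset_times >= tilt_start]
    if post.size < min_post_tilt_beats:
        raise ValueError(
            f"only {post.size} beats after tilt; need {min_post_tilt_beats}")
    lo15, hi15 = around_15
    lo30, hi30 = around_30
    rr15 = post[lo15 - 1:hi15]
    rr30 = post[lo30 - 1:hi30]
    return float(rr30.max() / rr15.min())


def hut_dsbp(sbp_times: np.ndarray, sbp_values: np.ndarray,
             baseline_window: Window, tilt_start: float,
             tilt_span_s: float = 180.0) -> float:
    """HUT ΔSBP: lowest systolic pressure in the first 3 min of tilt minus
    baseline mean (typically negative)."""
    base = _window_values(sbp_times, sbp_values, baseline_window)
    tilt = _window_values(sbp_times, sbp_values,
                          (tilt_start, tilt_start + tilt_span_s))
    if base.size == 0 or tilt.size == 0:
        raise ValueError("empty baseline or tilt window")
    return float(tilt.min() - base.mean())


def cold_pressor_ddbp(dbp_times: np.ndarray, dbp_values: np.ndarray,
                      baseline_window: Window, immersion_start: float,
                      immersion_s: float = 90.0) -> float:
    """Cold pressor ΔDBP: max diastolic pressure during the 90-s immersion
    minus baseline mean."""
    base = _window_values(dbp_times, dbp_values, baseline_window)
    imm = _window_values(dbp_times, dbp_values,
                         (immersion_start, immersion_start + immersion_s))
    if base.size == 0 or imm.size == 0:
        raise ValueError("empty baseline or immersion window")
    return float(imm.max() - base.mean())


def cold_pressor_dhr(nn: NNSeries, baseline_window: Window,
                     immersion_start: float, immersion_s: float = 90.0) -> float:
    """Cold pressor ΔHR: highest heart rate during the 90-s immersion minus
    baseline mean (bpm)."""
    hr = heart_rate(nn)
    base = _window_values(nn.onset_times, hr, baseline_window)
    imm = _window_values(nn.onset_times, hr,
                         (immersion_start, immersion_start + immersion_s))
    if base.size == 0 or imm.size == 0:
        raise ValueError("empty baseline or immersion window")
    return float(imm.max() - base.mean())


@dataclass
class TestThreshold:
    """Normal/borderline/abnormal cut-offs for one Ewing test.

    All Ewing outcomes are oriented so that higher is better (the
    orthostatic systolic fall enters as the signed ΔSBP, e.g. -9 mmHg):
    normal when value >= ``normal_min``, abnormal when value <=
    ``abnormal_max``, borderline in between.
    """

    normal_min: float
    abnormal_max: float

    def __post_init__(self) -> None:
        if self.normal_min <= self.abnormal_max:
            raise ValueError("normal_min must exceed abnormal_max")

    def score(self, value: float) -> float:
        if value >= self.normal_min:
            return 0.0
        if value <= self.abnormal_max:
            return 1.0
        return 0.5


#: the five Ewing-battery outcomes, in battery order
EWING_TESTS = ("db_dhr", "valsalva_ratio", "hut_3015", "hut_dsbp", "hg_ddbp")

#: classic Ewing cut-offs (editable; not asserted as any study's values)
DEFAULT_EWING_THRESHOLDS: dict[str, TestThreshold] = {
    "db_dhr": TestThreshold(normal_min=15.0, abnormal_max=10.0),       # bpm
    "valsalva_ratio": TestThreshold(normal_min=1.21, abnormal_max=1.10),
    "hut_3015": TestThreshold(normal_min=1.04, abnormal_max=1.00),
    "hut_dsbp": TestThreshold(normal_min=-10.0, abnormal_max=-30.0),   # mmHg
    "hg_ddbp": TestThreshold(normal_min=16.0, abnormal_max=10.0),      # mmHg
}


def ewing_score(outcomes: dict[str, float],
                thresholds: dict[str, TestThreshold] | None = None) -> float:
    """Total Ewing score: sum of per-test 0/0.5/1 scores over the five tests."""
    thresholds = thresholds or DEFAULT_EWING_THRESHOLDS
    total = 0.0
    for test in EWING_TESTS:
        if test not in outcomes:
            raise ValueError(f"missing Ewing test outcome: {test!r}")
        if test not in thresholds:
            raise ValueError(f"missing threshold for Ewing test: {test!r}")
        total += thresholds[test].score(outcomes[test])
    return total


def scopa_score(items: np.ndarray, item_max: np.ndarray | None = None,
                missing: str = "prorate") -> float:
    """SCOPA-AUT score as a percentage of the maximum achievable score.

    23 item responses; ``item_max`` defaults to 3 per item.  Missing items
    (NaN) are prorated (dropped from numerator and denominator) under the
    default policy, or rejected under ``missing="strict"``.
    """
    items = np.asarray(items, dtype=float)
    if item_max is None:
        item_max = np.full(items.size, 3.0)
    item_max = np.asarray(item_max, dtype=float)
    if items.size != item_max.size:
        raise ValueError("items and item_max must have equal length")
    nan_mask = np.isnan(items)
    if nan_mask.any():
        if missing == "strict":
            raise ValueError(f"{int(nan_mask.sum())} missing item response(s)")
        items = items[~nan_mask]
        item_max = item_max[~nan_mask]
        if items.size == 0:
            raise ValueError("all items missing")
    if np.any(items < 0) or np.any(items > item_max):
        raise ValueError("item responses must lie within [0, item_max]")
    return float(100.0 * items.sum() / item_max.sum())
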