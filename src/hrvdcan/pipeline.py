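"""End-to-end orchestration: signals -> per-subject indexes -> cohort -> ROC.

``compute_indexes`` evaluates every HRV index one condition's NN series
supports, recording an explicit reason for any index the record is too
short for.  ``run_subject`` applies it per condition window;
``run_cohort_signals`` synthesises and analyses a whole two-group cohort
from raw tachograms; ``run_cohort_indexes`` draws index values directly
from the published cohort distributions.  Both cohort runners emit a
long-format cohort table, a group-summary table (mean (SD) per index,
group and condition), and a ROC report per index and condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baroreflex, beats, complexity, spectral, stats, synthetic, time_domain
from .series import NNSeries

#: per-index classification direction: every HRV index is depressed in
#: patients (cut-offs are "<"), the symptom score is elevated.
CASE_DIRECTIONS: dict[str, str] = {name: stats.CASE_LOW
                                   for name in synthetic.COHORT_DEFAULTS}
CASE_DIRECTIONS["scopa_pct"] = stats.CASE_HIGH

HRV_INDEX_NAMES = list(synthetic.COHORT_DEFAULTS)


@dataclass
class SubjectRecord:
    """All computed indexes per condition, with reasons for missing ones."""

    subject_id: str
    indexes: dict[str, dict[str, float]]          # condition -> index -> value
    unavailable: dict[str, dict[str, str]]        # condition -> index -> reason


def compute_indexes(nn: NNSeries, sbp_values: np.ndarray | None = None
                    ) -> tuple[dict[str, float], dict[str, str]]:
    """Every computable HRV index (plus BRS/coherency if SBP given) for one
    condition, and the reason each unavailable index is missing."""
    values: dict[str, float] = {}
    missing: dict[str, str] = {}
    n, dur = len(nn), nn.duration

    values["nni_m"] = beats.mean_nn(nn)
    try:
        values["pnn50_plus"] = time_domain.pnn50(nn, "plus")
        values["pnn50_minus"] = time_domain.pnn50(nn, "minus")
        values["rmssd"] = time_domain.rmssd(nn)
    except ValueError as exc:
        for name in ("pnn50_plus", "pnn50_minus", "rmssd"):
            missing[name] = str(exc)
    if dur >= 300.0:
        values["sdnn_i"] = time_domain.sdnn_index(nn)
    else:
        missing["sdnn_i"] = f"record {dur:.0f} s shorter than one 5-min window"

    if spectral.n_welch_segments(dur) >= 2:
        bp = spectral.nn_band_powers(nn)
        values.update(vlf=bp.vlf, lf=bp.lf, hf=bp.hf, tot_p=bp.tot_p,
                      lf_hf=bp.lf_hf)
    else:
        reason = f"record {dur:.0f} s gives <2 Welch windows"
        for name in ("vlf", "lf", "hf", "tot_p", "lf_hf"):
            missing[name] = reason

    if n >= 250:
        values["sampen"] = complexity.sampen(nn.intervals)
        prof = complexity.mse_profile(nn)
        values["mse_hf"], values["mse_lf"] = complexity.mse_bands(prof)
    else:
        for name in ("sampen", "mse_hf", "mse_lf"):
            missing[name] = f"{n} beats < 250 required for multiscale entropy"
    if n >= 500:
        aprof = complexity.mdfa_profile(nn)
        values["alpha_short"], values["alpha_long"] = complexity.alpha_bands(aprof)
    else:
        for name in ("alpha_short", "alpha_long"):
            missing[name] = f"{n} beats < 500 required for multiscale DFA"

    if sbp_values is not None:
        if spectral.n_welch_segments(dur) >= 3:
            res = baroreflex.brs_from_beats(nn, sbp_values)
            values["brs"] = res.brs
            values["lf_coherency"] = res.lf_coherency
        else:
            reason = f"record {dur:.0f} s gives <3 Welch segments"
            missing["brs"] = missing["lf_coherency"] = reason
    return values, missing


def run_subject(subject_id: str, nn: NNSeries,
                condition_windows: dict[str, tuple[float, float]],
                sbp_values: np.ndarray | None = None) -> SubjectRecord:
    """Slice one recording into condition windows and index each separately."""
    indexes: dict[str, dict[str, float]] = {}
    unavailable: dict[str, dict[str, str]] = {}
    for cond, (start, end) in condition_windows.items():
        nn_cond = nn.slice(start, end)
        sbp_cond = None
        if sbp_values is not None:
            mask = (nn.onset_times >= start) & (nn.onset_times < end)
            sbp_cond = np.asarray(sbp_values)[mask]
        vals, miss = compute_indexes(nn_cond, sbp_cond)
        indexes[cond] = vals
        unavailable[cond] = miss
    return SubjectRecord(subject_id, indexes, unavailable)


def _subject_rr_config(group: str, condition: str, duration_s: float,
                       rng: np.random.Generator) -> synthetic.RRModelConfig:
    """Per-subject tachogram parameters drawn from the published cohort table."""
    def draw(index: str, floor: float) -> float:
        mean, sd = synthetic.COHORT_DEFAULTS[index][(group, condition)]
        return max(float(rng.normal(mean, sd)), floor)

    return synthetic.RRModelConfig(
        duration_s=duration_s,
        mean_nn=draw("nni_m", 400.0),
        vlf_power=draw("vlf", 10.0),
        lf_power=draw("lf", 10.0),
        hf_power=draw("hf", 10.0),
        noise_power=0.25 * draw("tot_p", 100.0),
        noise_beta=1.0,
        seed=int(rng.integers(2 ** 31)),
    )


def run_cohort_signals(n_per_group: int = 20, seed: int = 0,
                       sup_duration_s: float = 960.0,
                       hut_duration_s: float = 600.0,
                       include_brs: bool = True
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthesise and analyse a full cohort from raw tachograms.

    Each subject gets a supine and a tilt tachogram with band powers drawn
    from the published group distributions, plus a baroreflex-coupled SBP
    series.  Returns (long cohort table, group-summary table, ROC report).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in synthetic.GROUPS:
        for k in range(n_per_group):
            sid = f"{group}{k:04d}"
            for cond, dur in (("SUP", sup_duration_s), ("HUT", hut_duration_s)):
                cfg = _subject_rr_config(group, cond, dur, rng)
                nn = synthetic.generate_rr(cfg)
                sbp = None
                if include_brs:
                    gain = max(float(rng.normal(12.0 if cond == "SUP" else 7.5,
                                                3.0)), 0.5)
                    sbp = 120.0 + (nn.intervals - nn.intervals.mean()) / gain \
                        + rng.normal(0, 1.0, len(nn))
                vals, miss = compute_indexes(nn, sbp)
                for name, reason in miss.items():
                    warnings.warn(f"{sid}/{cond}: {name} unavailable ({reason})",
                                  UserWarning, stacklevel=2)
                for name, value in vals.items():
                    rows.append((sid, group, cond, name, value))
    cohort = pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                         "index", "value"])
    return cohort, summarize_cohort(cohort), roc_report(cohort)


def run_cohort_indexes(config: synthetic.CohortConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort run from the published index distributions (no signal synthesis)."""
    cohort = synthetic.generate_cohort(config)
    return cohort, summarize_cohort(cohort), roc_report(cohort)


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group-summary table: mean (SD) per index, group, and condition."""
    g = cohort.groupby(["index", "group", "condition"])["value"]
    summary = g.agg(["mean", "std", "count"]).reset_index()
    summary["mean_sd"] = summary.apply(
        lambda r: f"{r['mean']:.3g} ({r['std']:.3g})", axis=1)
    return summary


def roc_report(cohort: pd.DataFrame, case_group: str = "T1DM",
               control_group: str = "CNTR", alpha: float = 0.05,
               se_method: str = "hanley-mcneil") -> pd.DataFrame:
    """Per-index, per-condition ROC analysis of a long-format cohort table.

    Columns mirror standard reporting: AUC, SE, p, cut-off, sensitivity and
    specificity (cut-off columns populated only for significant AUCs).
    """
    rows = []
    for (index, cond), sub in cohort.groupby(["index", "condition"]):
        cases = sub.loc[sub["group"] == case_group, "value"].to_numpy()
        controls = sub.loc[sub["group"] == control_group, "value"].to_numpy()
        if cases.size < 2 or controls.size < 2:
            warnings.warn(f"{index}/{cond}: fewer than 2 subjects per group; "
                          "ROC skipped", UserWarning, stacklevel=2)
            continue
        direction = CASE_DIRECTIONS.get(index, stats.CASE_LOW)
        res = stats.roc(cases, controls, direction=direction, alpha=alpha,
                        se_method=se_method)
        rows.append({"index": index, "condition": cond, "auc": res.auc,
                     "se": res.se, "p": res.p, "cutoff": res.cutoff,
                     "sensitivity": res.sensitivity,
                     "specificity": res.specificity,
                     "direction": direction})
    return pd.DataFrame(rows)
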