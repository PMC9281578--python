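"""ROC/AUC/Youden classification and group-comparison statistics.

The AUC is computed through its Mann-Whitney identity (midrank ties), with
the Hanley-McNeil standard error by default (DeLong available), a normal
approximation p-value against AUC = 0.5, and the Youden-index cut-off with
its sensitivity and specificity.  Pointwise multiscale/spectral group
comparisons use two-sided Mann-Whitney tests per abscissa, and multiple
comparisons are handled by Benjamini-Hochberg false-discovery-rate
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as scs
from statsmodels.stats.multitest import multipletests

from .series import UndefinedResultWarning

CASE_LOW = "case_low"
CASE_HIGH = "case_high"


@dataclass
class ROCResult:
    auc: float
    se: float
    p: float
    direction: str
    n_cases: int
    n_controls: int
    cutoff: float = float("nan")
    sensitivity: float = float("nan")  # %
    specificity: float = float("nan")  # %


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray,
                      direction: str) -> float:
    """AUC = P(case ranks toward the case side of a control), midrank ties."""
    pooled = np.concatenate([cases, controls])
    ranks = scs.rankdata(pooled)
    r_cases = ranks[:cases.size].sum()
    n1, n2 = cases.size, controls.size
    u_case_high = r_cases - n1 * (n1 + 1) / 2.0  # pairs where case > control
    auc_high = u_case_high / (n1 * n2)
    return auc_high if direction == CASE_HIGH else 1.0 - auc_high


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n2 - 1) * (q2 - auc ** 2)) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(cases: np.ndarray, controls: np.ndarray, direction: str) -> float:
    """DeLong variance from placement values."""
    x = cases if direction == CASE_HIGH else -cases
    y = controls if direction == CASE_HIGH else -controls
    # placement of each case among controls and vice versa
    v10 = np.array([(np.sum(xi > y) + 0.5 * np.sum(xi == y)) / y.size for xi in x])
    v01 = np.array([(np.sum(x > yj) + 0.5 * np.sum(x == yj)) / x.size for yj in y])
    var = (np.var(v10, ddof=1) / x.size if x.size > 1 else 0.0) \
        + (np.var(v01, ddof=1) / y.size if y.size > 1 else 0.0)
    return float(np.sqrt(max(var, 0.0)))


def roc(cases: np.ndarray, controls: np.ndarray, direction: str = CASE_LOW,
        se_method: str = "hanley-mcneil", alpha: float = 0.05) -> ROCResult:
    """ROC analysis of one index: AUC, SE, p vs 0.5, and the Youden cut-off.

    The cut-off (with sensitivity/specificity) is only reported when the
    AUC differs from 0.5 at the configured ``alpha``, mirroring standard
    reporting practice.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("need at least 2 values per group")
    if direction not in (CASE_LOW, CASE_HIGH):
        raise ValueError("direction must be 'case_low' or 'case_high'")

    auc = _auc_mann_whitney(cases, controls, direction)
    if se_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, cases.size, controls.size)
    elif se_method == "delong":
        se = _delong_se(cases, controls, direction)
    else:
        raise ValueError("se_method must be 'hanley-mcneil' or 'delong'")
    # two-sided normal approximation of U against AUC = 0.5
    p = float(scs.mannwhitneyu(cases, controls, alternative="two-sided",
                               method="asymptotic").pvalue)

    result = ROCResult(auc=float(auc), se=se, p=p, direction=direction,
                       n_cases=cases.size, n_controls=controls.size)
    if p < alpha:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UndefinedResultWarning)
                cut, sn, sp = youden_cutoff(cases, controls, direction)
            result.cutoff, result.sensitivity, result.specificity = cut, sn, sp
        except ValueError:
            pass
    return result


def youden_cutoff(cases: np.ndarray, controls: np.ndarray,
                  direction: str = CASE_LOW) -> tuple[float, float, float]:
    """Cut-off maximising Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent pooled unique values; ties in
    J are broken toward higher specificity.  The cut-off is a strict
    inequality in the case direction (case_low: positive when value <
    cut-off).  Returns (cutoff, sensitivity %, specificity %).
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    pooled = np.unique(np.concatenate([cases, controls]))
    if pooled.size < 2:
        raise ValueError("degenerate data: all values identical")
    mids = 0.5 * (pooled[:-1] + pooled[1:])
    best = None
    for c in mids:
        if direction == CASE_LOW:
            sn = np.mean(cases < c)
            sp = np.mean(controls >= c)
        else:
            sn = np.mean(cases > c)
            sp = np.mean(controls <= c)
        j = sn + sp - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12
                                                   and sp > best[3]):
            best = (j, c, sn, sp)
    j, c, sn, sp = best
    if j <= 1e-12:
        warnings.warn("fully overlapping groups: Youden cut-off undefined",
                      UndefinedResultWarning, stacklevel=2)
        raise ValueError("Youden index is zero; no discriminating cut-off")
    return float(c), float(100 * sn), float(100 * sp)


def normal_model_sensitivity(cutoff: float, case_mean: float, case_sd: float,
                             direction: str = CASE_LOW) -> float:
    """Model-based sensitivity (%) of a cut-off under a Gaussian case group.

    For case_low this is 100 * Phi((cutoff - mean)/sd): the probability that
    a case falls on the positive side of the cut-off.
    """
    z = (cutoff - case_mean) / case_sd
    frac = scs.norm.cdf(z) if direction == CASE_LOW else scs.norm.sf(z)
    return float(100.0 * frac)


@dataclass
class PointwiseComparison:
    """Per-abscissa two-group Mann-Whitney comparison of profiles/spectra."""

    u: np.ndarray           # Mann-Whitney U (group A vs B)
    p: np.ndarray
    significant_05: np.ndarray
    significant_01: np.ndarray
    p_fdr: np.ndarray | None = None


def pointwise_group_profile(profiles_a: np.ndarray, profiles_b: np.ndarray,
                            fdr: bool = False,
                            exact_below: int = 8) -> PointwiseComparison:
    """Two-sided Mann-Whitney test at every abscissa of subject-wise profiles.

    ``profiles_a``/``profiles_b`` are (subjects x grid) arrays on a common
    abscissa grid; the exact U distribution is used when either group has
    fewer than ``exact_below`` subjects, the normal approximation otherwise.
    """
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("profiles must share the abscissa grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    method = "exact" if min(a.shape[0], b.shape[0]) < exact_below else "asymptotic"
    us = np.empty(a.shape[1])
    ps = np.empty(a.shape[1])
    for k in range(a.shape[1]):
        res = scs.mannwhitneyu(a[:, k], b[:, k], alternative="two-sided",
                               method=method)
        us[k], ps[k] = res.statistic, res.pvalue
    p_fdr = fdr_adjust(ps) if fdr else None
    return PointwiseComparison(u=us, p=ps, significant_05=ps < 0.05,
                               significant_01=ps < 0.01, p_fdr=p_fdr)


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
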