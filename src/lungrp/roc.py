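"""ROC/AUC estimation and DeLong's paired test for correlated AUCs.

The AUC is the Mann-Whitney concordance estimate: the fraction of
(event, non-event) pairs in which the event patient scores higher, with half
credit for ties.  DeLong's nonparametric method estimates the variance of an
AUC — and the covariance of two AUCs measured on the same patients — from
placement values (structural components), here computed with midranks so that
tied scores are handled consistently with the AUC itself.  This is the
standard way to compare two markers, e.g. the same dose metric under two
normal-lung definitions, on one cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = ["ROCResult", "PairedAUCTest", "auc_mann_whitney", "delong_paired_test", "auc_variance"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class PairedAUCTest:
    auc1: float
    auc2: float
    difference: float       # auc1 - auc2
    variance: float         # var(auc1 - auc2)
    z: float
    p_value: float
    degenerate: bool = False


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return y


def _placements(scores: np.ndarray, y: np.ndarray):
    """Midrank placement values V10 (per event) and V01 (per non-event).

    mean(V10) = mean(V01) = AUC; their empirical variances feed the DeLong
    (co)variance estimator.
    """
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - sps.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - sps.rankdata(neg)) / m
    return v10, v01


def auc_mann_whitney(scores, labels) -> ROCResult:
    """AUC with midrank tie handling plus the empirical ROC curve."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    v10, _ = _placements(s, y)
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return ROCResult(float(v10.mean()), fpr, tpr, thr,
                     n_pos=int(y.sum()), n_neg=int((1 - y).sum()))


def auc_variance(scores, labels) -> tuple[float, float]:
    """Single-marker DeLong AUC and variance: s10/m + s01/n."""
    y = _check_labels(labels)
    v10, v01 = _placements(np.asarray(scores, dtype=float), y)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)
    return auc, var


def delong_paired_test(scores1, scores2, labels) -> PairedAUCTest:
    """DeLong's test for the difference of two correlated AUCs.

    Both markers must be measured on the same patients (paired design).  The
    variance of the difference uses the placement-value covariance; z is the
    difference over its standard error with a two-sided normal p.  Zero
    variance with zero difference (e.g. ``scores2`` a monotone transform of
    ``scores1``) gives p = 1; zero variance with a nonzero difference is
    flagged degenerate.
    """
    y = _check_labels(labels)
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape or s1.shape != y.shape:
        raise ValueError("scores1, scores2 and labels must have equal length")
    v10_1, v01_1 = _placements(s1, y)
    v10_2, v01_2 = _placements(s2, y)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    m, n = v10_1.size, v01_1.size
    if m < 2 or n < 2:  # placement variances need >= 2 of each class
        return PairedAUCTest(auc1, auc2, auc1 - auc2, math.nan, math.nan,
                             math.nan, degenerate=True)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    var = max(var, 0.0)
    diff = auc1 - auc2
    if var == 0.0:
        if abs(diff) < 1e-12:
            return PairedAUCTest(auc1, auc2, diff, 0.0, 0.0, 1.0)
        return PairedAUCTest(auc1, auc2, diff, 0.0, math.inf, 0.0, degenerate=True)
    z = diff / math.sqrt(var)
    return PairedAUCTest(auc1, auc2, diff, var, z, 2.0 * sps.norm.sf(abs(z)))
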