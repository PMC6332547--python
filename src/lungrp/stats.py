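"""The study's statistical battery.

* 2x2 odds ratios with Wald 95% CI and Wald p (closed form);
* univariate logistic regression (ML via statsmodels) with Wald inference —
  on a binary covariate it reproduces the 2x2 closed form exactly;
* Mann-Whitney U with midranks: exact enumeration for combined n <= 10,
  normal approximation with tie and continuity corrections otherwise;
* paired mean differences with t-based 95% CI;
* one-way within-subject (repeated-measures) ANOVA across the three
  lung-definition conditions.

All p-values are two-sided and no multiple-testing correction is applied
anywhere. Inference is Wald throughout (not profile likelihood): the printed
convention of the tables this package mirrors.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TwoByTwoTable",
    "OddsRatioResult",
    "LogisticFit",
    "MannWhitneyResult",
    "PairedComparison",
    "RMAnovaResult",
    "odds_ratio",
    "logistic_fit_univariate",
    "mann_whitney_u",
    "paired_mean_difference",
    "repeated_measures_anova",
]

_Z975 = sps.norm.ppf(0.975)

EXACT_MWU_MAX_N = 10  # combined sample size at or below which U is enumerated


@dataclass(frozen=True)
class TwoByTwoTable:
    """Events/non-events by exposed/reference group.

    a, b: events and non-events in group 1 (exposed);
    c, d: events and non-events in group 0 (reference).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError(f"cell counts must be non-negative integers, got {self}")

    @classmethod
    def from_arrays(cls, exposed, events) -> "TwoByTwoTable":
        exposed = np.asarray(exposed).astype(bool)
        events = np.asarray(events).astype(bool)
        return cls(
            a=int((exposed & events).sum()),
            b=int((exposed & ~events).sum()),
            c=int((~exposed & events).sum()),
            d=int((~exposed & ~events).sum()),
        )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    estimable: bool
    table: TwoByTwoTable


def odds_ratio(table: TwoByTwoTable) -> OddsRatioResult:
    """OR = (a/b)/(c/d) with Wald CI exp(ln OR ± 1.96·SE), SE = sqrt(Σ 1/cell).

    A zero cell makes the OR non-estimable: the degenerate point estimate
    (0 or inf) is still reported, flagged with ``estimable=False`` and NaN
    CI/p, mirroring tables that print "0.00" for empty event cells.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if a == 0 or d == 0:
            point = 0.0 if a == 0 else math.inf
        else:
            point = math.inf  # b == 0 or c == 0
        return OddsRatioResult(point, math.nan, math.nan, math.nan, False, table)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - _Z975 * se), math.exp(math.log(or_) + _Z975 * se)
    z = math.log(or_) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return OddsRatioResult(or_, lo, hi, p, True, table)


@dataclass(frozen=True)
class LogisticFit:
    beta: float
    intercept: float
    or_per_unit: float
    ci_low: float
    ci_high: float
    p_wald: float
    converged: bool
    message: str = ""


def logistic_fit_univariate(x, y) -> LogisticFit:
    """Univariate ML logistic regression of a binary outcome on one covariate.

    Newton-Raphson (IRLS) fit with Wald CI/p on exp(beta).  Complete or
    quasi-complete separation and non-identifiable (constant-x) designs are
    flagged with ``converged=False`` and NaN estimates — never silent numbers.
    Outcomes containing a single class are rejected outright.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate values must be finite")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        return LogisticFit(*[math.nan] * 6, converged=False,
                           message="slope non-identifiable: covariate is constant")

    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=200, tol=1e-12, disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        return LogisticFit(*[math.nan] * 6, converged=False, message=f"separation: {exc}")
    beta, se = float(res.params[1]), float(res.bse[1])
    if not res.mle_retvals.get("converged", False) or abs(beta) > 50 or not np.isfinite(se):
        return LogisticFit(*[math.nan] * 6, converged=False,
                           message="optimizer did not converge (possible separation)")
    return LogisticFit(
        beta=beta,
        intercept=float(res.params[0]),
        or_per_unit=math.exp(beta),
        ci_low=math.exp(beta - _Z975 * se),
        ci_high=math.exp(beta + _Z975 * se),
        p_wald=2.0 * sps.norm.sf(abs(beta / se)),
        converged=True,
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    Midranks handle ties; the two-sided p counts assignments whose U deviates
    from the null mean n_a*n_b/2 at least as much as the observed U.
    """
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    mu = na * nb / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = total = 0
    for idx in itertools.combinations(range(na + nb), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        total += 1
        if abs(u - mu) >= dev:
            hits += 1
    return u_obs, hits / total


def mann_whitney_u(sample_a, sample_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (equivalent to Wilcoxon rank-sum).

    Combined n <= 10 is enumerated exactly (midranks, so ties are allowed);
    larger samples use the normal approximation with tie correction and
    continuity correction.  Returns U for ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size + b.size <= EXACT_MWU_MAX_N:
        u, p = _exact_mwu_p(a, b)
        return MannWhitneyResult(u, p, "exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")


@dataclass(frozen=True)
class PairedComparison:
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False  # zero variance of the paired differences


def paired_mean_difference(x, y) -> PairedComparison:
    """Mean of (x - y) with t-based 95% CI and paired-t p-value.

    Callers pass the larger-volume definition first so the reported magnitude
    follows the larger-minus-smaller convention.  A zero-variance difference
    vector returns the point estimate with a degenerate-width CI and a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    if sd <= 1e-12 * max(abs(mean), 1.0):
        return PairedComparison(mean, mean, mean, 1.0 if mean == 0 else 0.0, degenerate=True)
    half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    t = mean / (sd / math.sqrt(n))
    return PairedComparison(mean, mean - half, mean + half, 2.0 * sps.t.sf(abs(t), n - 1))


@dataclass(frozen=True)
class RMAnovaResult:
    f: float
    p_value: float
    df_condition: int
    df_error: int
    degenerate: bool = False


def repeated_measures_anova(data) -> RMAnovaResult:
    """One-way within-subject ANOVA on an (n_subjects, k_conditions) matrix.

    F = MS_condition / MS_error after removing the subject effect; with k
    conditions the degrees of freedom are (k-1, (k-1)(n-1)).  Zero error
    variance with a real condition effect returns p = 0 flagged degenerate;
    identical columns (0/0) are flagged rather than propagating NaN silently.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an (n_subjects, k>=2 conditions) matrix")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    grand = data.mean()
    ss_cond = n * float(((data.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((data.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_c, df_e = k - 1, (k - 1) * (n - 1)
    if ss_err <= 1e-12 * max(ss_total, 1.0):
        if ss_cond <= 1e-12 * max(ss_total, 1.0):
            return RMAnovaResult(math.nan, math.nan, df_c, df_e, degenerate=True)
        return RMAnovaResult(math.inf, 0.0, df_c, df_e, degenerate=True)
    f = (ss_cond / df_c) / (ss_err / df_e)
    return RMAnovaResult(float(f), float(sps.f.sf(f, df_c, df_e)), df_c, df_e)
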