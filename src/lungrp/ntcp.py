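"""Lyman NTCP model with volume-effect exponent n = 1 (dose covariate = MLD).

The model maps mean lung dose through a probit curve,

    NTCP(D) = Phi(t),   t = (D - TD50) / (m * TD50),

where Phi is the standard normal CDF, TD50 the dose producing a 50%
complication probability (Gy) and m the relative slope.  With n = 1 the
generalized-EUD dose reduction collapses to the mean dose, so the model is a
two-parameter probit dose-response in MLD.  Parameters are estimated by
maximizing the Bernoulli log-likelihood over (TD50, m) with a deterministic
coarse grid search followed by Nelder-Mead refinement, so fits are
bit-reproducible.

The iso-risk cutoff dose is the exact inverse of the curve:

    D(p) = TD50 * (1 + m * Phi^-1(p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "LymanParams",
    "LymanFit",
    "LymanNTCP",
    "ntcp_lyman",
    "cutoff_dose",
    "solve_two_point",
    "fit_lyman_mle",
    "compare_definitions_ntcp",
]

_P_CLIP = 1e-12  # likelihood clipping bound for extreme parameter proposals

TD50_BOUNDS = (5.0, 60.0)
M_BOUNDS = (0.05, 2.0)


@dataclass(frozen=True)
class LymanParams:
    """Lyman model parameters; the volume exponent n is fixed at 1."""

    td50: float
    m: float
    n: int = 1

    def __post_init__(self):
        if self.td50 <= 0:
            raise ValueError(f"td50 must be > 0, got {self.td50}")
        if self.m <= 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        if self.n != 1:
            raise ValueError("only n = 1 (mean-dose reduction) is supported")


@dataclass(frozen=True)
class LymanFit:
    params: LymanParams
    log_likelihood: float
    converged: bool
    at_boundary: bool
    n_patients: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "td50_gy": self.params.td50,
            "m": self.params.m,
            "n": self.params.n,
            "loglik": self.log_likelihood,
            "converged": self.converged,
            "at_boundary": self.at_boundary,
            "n_patients": self.n_patients,
            "n_events": self.n_events,
        }


def ntcp_lyman(d_eff, params: LymanParams):
    """Complication probability at effective (mean) dose ``d_eff`` in Gy."""
    d = np.asarray(d_eff, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_eff must be >= 0")
    t = (d - params.td50) / (params.m * params.td50)
    p = ndtr(t)
    return float(p) if np.isscalar(d_eff) else p


def cutoff_dose(params: LymanParams, p_target: float) -> float:
    """Dose at which the curve crosses ``p_target``; exact inverse of the model."""
    if not 0.0 < p_target < 1.0:
        raise ValueError(f"p_target must be in (0, 1), got {p_target}")
    return float(params.td50 * (1.0 + params.m * ndtri(p_target)))


def solve_two_point(d1: float, p1: float, d2: float, p2: float) -> LymanParams:
    """Closed-form (TD50, m) through two (dose, probability) anchor points.

    From Phi^-1(p_i) = (d_i - TD50) / (m * TD50):
    TD50 = (z2*d1 - z1*d2) / (z2 - z1) and m = (d1 - TD50) / (z1 * TD50).
    """
    if d1 == d2 or p1 == p2:
        raise ValueError("anchor points must differ in both dose and probability")
    z1, z2 = ndtri(p1), ndtri(p2)
    td50 = (z2 * d1 - z1 * d2) / (z2 - z1)
    m = (d1 - td50) / (z1 * td50)
    return LymanParams(td50=float(td50), m=float(m))


def _neg_loglik(td50: float, m: float, doses: np.ndarray, y: np.ndarray) -> float:
    if td50 <= 0 or m <= 0:
        return np.inf
    p = np.clip(ndtr((doses - td50) / (m * td50)), _P_CLIP, 1.0 - _P_CLIP)
    return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


class LymanNTCP(ClassifierMixin, BaseEstimator):
    """Lyman (probit, n = 1) dose-response model as a scikit-learn estimator.

    Fits TD50 and m by Bernoulli maximum likelihood on a single dose feature
    (mean lung dose).  Deterministic: an exhaustive coarse grid over the
    parameter box is scanned first, then the best cell is refined with
    Nelder-Mead; there are no stochastic restarts.

    Parameters
    ----------
    td50_bounds, m_bounds : tuple of float
        Parameter box for the grid stage; a fit whose refined optimum escapes
        the box is flagged via ``at_boundary_``.
    td50_step, m_step : float
        Grid resolution of the coarse scan (Gy, dimensionless).

    Attributes
    ----------
    td50_ : float
        Fitted dose at 50% complication probability (Gy).
    m_ : float
        Fitted relative slope.
    log_likelihood_ : float
        Bernoulli log-likelihood at the optimum (<= 0).
    converged_ : bool
    at_boundary_ : bool
    """

    def __init__(
        self,
        td50_bounds: tuple[float, float] = TD50_BOUNDS,
        m_bounds: tuple[float, float] = M_BOUNDS,
        td50_step: float = 1.0,
        m_step: float = 0.05,
    ):
        self.td50_bounds = td50_bounds
        self.m_bounds = m_bounds
        self.td50_step = td50_step
        self.m_step = m_step

    def fit(self, X, y):
        X, y = check_X_y(np.reshape(X, (-1, 1)) if np.ndim(X) == 1 else X, y)
        if X.shape[1] != 1:
            raise ValueError("LymanNTCP takes a single dose feature")
        doses = X[:, 0].astype(float)
        if np.any(doses < 0):
            raise ValueError("doses must be >= 0")
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcomes must be binary 0/1")
        n_events = int(y.sum())
        if n_events == 0 or n_events == y.size:
            raise ValueError(
                "non-identifiable: need at least one event and one non-event"
            )
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = 1

        td50_grid = np.arange(self.td50_bounds[0], self.td50_bounds[1] + 1e-9, self.td50_step)
        m_grid = np.arange(self.m_bounds[0], self.m_bounds[1] + 1e-9, self.m_step)
        # vectorized grid scan: (n_td50, n_m, n_patients) handled in m-chunks
        best = (np.inf, td50_grid[0], m_grid[0])
        for m_val in m_grid:
            t = (doses[None, :] - td50_grid[:, None]) / (m_val * td50_grid[:, None])
            p = np.clip(ndtr(t), _P_CLIP, 1.0 - _P_CLIP)
            nll = -np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p), axis=1)
            i = int(np.argmin(nll))
            if nll[i] < best[0]:
                best = (float(nll[i]), float(td50_grid[i]), float(m_val))

        res = optimize.minimize(
            lambda th: _neg_loglik(th[0], th[1], doses, y),
            x0=np.array(best[1:]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        nll, (td50, m) = float(res.fun), res.x
        if nll > best[0]:  # refinement must never lose to its own start
            nll, td50, m = best
        self.td50_, self.m_ = float(td50), float(m)
        self.log_likelihood_ = -nll
        self.converged_ = bool(res.success)
        eps = 1e-6
        self.at_boundary_ = bool(
            td50 <= self.td50_bounds[0] + eps or td50 >= self.td50_bounds[1] - eps
            or m <= self.m_bounds[0] + eps or m >= self.m_bounds[1] - eps
        )
        self.n_patients_ = int(y.size)
        self.n_events_ = n_events
        return self

    @property
    def params_(self) -> LymanParams:
        check_is_fitted(self, "td50_")
        return LymanParams(td50=self.td50_, m=self.m_)

    def predict_proba(self, X):
        check_is_fitted(self, "td50_")
        X = check_array(np.reshape(X, (-1, 1)) if np.ndim(X) == 1 else X)
        p = ntcp_lyman(X[:, 0], self.params_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)


def fit_lyman_mle(doses, outcomes) -> LymanFit:
    """Maximum-likelihood Lyman fit of (TD50, m) on per-patient MLD/outcome data."""
    est = LymanNTCP().fit(np.asarray(doses, dtype=float), np.asarray(outcomes))
    return LymanFit(
        params=est.params_,
        log_likelihood=est.log_likelihood_,
        converged=est.converged_,
        at_boundary=est.at_boundary_,
        n_patients=est.n_patients_,
        n_events=est.n_events_,
    )


def compare_definitions_ntcp(
    fits: dict[str, LymanParams], dose_points
) -> pd.DataFrame:
    """Per dose point: each fit's probability plus pairwise relative differences.

    The relative difference between two definitions is taken with respect to
    the smaller probability, 100 * (p_high - p_low) / p_low, rounded to integer
    percent — e.g. probabilities 0.13 vs 0.20 give 54%, 0.20 vs 0.29 give 45%.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted definitions to compare")
    names = list(fits)
    rows = []
    for d in np.atleast_1d(np.asarray(dose_points, dtype=float)):
        row: dict = {"dose_gy": float(d)}
        for name in names:
            row[f"ntcp_{name}"] = ntcp_lyman(float(d), fits[name])
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                lo, hi = sorted((row[f"ntcp_{a}"], row[f"ntcp_{b}"]))
                if hi == lo:
                    rel = 0
                elif lo <= 0.0:  # both-vanishing tail: difference undefined
                    rel = np.nan
                else:
                    rel = int(round(100.0 * (hi - lo) / lo))
                row[f"rel_diff_pct_{a}_vs_{b}"] = rel
        rows.append(row)
    return pd.DataFrame(rows)
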