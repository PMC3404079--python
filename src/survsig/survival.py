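"""Censored-survival primitives: Kaplan–Meier, two-sample log-rank, Cox PH.

These are the building blocks for the marker screening, backward elimination
and cross-validated risk classification layers.  Times are in months.  The Cox
fitter maximizes the partial likelihood by Newton–Raphson (Efron tie handling
by default, Breslow optional) and reports Wald inference: for each coefficient
beta the hazard ratio exp(beta), the 95% CI exp(beta +/- 1.96 * SE) and the
two-sided Wald p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _cox_kernel as _k


class CoxError(ValueError):
    """Base class for Cox fitting failures."""


class NonIdentifiableError(CoxError):
    """Design matrix carries no information about a coefficient."""


class MonotoneLikelihoodError(CoxError):
    """Partial likelihood is maximized at an infinite coefficient."""


class ConvergenceError(CoxError):
    """Newton iteration failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored times for one endpoint: (time, event) per subject."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or time.size == 0:
            raise ValueError("time must be a nonempty 1-d array")
        if not np.all(np.isfinite(time)) or np.any(time < 0):
            raise ValueError("times must be finite and nonnegative")
        if event.shape != time.shape:
            raise ValueError("time and event must be aligned")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event flags must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int64))

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.time[idx], self.event[idx])


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct observed event times."""

    time: np.ndarray        # distinct event times, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray    # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event time."""
        i = np.searchsorted(self.time, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; NaN if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.time[below[0]]) if below.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time, "n_at_risk": self.n_at_risk,
            "n_events": self.n_events, "survival": self.survival,
        })


@dataclass(frozen=True)
class LogRankResult:
    """Two-sample log-rank chi-square (1 df) with its asymptotic p-value."""

    statistic: float
    p_value: float
    observed: np.ndarray   # events per group (group 0, group 1)
    expected: np.ndarray


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit with Wald inference per coefficient."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    covariance: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.names, "coef": self.coef, "se": self.se,
            "z": self.z, "p": self.p, "hr": self.hr,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        })


def kaplan_meier(surv: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censored-only times contribute to risk sets but create no curve step.
    """
    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    e = surv.event[order]
    n = len(t)
    times, at_risk, events = [], [], []
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            times.append(t[i])
            at_risk.append(n - i)
            events.append(d)
        i = j
    times = np.asarray(times, dtype=float)
    at_risk = np.asarray(at_risk, dtype=np.int64)
    events = np.asarray(events, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv_prob = np.cumprod(1.0 - events / at_risk)
    return KMCurve(times, at_risk, events, surv_prob)


def log_rank(surv: SurvivalData, groups) -> LogRankResult:
    """Two-sample log-rank test with hypergeometric variance.

    ``groups`` is a binary label per subject; both groups must be nonempty.
    """
    from scipy.stats import chi2

    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(
            f"log-rank comparison needs exactly 2 groups, got {labels.size}")
    gb = (g == labels[1]).astype(np.int64)

    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    e = surv.event[order]
    gi = gb[order]
    n = len(t)
    o1 = e1 = var = 0.0
    n_total = n
    n1 = int(gi.sum())
    obs = np.zeros(2)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            d1 = int(e[i:j][gi[i:j] == 1].sum())
            o1 += d1
            obs[0] += d - d1
            obs[1] += d1
            e1 += d * n1 / n_total
            if n_total > 1:
                var += (d * (n1 / n_total) * (1 - n1 / n_total)
                        * (n_total - d) / (n_total - 1))
        n_total -= j - i
        n1 -= int(gi[i:j].sum())
        i = j
    total_events = obs.sum()
    expected = np.array([total_events - e1, e1])
    stat = 0.0 if var == 0 else (o1 - e1) ** 2 / var
    p = float(chi2.sf(stat, df=1))
    return LogRankResult(float(stat), p, obs, expected)


def _as_design(X, names):
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def fit_cox(X, surv: SurvivalData, names: Sequence[str] | None = None, *,
            ties: str = "efron", tol: float = 1e-8, max_iter: int = 100,
            init: np.ndarray | None = None) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    X : (n, p) design matrix (array or DataFrame); no missing entries.
    surv : aligned survival endpoint.
    ties : "efron" (default) or "breslow".
    tol : gradient-norm convergence tolerance.
    init : optional warm-start coefficient vector.

    Raises
    ------
    NonIdentifiableError
        for constant columns or a singular information matrix (names the column).
    MonotoneLikelihoodError
        when a coefficient runs away (|beta| > 20), naming the column.
    ConvergenceError
        when the iteration cap is hit, reporting the iteration trace.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    X, names = _as_design(X, names)
    if X.shape[0] != len(surv):
        raise ValueError("design matrix and survival data are misaligned")
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing entries; "
                         "handle missingness before fitting")
    const = np.nonzero(np.ptp(X, axis=0) == 0)[0]
    if const.size:
        raise NonIdentifiableError(
            f"constant column(s) {[names[i] for i in const]} carry no information")
    order = np.argsort(surv.time, kind="stable")
    Xs = np.ascontiguousarray(X[order])
    ts = surv.time[order]
    es = surv.event[order]
    beta0 = np.zeros(X.shape[1]) if init is None else np.asarray(init, dtype=float).copy()
    efron = ties == "efron"
    nll0 = _k.nll_grad_hess(Xs, ts, es, np.zeros(X.shape[1]), efron)[0]
    beta, cov, nll, gnorm, n_iter, status, fail = _k.newton_cox(
        Xs, ts, es, beta0, efron, tol, max_iter)
    if status == _k.STATUS_SINGULAR:
        raise NonIdentifiableError(
            f"singular information matrix at column {names[fail]!r} "
            "(collinear or degenerate design)")
    if status == _k.STATUS_DIVERGED:
        raise MonotoneLikelihoodError(
            f"coefficient for {names[fail]!r} exceeds bound "
            f"{_k.DIVERGENCE_BOUND} (monotone likelihood)")
    if status == _k.STATUS_MAXITER:
        raise ConvergenceError(
            f"no convergence in {n_iter} iterations "
            f"(final |grad| = {gnorm:.3e}, beta = {np.round(beta, 4).tolist()})")
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = np.array([_k.wald_p(zi) for zi in z])
    hr = np.exp(beta)
    ci_lo = np.exp(beta - 1.96 * se)
    ci_hi = np.exp(beta + 1.96 * se)
    return CoxFit(names, beta, se, z, p, hr, ci_lo, ci_hi,
                  loglik=-nll, loglik_null=-nll0, n_iter=n_iter,
                  converged=True, covariance=cov)
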