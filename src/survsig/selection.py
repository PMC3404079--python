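"""Marker screening and multivariate model construction.

``univariate_screen`` fits one single-covariate Cox model per coded variable
and reports Wald p, hazard ratio and 95% CI, sorted by p.  ``backward_eliminate``
builds the multivariate signature: starting from the full candidate set (or the
univariate-significant subset), it iteratively refits and removes the eligible
variable with the largest Wald p while that p exceeds the stay threshold
(default 0.10).  Mandatory covariates (e.g. disease stage) enter the model and
are never eligible for removal.  ``prognostic_index`` evaluates the resulting
coefficient-weighted score: PI = sum_i beta_i * x_i, so a high PI means a high
predicted hazard.

Missing entries are excluded pairwise in univariate fits and listwise in
multivariate fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _cox_kernel as _k
from .coding import CodedMatrix
from .survival import SurvivalData, fit_cox, CoxError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class UnivariateReport:
    """Per-variable single-covariate Cox results, sorted by Wald p."""

    table: pd.DataFrame   # variable, n_used, coef, se, p, hr, ci_lower, ci_upper,
                          # significant, fit_failed
    alpha: float

    @property
    def significant(self) -> list:
        t = self.table
        return list(t.loc[t["significant"], "variable"])


@dataclass(frozen=True)
class PrognosticModel:
    """A selected variable set with Cox coefficients and Wald inference."""

    variables: list
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    loglik: float
    empty: bool
    forced_drops: list = field(default_factory=list)
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variables, "coef": self.coef, "se": self.se,
            "p": self.p, "hr": self.hr,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        })


def _design_frame(coded) -> pd.DataFrame:
    if isinstance(coded, CodedMatrix):
        return coded.data
    if isinstance(coded, pd.DataFrame):
        return coded
    raise TypeError("expected a CodedMatrix or DataFrame")


def univariate_screen(coded, surv: SurvivalData,
                      alpha: float = 0.05) -> UnivariateReport:
    """Screen every variable with a single-covariate Cox fit.

    Variables whose fit fails (e.g. monotone likelihood for a near-degenerate
    marker) are reported with ``fit_failed=True`` rather than dropped.
    """
    data = _design_frame(coded)
    if len(data) != len(surv):
        raise ValueError("coded matrix and survival data are misaligned")
    rows = []
    for name in data.columns:
        x = data[name].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        row = {"variable": name, "n_used": int(ok.sum()),
               "coef": np.nan, "se": np.nan, "p": np.nan, "hr": np.nan,
               "ci_lower": np.nan, "ci_upper": np.nan,
               "significant": False, "fit_failed": False}
        try:
            fit = fit_cox(x[ok, None], surv.subset(ok), names=[name])
            row.update(coef=fit.coef[0], se=fit.se[0], p=fit.p[0],
                       hr=fit.hr[0], ci_lower=fit.ci_lower[0],
                       ci_upper=fit.ci_upper[0],
                       significant=bool(fit.p[0] < alpha))
        except CoxError as exc:
            row["fit_failed"] = True
            log.warning("univariate fit failed for %s: %s", name, exc)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["fit_failed", "p", "variable"], na_position="last",
        kind="stable").reset_index(drop=True)
    return UnivariateReport(table, alpha)


def _prepare_matrix(data: pd.DataFrame, surv: SurvivalData):
    """Listwise-complete, time-sorted arrays plus kernel bookkeeping."""
    X = data.to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    if not complete.all():
        log.warning("dropping %d subjects with missing entries (listwise)",
                    int((~complete).sum()))
    X = X[complete]
    sub = surv.subset(complete)
    order = np.argsort(sub.time, kind="stable")
    return (np.ascontiguousarray(X[order]), sub.time[order], sub.event[order],
            complete, order)


def _kernel_ranks(names) -> np.ndarray:
    """Lexicographic rank per column (larger = later name) for tie-breaking."""
    return np.argsort(np.argsort(np.asarray(names, dtype=object))).astype(np.int64)


def independent_columns(data: pd.DataFrame, keep_first=()):
    """Resolve exact collinearity by dropping reference levels.

    The Cox partial likelihood absorbs constants, so an exhaustive set of
    indicator columns (e.g. the three genotypes of a SNP, which sum to 1) is
    rank-deficient.  Columns are admitted to an orthogonal basis seeded with
    the intercept direction, rarest first, so that within each exact-dependency
    group the most frequent column — the natural reference level — is the one
    dropped.  ``keep_first`` columns (mandatory covariates) are admitted before
    all others.  Returns (kept, dropped) name lists, both in original column
    order.
    """
    X = data.to_numpy(dtype=float)
    X = np.where(np.isnan(X), 0.0, X)  # rank structure only; NaN rows are
    n, p = X.shape                     # handled listwise by the caller
    names = list(data.columns)
    freq = np.nanmean(data.to_numpy(dtype=float), axis=0)
    prio = {c: i for i, c in enumerate(keep_first)}
    order = sorted(range(p),
                   key=lambda j: (prio.get(names[j], len(prio)),
                                  freq[j], names[j]))
    basis = np.ones((n, 1)) / np.sqrt(n)
    kept = []
    dropped = []
    for j in order:
        v = X[:, j]
        norm0 = np.linalg.norm(v)
        r = v - basis @ (basis.T @ v)
        # second re-orthogonalization pass for numerical robustness
        r = r - basis @ (basis.T @ r)
        if norm0 == 0 or np.linalg.norm(r) <= 1e-8 * max(norm0, 1.0):
            dropped.append(names[j])
        else:
            kept.append(names[j])
            basis = np.hstack([basis, (r / np.linalg.norm(r))[:, None]])
    keep_set = set(kept)
    return ([c for c in names if c in keep_set],
            [c for c in names if c not in keep_set])


def backward_eliminate(coded, surv: SurvivalData, p_remove: float = 0.10,
                       mandatory=(), entry: str = "all",
                       alpha_entry: float = 0.05,
                       ties: str = "efron") -> PrognosticModel:
    """Backward-elimination Cox model over the coded variables.

    Parameters
    ----------
    mandatory : names of columns (present in ``coded``) that always stay.
    entry : "all" offers every column as a candidate; "univariate" offers only
        the univariately significant ones (at ``alpha_entry``) plus mandatory.
    p_remove : stay threshold on the Wald p (variables with p above it are
        removed one at a time, largest first).

    Non-identifiable or diverging columns encountered during fitting are
    force-dropped with a logged warning.  If every variable is eliminated the
    returned model is empty (``empty=True``) and its prognostic index is 0.
    """
    if not 0.0 < p_remove < 1.0:
        raise ValueError(f"p_remove must lie in (0, 1), got {p_remove}")
    if entry not in ("all", "univariate"):
        raise ValueError(f"unknown entry mode {entry!r}")
    data = _design_frame(coded)
    if len(data) != len(surv):
        raise ValueError("coded matrix and survival data are misaligned")
    mandatory = list(mandatory)
    for m in mandatory:
        if m not in data.columns:
            raise ValueError(f"mandatory covariate {m!r} not in matrix")
    if entry == "univariate":
        keep = univariate_screen(coded, surv, alpha=alpha_entry).significant
        cols = [c for c in data.columns if c in set(keep) or c in set(mandatory)]
        data = data[cols]
    kept, collinear = independent_columns(data, keep_first=mandatory)
    if collinear:
        log.warning("dropping reference/collinear columns: %s", collinear)
        data = data[kept]
    names = list(data.columns)
    Xs, ts, es, complete, _ = _prepare_matrix(data, surv)
    is_mand = np.array([c in set(mandatory) for c in names])
    active0 = np.arange(len(names), dtype=np.int64)
    active, beta, se, pvals, nll, flags, forced, _ = _k.backward_eliminate_core(
        Xs, ts, es, active0, is_mand, _kernel_ranks(names),
        p_remove, ties == "efron", 1e-8, 100, np.zeros(len(names)))
    kernel_forced = [names[i] for i in forced]
    if kernel_forced:
        warnings.warn(f"force-dropped non-identifiable/diverging columns: "
                      f"{kernel_forced}", stacklevel=2)
        log.warning("force-dropped columns: %s", kernel_forced)
    forced_names = collinear + kernel_forced
    sel = [names[i] for i in active]
    hr = np.exp(beta)
    return PrognosticModel(
        variables=sel, coef=beta, se=se, p=pvals, hr=hr,
        ci_lower=np.exp(beta - 1.96 * se), ci_upper=np.exp(beta + 1.96 * se),
        loglik=-nll, empty=len(sel) == 0, forced_drops=forced_names,
        converged=not (flags & _k.FLAG_NONCONVERGED))


def prognostic_index(model: PrognosticModel, x):
    """Coefficient-weighted prognostic score PI = sum_i beta_i x_i.

    ``x`` may be a DataFrame/Series/dict/array providing every model variable;
    missing entries raise.  An empty model scores 0 for any input.
    """
    if isinstance(x, pd.DataFrame):
        if model.empty:
            return np.zeros(len(x))
        missing = [v for v in model.variables if v not in x.columns]
        if missing:
            raise ValueError(f"input lacks model variables {missing}")
        vals = x[model.variables].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("missing entries for model variables; "
                             "impute or exclude those subjects")
        return vals @ model.coef
    if isinstance(x, (pd.Series, dict)):
        if model.empty:
            return 0.0
        try:
            vals = np.array([float(x[v]) for v in model.variables])
        except KeyError as exc:
            raise ValueError(f"input lacks model variable {exc}") from exc
        if np.isnan(vals).any():
            raise ValueError("missing entry for a model variable")
        return float(vals @ model.coef)
    arr = np.asarray(x, dtype=float)
    if model.empty:
        return 0.0 if arr.ndim == 1 else np.zeros(arr.shape[0])
    if arr.shape[-1] != len(model.variables):
        raise ValueError("input length does not match the model variables")
    if np.isnan(arr).any():
        raise ValueError("missing entry for a model variable")
    return arr @ model.coef
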