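"""Leave-one-out cross-validated survival risk classification.

For each of the n folds the *entire* model-building procedure — backward
elimination included — is repeated on the n-1 training subjects.  The held-out
subject's prognostic index is compared with the median training prognostic
index and the subject is assigned to the high-risk group iff PI >= median
(ties at the median go to high risk).  After all folds, Kaplan–Meier curves
and the two-group log-rank statistic LR_d are computed between the
cross-validated groups; because no subject's group used its own data, the
separation between those curves is an honest estimate of predictive value,
unlike the optimistic resubstitution split (provided here for contrast).

``cross_endpoint_validate`` runs the identical fold loop with model building
and the median computed from the training endpoint (e.g. OS) but evaluates the
resulting groups on a second endpoint (e.g. RFS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _cox_kernel as _k
from .selection import (PrognosticModel, _design_frame, _prepare_matrix,
                        _kernel_ranks, backward_eliminate, prognostic_index)
from .survival import SurvivalData, KMCurve, LogRankResult, kaplan_meier, log_rank

log = logging.getLogger(__name__)

HIGH, LOW = "high", "low"

MIN_SUBJECTS = 10


@dataclass(frozen=True)
class CvRiskResult:
    """Cross-validated risk classification and its group-level summaries."""

    subject_ids: list
    pi: np.ndarray                  # cross-validated prognostic index
    group: np.ndarray               # "high" / "low" per subject
    logrank: LogRankResult          # LR_d between the cross-validated groups
    km: dict                        # group -> KMCurve on the evaluation endpoint
    group_sizes: dict
    group_events: dict
    median_survival: dict
    fold_flags: np.ndarray          # per-fold kernel flags (0 = clean)
    fold_models: list = field(default=None, repr=False)

    def summary(self) -> str:
        lines = []
        for g in (LOW, HIGH):
            med = self.median_survival[g]
            med_s = f"{med:.1f} months" if np.isfinite(med) else "not reached"
            lines.append(f"{self.group_sizes[g]} patients "
                         f"({self.group_events[g]} events) in the {g} risk group "
                         f"(median survival: {med_s})")
        lines.append(f"log-rank LR_d = {self.logrank.statistic:.4f}, "
                     f"asymptotic p = {self.logrank.p_value:.4g}")
        return "\n".join(lines)

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "cv_prognostic_index": self.pi,
                             "risk_group": self.group})


def _evaluate_groups(eval_surv: SurvivalData, group: np.ndarray):
    hi = group == HIGH
    km = {HIGH: kaplan_meier(eval_surv.subset(hi)) if hi.any() else None,
          LOW: kaplan_meier(eval_surv.subset(~hi)) if (~hi).any() else None}
    if hi.all() or (~hi).all():
        # a degenerate classifier that puts everyone in one group separates
        # nothing: LR_d = 0 by definition (keeps permutation nulls honest)
        obs = np.array([eval_surv.event[~hi].sum(), eval_surv.event[hi].sum()],
                       dtype=float)
        lr = LogRankResult(0.0, 1.0, obs, obs.copy())
    else:
        lr = log_rank(eval_surv, hi.astype(int))
    sizes = {HIGH: int(hi.sum()), LOW: int((~hi).sum())}
    events = {HIGH: int(eval_surv.event[hi].sum()),
              LOW: int(eval_surv.event[~hi].sum())}
    medians = {g: (km[g].median() if km[g] is not None else float("nan"))
               for g in (HIGH, LOW)}
    return km, lr, sizes, events, medians


def _fold_details(Xs, ts, es, active0, is_mand, ranks, p_remove, efron):
    """Python re-run of the fold loop collecting per-fold models (same kernel)."""
    n = Xs.shape[0]
    # same warm start as the assignment kernel, for fold-for-fold agreement
    beta_init = np.zeros(len(active0))
    if len(active0):
        b0, _, _, _, _, st0, _ = _k.newton_cox(
            np.ascontiguousarray(Xs[:, active0]), ts, es,
            beta_init.copy(), efron, 1e-8, 100)
        if st0 == _k.STATUS_OK:
            beta_init = b0
    models = []
    for held in range(n):
        keep = np.arange(n) != held
        active, beta, se, pvals, nll, flags, forced, _ = _k.backward_eliminate_core(
            np.ascontiguousarray(Xs[keep]), ts[keep], es[keep],
            active0, is_mand, ranks, p_remove, efron, 1e-8, 100, beta_init)
        models.append({"columns": active.copy(), "coef": beta.copy(),
                       "flags": int(flags)})
    return models


def _loocv_groups(design: pd.DataFrame, train_surv: SurvivalData,
                  mandatory, p_remove, feature_selection, ties,
                  collect_folds):
    names = list(design.columns)
    mandatory = list(mandatory)
    for m in mandatory:
        if m not in names:
            raise ValueError(f"mandatory covariate {m!r} not in matrix")
    if not feature_selection:
        cols = [c for c in names if c in set(mandatory)]
        design = design[cols]
        names = cols
    else:
        from .selection import independent_columns
        kept, collinear = independent_columns(design, keep_first=mandatory)
        if collinear:
            log.warning("dropping reference/collinear columns: %s", collinear)
            design = design[kept]
            names = kept
    Xs, ts, es, complete, order = _prepare_matrix(design, train_surv)
    n = Xs.shape[0]
    if n < MIN_SUBJECTS:
        raise ValueError(
            f"LOOCV needs at least {MIN_SUBJECTS} complete subjects, got {n}")
    if not complete.all():
        raise ValueError("LOOCV requires complete coded rows; "
                         "exclude or impute missing entries first")
    is_mand = np.array([c in set(mandatory) for c in names])
    ranks = _kernel_ranks(names)
    active0 = np.arange(len(names), dtype=np.int64)
    efron = ties == "efron"
    g_sorted, pi_sorted, flags_sorted = _k.loocv_assign(
        Xs, ts, es, active0, is_mand, ranks, p_remove, efron, 1e-8, 100)
    # map back from time-sorted order to input order
    group = np.empty(n, dtype=object)
    pi = np.empty(n)
    flags = np.empty(n, dtype=np.int64)
    group[order] = np.where(g_sorted == 1, HIGH, LOW)
    pi[order] = pi_sorted
    flags[order] = flags_sorted
    fold_models = None
    if collect_folds:
        details = _fold_details(Xs, ts, es, active0, is_mand, ranks,
                                p_remove, efron)
        fold_models = [None] * n
        for s, m in enumerate(details):
            fold_models[order[s]] = {"variables": [names[j] for j in m["columns"]],
                                     "coef": m["coef"], "flags": m["flags"]}
    return group, pi, flags, fold_models


def loocv_risk_classify(coded, surv: SurvivalData, mandatory=(), *,
                        p_remove: float = 0.10, feature_selection: bool = True,
                        ties: str = "efron",
                        collect_folds: bool = False) -> CvRiskResult:
    """Leave-one-out cross-validated risk-group classification.

    With ``feature_selection=False`` the per-fold model contains exactly the
    mandatory covariates (the "covariate model"); otherwise every fold runs
    backward elimination from the full candidate set.
    """
    design = _design_frame(coded)
    if len(design) != len(surv):
        raise ValueError("coded matrix and survival data are misaligned")
    group, pi, flags, fold_models = _loocv_groups(
        design, surv, mandatory, p_remove, feature_selection, ties,
        collect_folds)
    km, lr, sizes, events, medians = _evaluate_groups(surv, group)
    return CvRiskResult(list(design.index), pi, group, lr, km, sizes, events,
                        medians, flags, fold_models)


def cross_endpoint_validate(coded, train_surv: SurvivalData,
                            test_surv: SurvivalData, mandatory=(), *,
                            p_remove: float = 0.10,
                            feature_selection: bool = True,
                            ties: str = "efron",
                            collect_folds: bool = False) -> CvRiskResult:
    """Build per-fold models and risk groups on one endpoint, evaluate on another.

    The fold loop, model building and median split use ``train_surv`` (e.g.
    OS); the final Kaplan–Meier curves and log-rank statistic are computed
    against ``test_surv`` (e.g. RFS).  With identical endpoints this equals
    ``loocv_risk_classify``.
    """
    design = _design_frame(coded)
    if len(design) != len(train_surv) or len(design) != len(test_surv):
        raise ValueError("coded matrix and survival endpoints are misaligned")
    group, pi, flags, fold_models = _loocv_groups(
        design, train_surv, mandatory, p_remove, feature_selection, ties,
        collect_folds)
    km, lr, sizes, events, medians = _evaluate_groups(test_surv, group)
    return CvRiskResult(list(design.index), pi, group, lr, km, sizes, events,
                        medians, flags, fold_models)


def resubstitution_classify(coded, surv: SurvivalData, mandatory=(), *,
                            p_remove: float = 0.10,
                            feature_selection: bool = True,
                            ties: str = "efron") -> CvRiskResult:
    """Non-cross-validated median split (the optimistic reference).

    The model is built once on all subjects and the same subjects are split at
    the median of their own prognostic indices; the resulting log-rank
    statistic is biased upward, which is exactly why the cross-validated LR_d
    exists.  Provided for optimism-contrast diagnostics.
    """
    design = _design_frame(coded)
    if len(design) != len(surv):
        raise ValueError("coded matrix and survival data are misaligned")
    if feature_selection:
        model = backward_eliminate(design, surv, p_remove=p_remove,
                                   mandatory=mandatory, ties=ties)
    else:
        from .survival import fit_cox
        cols = list(mandatory)
        fit = fit_cox(design[cols], surv, ties=ties)
        model = PrognosticModel(cols, fit.coef, fit.se, fit.p, fit.hr,
                                fit.ci_lower, fit.ci_upper, fit.loglik,
                                empty=False)
    pi = np.asarray(prognostic_index(model, design), dtype=float)
    if np.ndim(pi) == 0:
        pi = np.zeros(len(design))
    med = np.median(pi)
    group = np.where(pi >= med, HIGH, LOW)
    km, lr, sizes, events, medians = _evaluate_groups(surv, group)
    return CvRiskResult(list(design.index), pi, group, lr, km, sizes, events,
                        medians, np.zeros(len(design), dtype=np.int64),
                        [{"variables": model.variables, "coef": model.coef,
                          "flags": 0}])
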