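"""Time-dependent ROC curves and AUC(t) from censored survival data.

Cumulative-case / dynamic-control construction: at horizon t, cases are
subjects with an event by t and controls are subjects still event-free at t,

    sensitivity(c, t) = P(M > c | T <= t)
    specificity(c, t) = P(M <= c | T > t).

Under censoring these are estimated through Bayes' rule from Kaplan–Meier
estimates — the overall S(t) and the conditional S(t | M > c) within the
marker stratum above each threshold:

    TP(c, t) = [1 - S(t | M > c)] P(M > c) / [1 - S(t)]
    FP(c, t) = S(t | M > c) P(M > c) / S(t)

with P(M > c) the empirical marker-exceedance fraction.  The KM-plug-in
estimator is not guaranteed monotone in c; estimates are clipped to [0, 1] and
made monotone by a cumulative maximum along the threshold sweep (disable with
``monotone=False`` for diagnostics).  AUC(t) is the trapezoidal area under the
(FP, TP) curve.  Without censoring the construction reduces exactly to the
empirical (Mann–Whitney) ROC between cases and controls at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import SurvivalData, kaplan_meier


@dataclass(frozen=True)
class TimeROC:
    """ROC curve for the outcome "event by time t" under censoring."""

    t: float
    thresholds: np.ndarray   # descending; +/- inf anchors
    tp: np.ndarray
    fp: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fp": self.fp, "tp": self.tp})


def time_dependent_roc(marker, surv: SurvivalData, t: float, *,
                       monotone: bool = True) -> TimeROC:
    """Cumulative/dynamic time-dependent ROC of a continuous marker at time t.

    Raises if no event has occurred by t (sensitivity undefined) or if t lies
    beyond the last follow-up time (no controls remain at risk).
    """
    m = np.asarray(marker, dtype=float)
    if m.shape != (len(surv),):
        raise ValueError("marker vector misaligned with survival data")
    if np.isnan(m).any():
        raise ValueError("marker contains missing values")
    if not t > 0:
        raise ValueError(f"evaluation time must be positive, got {t}")
    if t > surv.time.max():
        raise ValueError(f"t = {t} lies beyond the last follow-up time "
                         f"({surv.time.max():.4g})")
    km_all = kaplan_meier(surv)
    s_t = km_all.survival_at(t)
    if s_t >= 1.0:
        raise ValueError(f"no events observed by t = {t}; "
                         "sensitivity is undefined")
    if not (surv.time > t).any():
        raise ValueError(f"no subjects remain at risk beyond t = {t}")

    uniq = np.unique(m)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    tp = np.empty(thresholds.size)
    fp = np.empty(thresholds.size)
    n = len(surv)
    for i, c in enumerate(thresholds):
        above = m > c
        p_above = above.sum() / n
        if p_above == 0.0:
            tp[i] = fp[i] = 0.0
            continue
        s_c = kaplan_meier(surv.subset(above)).survival_at(t)
        tp[i] = (1.0 - s_c) * p_above / (1.0 - s_t)
        fp[i] = 0.0 if s_t == 0.0 else s_c * p_above / s_t
    tp = np.clip(tp, 0.0, 1.0)
    fp = np.clip(fp, 0.0, 1.0)
    if monotone:
        tp = np.maximum.accumulate(tp)
        fp = np.maximum.accumulate(fp)
    tp[-1] = 1.0
    fp[-1] = 1.0
    auc = float(np.trapezoid(tp, fp))
    return TimeROC(float(t), thresholds, tp, fp, auc)


def auc_timeline(marker, surv: SurvivalData, times) -> pd.DataFrame:
    """AUC(t) at each requested horizon.

    Returns a frame with columns (time, auc, note); horizons that violate the
    ROC preconditions get NaN with the reason in ``note``.
    """
    times = list(times)
    if not times:
        raise ValueError("empty list of evaluation times")
    rows = []
    for t in times:
        try:
            roc = time_dependent_roc(marker, surv, t)
            rows.append({"time": float(t), "auc": roc.auc, "note": ""})
        except ValueError as exc:
            rows.append({"time": float(t), "auc": np.nan, "note": str(exc)})
    return pd.DataFrame(rows)
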