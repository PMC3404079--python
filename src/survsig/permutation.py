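"""Permutation nulls for the cross-validated log-rank statistic.

Two constructions:

``permutation_significance``
    Does the marker panel associate with survival at all?  The (time, event)
    pairs are shuffled jointly among subjects (genotypes fixed) and the entire
    leave-one-out procedure — per-fold feature selection included — is rerun,
    yielding a null sample of the cross-validated LR_d.

``compare_with_covariate``
    Do the markers add to a clinical covariate (stage)?  The test statistic is
    LR_d(combined model: markers + mandatory covariate) minus LR_d(covariate-
    only model).  Null replicates permute whole genotype rows among subjects
    while the (time, event, covariate) triples stay fixed, so the covariate
    model — whose inputs the permutation never touches — keeps its observed
    value in every replicate.

Both use the add-one estimator p = (1 + #{null >= observed}) / (1 + B), which
is a valid p-value and never returns 0.  Each replicate draws from its own
seed stream spawned from the master seed, so serial and parallel execution
produce bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .crossval import loocv_risk_classify
from .selection import _design_frame
from .survival import SurvivalData

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null sample, and the tail p-value."""

    observed: float
    null: np.ndarray
    p_value: float
    B: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self):
        assert self.null.shape == (self.B,)


def _add_one_p(observed: float, null: np.ndarray) -> float:
    return (1.0 + int(np.sum(null >= observed))) / (1.0 + null.size)


def _replicate_seeds(seed: int, B: int):
    return np.random.SeedSequence(seed).spawn(B)


def _run_replicates(worker, seeds, n_jobs):
    """Run one worker per replicate seed; failed replicates are redrawn from a
    child of their own stream (logged), never silently dropped."""

    def safe(ss):
        redrawn = 0
        while True:
            rng = np.random.default_rng(ss)
            try:
                return worker(rng), redrawn
            except Exception as exc:  # noqa: BLE001 - flagged and redrawn
                redrawn += 1
                log.warning("permutation replicate failed (%s); redrawing", exc)
                if redrawn > 10:
                    raise
                ss = ss.spawn(1)[0]

    if n_jobs == 1:
        out = [safe(ss) for ss in seeds]
    else:
        out = Parallel(n_jobs=n_jobs)(delayed(safe)(ss) for ss in seeds)
    stats = np.array([o[0] for o in out], dtype=float)
    redrawn = int(sum(o[1] for o in out))
    return stats, redrawn


def permutation_significance(coded, surv: SurvivalData, mandatory=(), *,
                             p_remove: float = 0.10, B: int = 500,
                             seed: int = 0, n_jobs: int = 1,
                             feature_selection: bool = True) -> PermutationResult:
    """Survival-shuffle permutation test of the cross-validated LR_d."""
    if B < 1:
        raise ValueError("B must be >= 1")
    design = _design_frame(coded)
    observed = loocv_risk_classify(
        design, surv, mandatory, p_remove=p_remove,
        feature_selection=feature_selection).logrank.statistic
    n = len(surv)

    def worker(rng):
        perm = rng.permutation(n)
        shuffled = SurvivalData(surv.time[perm], surv.event[perm])
        return loocv_risk_classify(
            design, shuffled, mandatory, p_remove=p_remove,
            feature_selection=feature_selection).logrank.statistic

    null, redrawn = _run_replicates(worker, _replicate_seeds(seed, B), n_jobs)
    return PermutationResult(observed, null, _add_one_p(observed, null),
                             B, seed, redrawn)


def compare_with_covariate(coded, covariate, surv: SurvivalData, *,
                           covariate_name: str = "stage",
                           p_remove: float = 0.10, B: int = 500,
                           seed: int = 0, n_jobs: int = 1) -> PermutationResult:
    """Added value of the marker panel beyond a mandatory covariate.

    ``coded`` holds the genotype columns; ``covariate`` is the aligned stage
    vector.  Observed statistic: LR_d(markers + covariate, covariate mandatory)
    - LR_d(covariate alone).  Null: permute genotype rows, keep (time, event,
    covariate) fixed, recompute the combined model's LR_d.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    design = _design_frame(coded)
    cov = np.asarray(covariate, dtype=float)
    if cov.shape != (len(design),):
        raise ValueError("covariate vector misaligned with coded matrix")
    if covariate_name in design.columns:
        raise ValueError(f"{covariate_name!r} already a column of the matrix")
    combined = design.copy()
    combined[covariate_name] = cov

    # covariate-only model: mandatory covariate, no feature selection; its
    # inputs are untouched by the genotype permutation, so one evaluation
    # serves every replicate.
    lr_cov = loocv_risk_classify(
        combined[[covariate_name]], surv, [covariate_name],
        p_remove=p_remove, feature_selection=False).logrank.statistic
    lr_comb = loocv_risk_classify(
        combined, surv, [covariate_name], p_remove=p_remove).logrank.statistic
    observed = lr_comb - lr_cov
    n = len(design)
    geno = design.to_numpy(dtype=float)
    marginal_events = int(surv.event.sum())

    def worker(rng):
        perm = rng.permutation(n)
        pc = combined.copy()
        pc.iloc[:, :geno.shape[1]] = geno[perm]
        # permuting genotype rows must leave the cohort's survival marginal
        # untouched - the endpoint arrays are never reindexed
        assert int(surv.event.sum()) == marginal_events
        lr_b = loocv_risk_classify(
            pc, surv, [covariate_name], p_remove=p_remove).logrank.statistic
        return lr_b - lr_cov

    null, redrawn = _run_replicates(worker, _replicate_seeds(seed, B), n_jobs)
    return PermutationResult(observed, null, _add_one_p(observed, null),
                             B, seed, redrawn)
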