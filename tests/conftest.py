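import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from survsig.coding import CodedMatrix
from survsig.cohort import (CohortConfig, CensoringSpec, LocusSpec, EffectSpec,
                            simulate_survival)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# simulation noise is intentional in this suite; keep logs quiet
logging.getLogger("survsig").setLevel(logging.ERROR)


def bernoulli_coded(n, p, seed, freq=0.3, prefix="M") -> CodedMatrix:
    """Independent binary marker matrix (freq = carrier fraction)."""
    rng = np.random.default_rng([21, seed])
    X = (rng.random((n, p)) < freq).astype(float)
    names = [f"{prefix}{j:02d}" for j in range(p)]
    df = pd.DataFrame(X, index=[f"S{i + 1:04d}" for i in range(n)],
                      columns=names)
    return CodedMatrix(df, {c: c for c in names})


def survival_for(coded, seed, effects=(), rate=0.0072, stage=None,
                 stage_log_hazard=0.0, censoring=CensoringSpec(90.0, 120.0)):
    """OS/RFS endpoints for a coded matrix under the standard censoring mix."""
    n = len(coded)
    cfg = CohortConfig(
        n_subjects=n,
        loci=[LocusSpec("D", "multiallelic", ("a", "b"), (0.5, 0.5))],
        effects=[EffectSpec(v, math.log(hr)) for v, hr in effects],
        baseline_rate=rate, censoring=censoring,
        stage_log_hazard=stage_log_hazard, seed=seed)
    if stage is None:
        stage = np.zeros(n, dtype=int)
    return simulate_survival(coded, stage, cfg)


@pytest.fixture(scope="session")
def planted_replicates():
    """Ten planted-scenario replicates (n = 150) with LOOCV, resubstitution
    and cross-endpoint summaries; shared across optimism and power checks."""
    from survsig import (make_scenario, simulate_genotypes, simulate_stage,
                         code_alleles, filter_by_frequency)
    from survsig.crossval import loocv_risk_classify, resubstitution_classify
    from survsig.survival import log_rank
    reps = []
    for s in range(10):
        cfg = make_scenario("planted_five_marker", n_subjects=150,
                            seed=100 + s)
        coded_all = code_alleles(simulate_genotypes(cfg))
        stage = simulate_stage(cfg)
        os_surv, rfs_surv = simulate_survival(coded_all, stage, cfg)
        analysis = filter_by_frequency(coded_all).drop_loci(["FOXP3"])
        cv = loocv_risk_classify(analysis, os_surv)
        rs = resubstitution_classify(analysis, os_surv)
        hi = (cv.group == "high").astype(int)
        rfs_lr = log_rank(rfs_surv, hi) if 0 < hi.sum() < len(hi) else None
        reps.append({"cv": cv, "resub": rs, "os": os_surv, "rfs": rfs_surv,
                     "analysis": analysis, "rfs_logrank": rfs_lr})
    return reps


@pytest.fixture(scope="session")
def null_scenario_replicates():
    """Twenty full-panel null-scenario replicates (n = 120) with LOOCV and
    resubstitution log-rank statistics, for calibration checks."""
    from survsig import (make_scenario, simulate_genotypes, simulate_stage,
                         code_alleles, filter_by_frequency)
    from survsig.crossval import loocv_risk_classify, resubstitution_classify
    reps = []
    for s in range(20):
        cfg = make_scenario("null", n_subjects=120, seed=700 + s)
        coded_all = code_alleles(simulate_genotypes(cfg))
        stage = simulate_stage(cfg)
        os_surv, _ = simulate_survival(coded_all, stage, cfg)
        analysis = filter_by_frequency(coded_all).drop_loci(["FOXP3"])
        cv = loocv_risk_classify(analysis, os_surv)
        rs = resubstitution_classify(analysis, os_surv)
        reps.append({"cv": cv, "resub": rs})
    return reps


@pytest.fixture(scope="session")
def planted_cohort():
    """One fixed planted-scenario cohort at the reference size."""
    from survsig import (make_scenario, simulate_genotypes, simulate_stage,
                         code_alleles, filter_by_frequency)
    cfg = make_scenario("planted_five_marker", seed=0)
    coded_all = code_alleles(simulate_genotypes(cfg))
    stage = simulate_stage(cfg)
    os_surv, rfs_surv = simulate_survival(coded_all, stage, cfg)
    analysis = filter_by_frequency(coded_all).drop_loci(["FOXP3"])
    return {"config": cfg, "coded_all": coded_all, "analysis": analysis,
            "stage": stage, "os": os_surv, "rfs": rfs_surv}
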