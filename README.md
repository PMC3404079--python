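# survsig

Cross-validated survival risk signatures from immunogenetic marker panels.

`survsig` is a toolkit for a question that comes up whenever a cohort of
treated cancer patients has been genotyped at candidate immune loci: *does a
combination of genetic markers — HLA alleles, SNP genotypes, microsatellite
alleles — predict survival, and does it add anything beyond clinical
covariates like disease stage?*  Individually such markers are usually only
weakly prognostic; the methodology here evaluates them **in concert**, with
cross-validation and permutation inference guarding against the severe
selection optimism that multivariate model building produces.

The package is aimed at biostatisticians and translational researchers
analyzing genotype + survival tables (e.g. melanoma patients on adjuvant
interferon, typed for HLA-A/B/C/DRB1/DQB1, CTLA4 SNPs and a FOXP3
microsatellite), and ships a synthetic-cohort generator so the entire
pipeline is testable and demonstrable without patient data.

## The method

1. **Coding.**  Each allele becomes a binary *presence* variable (1 if
   carried) plus a *homozygosity* variable; SNPs become genotype indicators
   (`CT60*G/G`).  Variables with carrier frequency < 10% are discarded.
2. **Screening and signature.**  Each marker is screened with a univariate
   Cox proportional-hazards model (Wald p, HR, 95% CI).  The multivariate
   signature is built by backward elimination: refit, remove the variable
   with the largest Wald p while p > 0.10, repeat.  Disease stage can enter
   as a mandatory, never-removed covariate.
3. **Prognostic index and risk groups.**  Each patient's prognostic index is
   the Cox linear predictor PI = Σᵢ βᵢxᵢ; patients split into high/low risk
   at the median PI.
4. **LOOCV.**  Steps 2–3 are repeated n times leaving one patient out; the
   held-out patient is classified (high risk iff PI ≥ training median) by a
   model that never saw them.  Kaplan–Meier curves of the cross-validated
   groups and their log-rank statistic LR_d measure honest predictive value.
5. **Permutation inference.**  Significance of LR_d by shuffling survival
   data and rerunning the *entire* cross-validation, p = (1 + #{LRᵦ ≥
   LR_d})/(1 + B); added value beyond stage by permuting genotype vectors
   while (time, event, stage) stay fixed.
6. **Validation.**  The OS-built risk groups are evaluated on relapse-free
   survival (cross-endpoint validation), and discrimination at clinical
   horizons is summarized with time-dependent (cumulative/dynamic) ROC
   curves and AUC(t) at 5 and 7 years.

See `docs/methods.md` for estimators, tie handling, tie-breaking rules, and
the synthetic-cohort model.

## Worked example

Simulate a 284-subject cohort with five planted markers (hazard ratios
0.097–1.948, stage HR 2.062), build the signature and cross-validate it:

```python
from survsig import (make_scenario, simulate_genotypes, simulate_stage,
                     simulate_survival, code_alleles, filter_by_frequency,
                     backward_eliminate, loocv_risk_classify)

cfg = make_scenario("planted_five_marker", seed=0)
genotypes = simulate_genotypes(cfg)
stage = simulate_stage(cfg)
os_surv, rfs_surv = simulate_survival(code_alleles(genotypes), stage, cfg)

analysis = filter_by_frequency(code_alleles(genotypes)).drop_loci(["FOXP3"])
model = backward_eliminate(analysis, os_surv)
print(model.to_frame()[["variable", "hr", "p"]].round(3))

cv = loocv_risk_classify(analysis, os_surv)
print(cv.summary())
```

Output (seed 0):

```
    variable     hr      p
0       B*08  1.872  0.025
1       B*27  1.829  0.052
2       B*38  0.122  0.000
3       C*02  0.461  0.023
4       C*03  0.464  0.008
5       C*07  2.087  0.003
6       C*15  0.317  0.001
7    DRB1*07  0.607  0.062
8    DRB1*11  0.498  0.036
9    DRB1*13  0.454  0.013
10   DRB1*16  0.350  0.006
11   DQB1*08  3.261  0.000
12  CT60*G/G  1.745  0.023
13  JO27*T/T  1.517  0.058
141 patients (32 events) in the low risk group (median survival: not reached)
143 patients (64 events) in the high risk group (median survival: 61.0 months)
log-rank LR_d = 18.9382, asymptotic p = 1.35e-05
```

The planted protective alleles (B\*38 HR 0.12, C\*15 HR 0.32, C\*03 HR 0.46)
and risk genotype (CT60\*G/G HR 1.75) are recovered by name, alongside noise
variables that slipped through selection — exactly the behavior the
cross-validated log-rank and the permutation test are there to keep honest:
the low-risk group shows far fewer deaths than the high-risk group, with a
model that never used the classified patient.

The same workflow is scriptable from the shell:

```bash
survsig simulate --scenario planted_five_marker --n-subjects 284 --seed 0 --out cohort/
survsig run-all --genotypes cohort/genotypes.tsv --clinical cohort/clinical.tsv \
        -B 100 --seed 0 --out results/
```

`run-all` writes univariate tables, both multivariate models (with and
without mandatory stage), per-subject LOOCV assignments, KM curves per risk
group, permutation null distributions, the AUC timeline and a plain-text
summary — all as tab-separated text.

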