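"""End-to-end orchestration: coding, screening, model building, LOOCV risk
classification, permutation inference, cross-endpoint validation and AUC(t).

``run_analysis`` executes the full workflow on either a synthetic scenario or
a pair of genotype/clinical tables and writes every artifact as delimited
text.  All randomness flows from the config's master seed, so a fixed config
yields byte-identical artifacts (the run log carries wall-clock timestamps and
is the one file excluded from that guarantee).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .coding import code_alleles, filter_by_frequency
from .cohort import make_scenario, simulate_genotypes, simulate_stage, \
    simulate_survival, SCENARIOS
from .crossval import (loocv_risk_classify, cross_endpoint_validate,
                       resubstitution_classify, CvRiskResult, HIGH, LOW)
from .permutation import permutation_significance, compare_with_covariate
from .selection import univariate_screen, backward_eliminate
from .survival import SurvivalData
from .tdroc import auc_timeline

log = logging.getLogger(__name__)

STAGE = "stage"


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of (``genotype_path`` + ``clinical_path``) or ``scenario``
    must be given.  Defaults mirror the reference workflow: a 10% carrier
    filter, stay threshold 0.10, 500 permutations and AUC horizons at 5 and
    7 years (60 and 84 months).
    """

    genotype_path: str | None = None
    clinical_path: str | None = None
    scenario: str | None = None
    n_subjects: int = 284
    freq_threshold: float = 0.10
    p_remove: float = 0.10
    entry: str = "all"
    exclude_loci: tuple = ("FOXP3",)
    B: int = 500
    auc_times: tuple = (60.0, 84.0)
    seed: int = 0
    n_jobs: int = 1
    outdir: str = "survsig_run"

    def __post_init__(self):
        file_mode = self.genotype_path is not None or self.clinical_path is not None
        if file_mode == (self.scenario is not None):
            raise ValueError("give either input table paths or a scenario name")
        if file_mode and (self.genotype_path is None or self.clinical_path is None):
            raise ValueError("both genotype_path and clinical_path are required")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.freq_threshold < 1:
            raise ValueError("freq_threshold must lie in (0, 1)")
        if not 0 < self.p_remove < 1:
            raise ValueError("p_remove must lie in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exclude_loci", "auc_times"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """All artifacts of one run, writable as delimited text."""

    config: RunConfig
    n_subjects: int
    n_variables_coded: int
    n_variables_filtered: int
    univariate_os: pd.DataFrame
    univariate_rfs: pd.DataFrame
    model_os: pd.DataFrame
    model_os_stage: pd.DataFrame
    cv_os: CvRiskResult
    cv_combined: CvRiskResult
    cv_covariate: CvRiskResult
    cv_rfs_from_os: CvRiskResult
    cv_rfs_combined: CvRiskResult
    perm_survival: object
    perm_covariate: object
    auc: pd.DataFrame
    summary_lines: list = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep=sio.SEP, index=False, float_format="%.6g")
        self.univariate_os.to_csv(out / "univariate_os.tsv", **kw)
        self.univariate_rfs.to_csv(out / "univariate_rfs.tsv", **kw)
        self.model_os.to_csv(out / "model_os.tsv", **kw)
        self.model_os_stage.to_csv(out / "model_os_stage.tsv", **kw)
        for tag, cv in (("os", self.cv_os), ("combined", self.cv_combined),
                        ("covariate", self.cv_covariate),
                        ("rfs_from_os", self.cv_rfs_from_os),
                        ("rfs_combined", self.cv_rfs_combined)):
            cv.assignments().to_csv(out / f"loocv_{tag}_assignments.tsv", **kw)
            for g in (HIGH, LOW):
                if cv.km[g] is not None:
                    cv.km[g].to_frame().to_csv(
                        out / f"loocv_{tag}_km_{g}.tsv", **kw)
        np.savetxt(out / "perm_null_survival_shuffle.txt",
                   self.perm_survival.null, fmt="%.6g")
        np.savetxt(out / "perm_null_vs_covariate.txt",
                   self.perm_covariate.null, fmt="%.6g")
        self.auc.to_csv(out / "auc_timeline.tsv", **kw)
        (out / "summary.txt").write_text("\n".join(self.summary_lines) + "\n")


def _summary(report: AnalysisReport) -> list:
    c = report.config
    lines = [
        "survsig analysis summary",
        f"subjects: {report.n_subjects}",
        f"coded variables: {report.n_variables_coded} "
        f"({report.n_variables_filtered} pass the "
        f"{c.freq_threshold:.0%} carrier filter)",
        "",
        f"univariate OS markers with p < 0.05: "
        f"{int(report.univariate_os['significant'].sum())}",
        f"univariate RFS markers with p < 0.05: "
        f"{int(report.univariate_rfs['significant'].sum())}",
        "",
        f"multivariate OS model ({len(report.model_os)} variables): "
        + ", ".join(report.model_os['variable']),
        f"multivariate OS model with stage ({len(report.model_os_stage)}): "
        + ", ".join(report.model_os_stage['variable']),
    ]
    for title, cv in (
            ("LOOCV risk groups (OS, genotype model)", report.cv_os),
            ("LOOCV risk groups (OS, genotype + stage)", report.cv_combined),
            ("LOOCV risk groups (OS, stage only)", report.cv_covariate),
            ("OS model validated on RFS", report.cv_rfs_from_os),
            ("OS + stage model validated on RFS", report.cv_rfs_combined)):
        lines += ["", title, cv.summary()]
    lines += [
        "",
        f"survival-shuffle permutation p = {report.perm_survival.p_value:.4g} "
        f"(B = {report.perm_survival.B})",
        f"genotype-beyond-stage permutation p = "
        f"{report.perm_covariate.p_value:.4g} (B = {report.perm_covariate.B})",
        "",
    ]
    for _, row in report.auc.iterrows():
        if np.isfinite(row["auc"]):
            lines.append(f"AUC({row['time']:.0f} months) = {row['auc']:.3f}")
        else:
            lines.append(f"AUC({row['time']:.0f} months) skipped: {row['note']}")
    return lines


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis and write its artifacts to config.outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("survsig")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> AnalysisReport:
    if config.scenario is not None:
        log.info("simulating scenario %r (n=%d, seed=%d)",
                 config.scenario, config.n_subjects, config.seed)
        cohort = make_scenario(config.scenario, n_subjects=config.n_subjects,
                               seed=config.seed)
        genotypes = simulate_genotypes(cohort)
        stage = simulate_stage(cohort)
        coded_all = code_alleles(genotypes)
        os_surv, rfs_surv = simulate_survival(coded_all, stage, cohort)
        sio.write_genotype_table(genotypes, out / "genotypes.tsv")
        sio.write_clinical_table(genotypes.subject_ids, os_surv, rfs_surv,
                                 stage, out / "clinical.tsv")
    else:
        log.info("reading %s / %s", config.genotype_path, config.clinical_path)
        genotypes, os_surv, rfs_surv, stage = sio.read_tables(
            config.genotype_path, config.clinical_path)
        coded_all = code_alleles(genotypes)

    filtered = filter_by_frequency(coded_all, config.freq_threshold)
    analysis = filtered.drop_loci(config.exclude_loci)
    log.info("coded %d variables; %d pass the filter; %d offered to the "
             "analysis after excluding loci %s", len(coded_all.variable_names),
             len(filtered.variable_names), len(analysis.variable_names),
             list(config.exclude_loci))
    analysis.data.to_csv(out / "coded_matrix.tsv", sep=sio.SEP,
                         float_format="%.0f")

    uni_os = univariate_screen(analysis, os_surv).table
    uni_rfs = univariate_screen(analysis, rfs_surv).table

    model_os = backward_eliminate(analysis, os_surv, p_remove=config.p_remove,
                                  entry=config.entry)
    design_stage = analysis.data.copy()
    design_stage[STAGE] = stage.astype(float)
    model_os_stage = backward_eliminate(design_stage, os_surv,
                                        p_remove=config.p_remove,
                                        mandatory=[STAGE], entry=config.entry)

    log.info("running LOOCV risk classification")
    cv_os = loocv_risk_classify(analysis, os_surv, p_remove=config.p_remove)
    cv_combined = loocv_risk_classify(design_stage, os_surv, [STAGE],
                                      p_remove=config.p_remove)
    cv_covariate = loocv_risk_classify(design_stage[[STAGE]], os_surv, [STAGE],
                                       p_remove=config.p_remove,
                                       feature_selection=False)

    log.info("permutation tests (B=%d)", config.B)
    perm_survival = permutation_significance(
        analysis, os_surv, p_remove=config.p_remove, B=config.B,
        seed=config.seed, n_jobs=config.n_jobs)
    perm_covariate = compare_with_covariate(
        analysis, stage, os_surv, p_remove=config.p_remove, B=config.B,
        seed=config.seed, n_jobs=config.n_jobs)

    log.info("cross-endpoint validation (OS model on RFS)")
    cv_rfs_from_os = cross_endpoint_validate(analysis, os_surv, rfs_surv,
                                             p_remove=config.p_remove)
    cv_rfs_combined = cross_endpoint_validate(design_stage, os_surv, rfs_surv,
                                              [STAGE], p_remove=config.p_remove)

    auc = auc_timeline(cv_os.pi, os_surv, config.auc_times)

    report = AnalysisReport(
        config=config, n_subjects=len(os_surv),
        n_variables_coded=len(coded_all.variable_names),
        n_variables_filtered=len(filtered.variable_names),
        univariate_os=uni_os, univariate_rfs=uni_rfs,
        model_os=model_os.to_frame(), model_os_stage=model_os_stage.to_frame(),
        cv_os=cv_os, cv_combined=cv_combined, cv_covariate=cv_covariate,
        cv_rfs_from_os=cv_rfs_from_os, cv_rfs_combined=cv_rfs_combined,
        perm_survival=perm_survival, perm_covariate=perm_covariate, auc=auc)
    report.summary_lines = _summary(report)
    report.write(out)
    log.info("artifacts written to %s", out)
    return report
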