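"""Synthetic immunogenetic cohorts with proportional-hazards survival.

The generator emulates the statistical structure the downstream analysis
assumes: multi-allelic HLA loci and biallelic SNPs sampled under
Hardy–Weinberg equilibrium from configurable allele-frequency vectors, a
multi-allelic microsatellite, a binary disease-stage covariate, and overall /
relapse-free survival drawn from a proportional-hazards model whose log-hazard
effects are planted on *coded* marker variables.

Endpoints are coupled the way the clinical endpoints are: the latent
relapse-free time is the minimum of an independent relapse time and the death
time (both sharing the subject's linear predictor), so RFS <= OS always holds.
Censoring combines an administrative horizon with uniform dropout; one
censoring time per subject is shared by both endpoints.

Three named scenarios are provided:

``null``
    no planted effects, no stage effect — survival independent of genotype.
``planted_five_marker``
    five marker variables (two HLA-B/C protective alleles, one HLA-C and one
    DRB1 risk allele, one SNP homozygous genotype) with hazard ratios
    0.097, 0.387, 0.449, 1.948, 1.484 and carrier frequencies in [0.10, 0.35],
    plus a prognostic binary stage (HR 2.062).
``stage_only``
    prognostic stage (HR 2.062), no marker effects.

All randomness flows from one master seed through fixed per-operation streams,
so each operation is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coding import (GenotypeTable, CodedMatrix, KIND_MULTIALLELIC, KIND_SNP,
                     KIND_MICROSATELLITE, KINDS)
from .survival import SurvivalData

# per-operation substream tags under the master seed
_STREAM_GENO = 11
_STREAM_STAGE = 13
_STREAM_SURV = 17
_STREAM_CODED = 19


@dataclass(frozen=True)
class LocusSpec:
    """A typed locus: allele labels and their population frequencies."""

    name: str
    kind: str
    allele_labels: tuple
    allele_freqs: tuple

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown locus kind {self.kind!r}")
        labels = tuple(str(a) for a in self.allele_labels)
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if len(labels) != len(set(labels)):
            raise ValueError(f"{self.name}: allele labels must be unique")
        if len(labels) != freqs.size:
            raise ValueError(f"{self.name}: labels and frequencies misaligned")
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: frequencies must be nonnegative and sum to 1")
        if self.kind in (KIND_SNP, KIND_MICROSATELLITE) and len(labels) < 2:
            raise ValueError(f"{self.name}: {self.kind} needs >= 2 alleles")
        object.__setattr__(self, "allele_labels", labels)
        object.__setattr__(self, "allele_freqs", tuple(freqs))


@dataclass(frozen=True)
class EffectSpec:
    """A planted log-hazard effect on one coded marker variable."""

    variable_name: str
    log_hazard: float


@dataclass(frozen=True)
class CensoringSpec:
    """Administrative horizon plus independent uniform dropout (months).

    Either component may be None; with both None follow-up is complete.
    """

    admin_horizon: float | None = 90.0
    dropout_max: float | None = None

    def __post_init__(self):
        for v, what in ((self.admin_horizon, "admin_horizon"),
                        (self.dropout_max, "dropout_max")):
            if v is not None and not v > 0:
                raise ValueError(f"{what} must be positive, got {v}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        c = np.full(n, np.inf)
        if self.admin_horizon is not None:
            c = np.minimum(c, self.admin_horizon)
        if self.dropout_max is not None:
            c = np.minimum(c, rng.uniform(0.0, self.dropout_max, size=n))
        return c


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    n_subjects: int
    loci: tuple
    effects: tuple = ()
    baseline_rate: float = 0.006      # events per month at x = 0
    baseline_shape: float = 1.0       # Weibull shape; 1.0 = exponential
    rfs_rate_ratio: float = 1.3       # relapse hazard as multiple of death hazard
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    stage_prevalence: float = 0.5
    stage_log_hazard: float = 0.0
    round_to: float | None = None     # round times to this grain (months)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (self.baseline_rate > 0 and self.baseline_shape > 0):
            raise ValueError("baseline parameters must be strictly positive")
        if not self.rfs_rate_ratio > 0:
            raise ValueError("rfs_rate_ratio must be positive")
        if not 0.0 <= self.stage_prevalence <= 1.0:
            raise ValueError("stage_prevalence must lie in [0, 1]")
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "effects", tuple(self.effects))


    def to_dict(self) -> dict:
        """Plain nested-dict form (YAML/JSON serializable)."""
        return {
            "n_subjects": self.n_subjects,
            "loci": [{"name": l.name, "kind": l.kind,
                      "allele_labels": list(l.allele_labels),
                      "allele_freqs": [float(f) for f in l.allele_freqs]}
                     for l in self.loci],
            "effects": [{"variable_name": e.variable_name,
                         "log_hazard": float(e.log_hazard)}
                        for e in self.effects],
            "baseline_rate": self.baseline_rate,
            "baseline_shape": self.baseline_shape,
            "rfs_rate_ratio": self.rfs_rate_ratio,
            "censoring": {"admin_horizon": self.censoring.admin_horizon,
                          "dropout_max": self.censoring.dropout_max},
            "stage_prevalence": self.stage_prevalence,
            "stage_log_hazard": self.stage_log_hazard,
            "round_to": self.round_to,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        raw["loci"] = tuple(LocusSpec(**l) for l in raw.get("loci", ()))
        raw["effects"] = tuple(EffectSpec(**e) for e in raw.get("effects", ()))
        if "censoring" in raw and isinstance(raw["censoring"], dict):
            raw["censoring"] = CensoringSpec(**raw["censoring"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(config: CohortConfig) -> GenotypeTable:
    """Draw two alleles per locus per subject i.i.d. from the allele frequencies."""
    rng = _rng(config, _STREAM_GENO)
    n = config.n_subjects
    ids = [f"S{i + 1:04d}" for i in range(n)]
    cols = {}
    kinds = {}
    for locus in config.loci:
        labels = np.asarray(locus.allele_labels, dtype=object)
        freqs = np.asarray(locus.allele_freqs, dtype=float)
        freqs = freqs / freqs.sum()
        draws = rng.choice(labels.size, size=(n, 2), p=freqs)
        cols[f"{locus.name}:slot1"] = labels[draws[:, 0]]
        cols[f"{locus.name}:slot2"] = labels[draws[:, 1]]
        kinds[locus.name] = locus.kind
    calls = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))
    return GenotypeTable(calls, kinds)


def simulate_stage(config: CohortConfig) -> np.ndarray:
    """Binary high-stage indicator, Bernoulli(stage_prevalence)."""
    rng = _rng(config, _STREAM_STAGE)
    return (rng.random(config.n_subjects) < config.stage_prevalence).astype(np.int64)


def _inverse_cumulative_hazard(u: np.ndarray, rate: float, shape: float) -> np.ndarray:
    # H0(t) = (rate * t) ** shape  =>  t = H^(1/shape) / rate
    return np.power(u, 1.0 / shape) / rate


def simulate_survival(coded: CodedMatrix, stage: np.ndarray,
                      config: CohortConfig) -> tuple[SurvivalData, SurvivalData]:
    """Draw (OS, RFS) under proportional hazards from the coded matrix.

    Per-subject hazard multiplier is exp(sum effects * x + stage_log_hazard *
    stage).  The RFS latent time is min(relapse time, death time), with the
    relapse cumulative hazard scaled by ``rfs_rate_ratio``; both endpoints
    share one censoring time.
    """
    rng = _rng(config, _STREAM_SURV)
    n = len(coded)
    stage = np.asarray(stage)
    if stage.shape != (n,):
        raise ValueError("stage vector misaligned with coded matrix")
    lp = config.stage_log_hazard * stage.astype(float)
    for eff in config.effects:
        if eff.variable_name not in coded.data.columns:
            raise ValueError(
                f"effect variable {eff.variable_name!r} not present in coded matrix")
        x = coded.data[eff.variable_name].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(
                f"effect variable {eff.variable_name!r} has missing entries")
        lp = lp + eff.log_hazard * x
    mult = np.exp(lp)
    e_death = rng.exponential(size=n)
    e_relapse = rng.exponential(size=n)
    cens = config.censoring.draw(rng, n)
    t_death = _inverse_cumulative_hazard(
        e_death / mult, config.baseline_rate, config.baseline_shape)
    t_relapse = _inverse_cumulative_hazard(
        e_relapse / (mult * config.rfs_rate_ratio),
        config.baseline_rate, config.baseline_shape)
    t_rfs = np.minimum(t_relapse, t_death)

    def _observe(t_latent):
        t = np.minimum(t_latent, cens)
        e = (t_latent <= cens).astype(np.int64)
        if config.round_to is not None:
            t = np.maximum(np.round(t / config.round_to) * config.round_to,
                           config.round_to)
        return SurvivalData(t, e)

    return _observe(t_death), _observe(t_rfs)


def simulate_coded_null(n_subjects: int, n_markers: int,
                        carrier_freq: float = 0.30, seed: int = 0) -> CodedMatrix:
    """Directly generate a coded matrix of independent null Bernoulli markers.

    Convenience for calibration studies on the downstream machinery (screening,
    elimination, permutation) without the genotype-coding round trip.
    """
    rng = np.random.default_rng([seed, _STREAM_CODED])
    data = (rng.random((n_subjects, n_markers)) < carrier_freq).astype(float)
    ids = [f"S{i + 1:04d}" for i in range(n_subjects)]
    names = [f"M{j + 1:02d}" for j in range(n_markers)]
    df = pd.DataFrame(data, index=pd.Index(ids, name="subject_id"), columns=names)
    return CodedMatrix(df, {c: c for c in names})


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

def _hla_loci() -> list[LocusSpec]:
    """Five HLA loci with realistic low-resolution allele spectra.

    Frequencies are round, plausible European-population values chosen so that
    roughly ten presence variables per locus clear a 10% carrier filter and the
    planted alleles (B*38, C*15, C*03, DRB1*15) have carrier frequencies of
    about 0.15, 0.15, 0.25 and 0.30 under Hardy–Weinberg.
    """
    return [
        LocusSpec("A", KIND_MULTIALLELIC,
                  ("01", "02", "03", "11", "23", "24", "26", "29", "30",
                   "31", "32", "68"),
                  (0.12, 0.15, 0.11, 0.09, 0.06, 0.10, 0.08, 0.07, 0.05,
                   0.04, 0.06, 0.07)),
        LocusSpec("B", KIND_MULTIALLELIC,
                  ("07", "08", "13", "14", "15", "18", "27", "35", "37",
                   "38", "44", "49", "51", "52", "57"),
                  (0.08, 0.07, 0.04, 0.03, 0.07, 0.10, 0.06, 0.11, 0.02,
                   0.08, 0.12, 0.06, 0.09, 0.01, 0.06)),
        LocusSpec("C", KIND_MULTIALLELIC,
                  ("01", "02", "03", "04", "05", "06", "07", "08", "12",
                   "14", "15", "16"),
                  (0.08, 0.07, 0.135, 0.12, 0.06, 0.11, 0.14, 0.06, 0.10,
                   0.04, 0.08, 0.005)),
        LocusSpec("DRB1", KIND_MULTIALLELIC,
                  ("01", "03", "04", "07", "08", "09", "10", "11", "13",
                   "14", "15", "16"),
                  (0.08, 0.11, 0.10, 0.12, 0.07, 0.01, 0.007, 0.13, 0.09,
                   0.06, 0.163, 0.06)),
        LocusSpec("DQB1", KIND_MULTIALLELIC,
                  ("02", "03", "04", "05", "06", "07", "08", "09", "10", "11"),
                  (0.13, 0.18, 0.09, 0.14, 0.16, 0.08, 0.07, 0.06, 0.05, 0.04)),
    ]


def _snp_loci() -> list[LocusSpec]:
    """Six biallelic SNPs (CTLA4 region panel) with plausible allele frequencies."""
    return [
        LocusSpec("CT60", KIND_SNP, ("A", "G"), (0.45, 0.55)),
        LocusSpec("AG49", KIND_SNP, ("A", "G"), (0.60, 0.40)),
        LocusSpec("CT318", KIND_SNP, ("C", "T"), (0.85, 0.15)),
        LocusSpec("JO27", KIND_SNP, ("C", "T"), (0.30, 0.70)),
        LocusSpec("JO30", KIND_SNP, ("A", "G"), (0.65, 0.35)),
        LocusSpec("JO31", KIND_SNP, ("G", "T"), (0.75, 0.25)),
    ]


def _microsatellite_locus() -> LocusSpec:
    """FOXP3-style (TC)n microsatellite; alleles are fragment lengths."""
    return LocusSpec("FOXP3", KIND_MICROSATELLITE,
                     ("330", "332", "334", "336", "338", "340"),
                     (0.10, 0.22, 0.30, 0.20, 0.12, 0.06))


#: the five planted markers and their hazard ratios
PLANTED_MARKER_HRS = {
    "B*38": 0.097,
    "C*15": 0.387,
    "C*03": 0.449,
    "DRB1*15": 1.948,
    "CT60*G/G": 1.484,
}

STAGE_HR = 2.062

SCENARIOS = ("null", "planted_five_marker", "stage_only")


def make_scenario(name: str, n_subjects: int = 284, seed: int = 0) -> CohortConfig:
    """Return a fully populated cohort configuration for a named scenario."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    loci = tuple(_hla_loci() + _snp_loci() + [_microsatellite_locus()])
    base = CohortConfig(
        n_subjects=n_subjects,
        loci=loci,
        effects=(),
        baseline_rate=0.0072,
        baseline_shape=1.0,
        rfs_rate_ratio=1.3,
        censoring=CensoringSpec(admin_horizon=90.0, dropout_max=120.0),
        stage_prevalence=0.5,
        stage_log_hazard=0.0,
        round_to=0.1,
        seed=seed,
    )
    if name == "null":
        return base
    if name == "stage_only":
        return replace(base, stage_log_hazard=math.log(STAGE_HR))
    effects = tuple(EffectSpec(v, math.log(hr))
                    for v, hr in PLANTED_MARKER_HRS.items())
    return replace(base, effects=effects, stage_log_hazard=math.log(STAGE_HR))
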