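"""Delimited-text I/O for genotype and clinical tables.

Dialect: tab-separated, header required, ``NA`` for missing.  The genotype
table has one row per subject with columns ``subject_id`` then
``<locus>:slot1`` / ``<locus>:slot2`` per locus.  The clinical table has
columns ``subject_id, os_months, os_event, rfs_months, rfs_event, stage``
with times in months, events in {0, 1} and stage in {0, 1}
(0 = lower stage, 1 = high stage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .coding import GenotypeTable, MISSING, KIND_SNP, KIND_MICROSATELLITE, \
    KIND_MULTIALLELIC
from .survival import SurvivalData

log = logging.getLogger(__name__)

SEP = "\t"

CLINICAL_COLUMNS = ("subject_id", "os_months", "os_event",
                    "rfs_months", "rfs_event", "stage")

#: loci treated as SNPs / microsatellites when no explicit kinds are given
DEFAULT_SNP_LOCI = ("CT60", "AG49", "CT318", "JO27", "JO30", "JO31")
DEFAULT_MICROSATELLITE_LOCI = ("FOXP3",)


def write_genotype_table(genotypes: GenotypeTable, path) -> None:
    out = genotypes.calls.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep=SEP, na_rep=MISSING)


def read_genotype_table(path, kinds: dict | None = None) -> GenotypeTable:
    """Read a genotype table; locus kinds default by locus name.

    Loci named in ``DEFAULT_SNP_LOCI`` / ``DEFAULT_MICROSATELLITE_LOCI`` get
    those kinds; everything else is treated as a multi-allelic locus.  Pass
    ``kinds`` to override.
    """
    df = pd.read_csv(path, sep=SEP, dtype=str, na_values=[MISSING],
                     keep_default_na=False)
    if "subject_id" not in df.columns:
        raise ValueError("genotype table lacks a subject_id column")
    df = df.set_index("subject_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids in genotype table: {dups}")
    loci = []
    for col in df.columns:
        if ":" not in col:
            raise ValueError(f"unparseable genotype column {col!r}; "
                             "expected '<locus>:slot1' / '<locus>:slot2'")
        locus = col.rsplit(":", 1)[0]
        if locus not in loci:
            loci.append(locus)
    if kinds is None:
        kinds = {}
        for locus in loci:
            if locus in DEFAULT_SNP_LOCI:
                kinds[locus] = KIND_SNP
            elif locus in DEFAULT_MICROSATELLITE_LOCI:
                kinds[locus] = KIND_MICROSATELLITE
            else:
                kinds[locus] = KIND_MULTIALLELIC
    return GenotypeTable(df, {locus: kinds[locus] for locus in loci})


def write_clinical_table(subject_ids, os_surv: SurvivalData,
                         rfs_surv: SurvivalData, stage, path) -> None:
    pd.DataFrame({
        "subject_id": list(subject_ids),
        "os_months": os_surv.time, "os_event": os_surv.event,
        "rfs_months": rfs_surv.time, "rfs_event": rfs_surv.event,
        "stage": np.asarray(stage, dtype=int),
    }).to_csv(path, sep=SEP, index=False, na_rep=MISSING)


def read_clinical_table(path):
    """Read and validate a clinical table.

    Returns (subject_ids, os SurvivalData, rfs SurvivalData, stage array).
    """
    df = pd.read_csv(path, sep=SEP, na_values=[MISSING], keep_default_na=False)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table lacks columns {missing_cols}")
    ids = df["subject_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids in clinical table: {dups}")
    for col in ("os_event", "rfs_event"):
        vals = pd.to_numeric(df[col], errors="raise")
        bad = ~vals.isin([0, 1])
        if bad.any():
            raise ValueError(
                f"{col} outside {{0, 1}} for subjects "
                f"{df.loc[bad, 'subject_id'].tolist()}")
    for col in ("os_months", "rfs_months"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValueError(f"{col} must be finite and nonnegative")
    stage = pd.to_numeric(df["stage"], errors="raise")
    if not stage.isin([0, 1]).all():
        raise ValueError("stage must be binary (0 = lower stage, 1 = high)")
    over = df["rfs_months"].to_numpy(float) > df["os_months"].to_numpy(float)
    if over.any():
        log.warning("RFS time exceeds OS time for subjects %s",
                    df.loc[over, "subject_id"].tolist())
    os_surv = SurvivalData(df["os_months"].to_numpy(float),
                           df["os_event"].to_numpy(int))
    rfs_surv = SurvivalData(df["rfs_months"].to_numpy(float),
                            df["rfs_event"].to_numpy(int))
    return ids, os_surv, rfs_surv, stage.to_numpy(int)


def read_tables(genotype_path, clinical_path, kinds: dict | None = None):
    """Read, validate and id-join the genotype and clinical tables.

    Join order follows the clinical table.  Subjects present in one table but
    not the other raise an error naming the orphans.
    """
    genotypes = read_genotype_table(genotype_path, kinds=kinds)
    ids, os_surv, rfs_surv, stage = read_clinical_table(clinical_path)
    geno_ids = set(map(str, genotypes.subject_ids))
    clin_ids = set(ids)
    orphans_clin = sorted(clin_ids - geno_ids)
    orphans_geno = sorted(geno_ids - clin_ids)
    if orphans_clin or orphans_geno:
        raise ValueError(
            "subject-id mismatch between tables: "
            f"clinical-only {orphans_clin}, genotype-only {orphans_geno}")
    calls = genotypes.calls.loc[[str(i) for i in ids]]
    return (GenotypeTable(calls, genotypes.kinds), os_surv, rfs_surv, stage)
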