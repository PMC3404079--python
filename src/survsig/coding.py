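"""Binary coding of genotype calls into a survival-analysis design matrix.

Coding rules
------------
* Multi-allelic loci (HLA, microsatellites): for every allele observed at the
  locus, a *presence* column (1 if the subject carries >= 1 copy) and a
  *homozygosity* column (1 iff both calls equal that allele).  Microsatellite
  fragment lengths are treated verbatim as allele labels, no binning.
* SNP loci: genotype-level indicator columns, e.g. ``CT60*G/G`` is 1 iff both
  calls are G.  Genotype labels are order-normalized (``A/G`` == ``G/A``).
* Missing calls: with both calls missing every column of the locus is missing
  for that subject.  With one call missing, presence is coded from the observed
  call (1 if it matches the allele, else 0) while homozygosity of the observed
  allele is missing; homozygosity of any other allele is a definite 0.  SNP
  genotypes with any missing call are missing.

Column names are ``locus*allele`` / ``locus*allele_hom`` / ``locus*g1/g2``.
Carrier frequency of a column is the mean over subjects with non-missing
entries; the frequency filter keeps columns at or above the threshold
(default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "NA"

KIND_MULTIALLELIC = "multiallelic"
KIND_SNP = "snp"
KIND_MICROSATELLITE = "microsatellite"
KINDS = (KIND_MULTIALLELIC, KIND_SNP, KIND_MICROSATELLITE)


@dataclass
class GenotypeTable:
    """Raw per-subject genotype calls: two allele slots per locus.

    ``calls`` is indexed by subject id with columns ``"<locus>:slot1"`` and
    ``"<locus>:slot2"`` holding allele labels (NaN = missing call).
    ``kinds`` maps each locus to one of {multiallelic, snp, microsatellite}.
    """

    calls: pd.DataFrame
    kinds: dict

    def __post_init__(self):
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dups}")
        for locus in self.loci:
            for slot in (1, 2):
                if f"{locus}:slot{slot}" not in self.calls.columns:
                    raise ValueError(f"locus {locus!r} lacks slot{slot} column")
            if self.kinds[locus] not in KINDS:
                raise ValueError(f"unknown locus kind {self.kinds[locus]!r}")

    @property
    def loci(self) -> list:
        return list(self.kinds)

    @property
    def subject_ids(self) -> list:
        return list(self.calls.index)

    def __len__(self) -> int:
        return len(self.calls)

    def locus_calls(self, locus: str) -> pd.DataFrame:
        return self.calls[[f"{locus}:slot1", f"{locus}:slot2"]]


@dataclass
class CodedMatrix:
    """Subjects x binary design variables, with provenance and carrier stats.

    Entries are float 0.0/1.0 with NaN for missing.  ``locus_of`` maps each
    column back to its source locus; ``dropped`` records columns removed by the
    frequency filter.
    """

    data: pd.DataFrame
    locus_of: dict
    dropped: list = field(default_factory=list)

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def variable_names(self) -> list:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def carrier_frequency(self) -> pd.Series:
        """Per-column carrier fraction over subjects with non-missing entries."""
        return self.data.mean(axis=0, skipna=True)

    def drop_loci(self, loci) -> "CodedMatrix":
        """Remove every column that originates from the given loci."""
        loci = set(loci)
        keep = [c for c in self.data.columns if self.locus_of[c] not in loci]
        return CodedMatrix(self.data[keep],
                           {c: self.locus_of[c] for c in keep},
                           list(self.dropped))


def _sorted_alleles(values) -> list:
    """Deterministic allele ordering: numeric labels numerically, else lexical."""
    vals = sorted(set(values))
    try:
        return sorted(vals, key=lambda v: (float(v), str(v)))
    except (TypeError, ValueError):
        return vals


def code_alleles(genotypes: GenotypeTable) -> CodedMatrix:
    """Code a genotype table into the (unfiltered) binary design matrix."""
    cols = {}
    locus_of = {}
    n = len(genotypes)
    for locus in genotypes.loci:
        kind = genotypes.kinds[locus]
        lc = genotypes.locus_calls(locus)
        a1 = lc.iloc[:, 0].to_numpy(dtype=object)
        a2 = lc.iloc[:, 1].to_numpy(dtype=object)
        miss1 = pd.isna(a1)
        miss2 = pd.isna(a2)
        observed = [str(v) for v in np.concatenate([a1[~miss1], a2[~miss2]])]
        if kind == KIND_SNP:
            both = ~(miss1 | miss2)
            geno = np.full(n, None, dtype=object)
            for i in np.nonzero(both)[0]:
                pair = sorted([str(a1[i]), str(a2[i])])
                geno[i] = f"{pair[0]}/{pair[1]}"
            for g in _sorted_alleles([v for v in geno if v is not None]):
                name = f"{locus}*{g}"
                col = np.where(geno == g, 1.0, 0.0)
                col[~both] = np.nan
                cols[name] = col
                locus_of[name] = locus
        else:
            for allele in _sorted_alleles(observed):
                pres = np.empty(n)
                hom = np.empty(n)
                for i in range(n):
                    if miss1[i] and miss2[i]:
                        pres[i] = np.nan
                        hom[i] = np.nan
                        continue
                    if miss1[i] or miss2[i]:
                        obs = str(a2[i]) if miss1[i] else str(a1[i])
                        pres[i] = 1.0 if obs == allele else 0.0
                        # one matching call: could be hetero- or homozygous
                        hom[i] = np.nan if pres[i] == 1.0 else 0.0
                        continue
                    c1, c2 = str(a1[i]), str(a2[i])
                    pres[i] = 1.0 if (c1 == allele or c2 == allele) else 0.0
                    hom[i] = 1.0 if (c1 == allele and c2 == allele) else 0.0
                pname = f"{locus}*{allele}"
                cols[pname] = pres
                cols[f"{pname}_hom"] = hom
                locus_of[pname] = locus
                locus_of[f"{pname}_hom"] = locus
    data = pd.DataFrame(cols, index=genotypes.calls.index)
    return CodedMatrix(data, locus_of)


def filter_by_frequency(coded: CodedMatrix, threshold: float = 0.10) -> CodedMatrix:
    """Retain columns whose carrier frequency is at least ``threshold``.

    The discarded column names are recorded on the returned matrix.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    freq = coded.carrier_frequency()
    keep = [c for c in coded.data.columns if freq[c] >= threshold]
    dropped = [c for c in coded.data.columns if c not in set(keep)]
    return CodedMatrix(coded.data[keep],
                       {c: coded.locus_of[c] for c in keep},
                       dropped)
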