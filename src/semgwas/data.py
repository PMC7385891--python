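"""Shared dataset containers: aligned genotype and phenotype blocks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
ORDINAL = "ordinal"

MISSING = np.nan


@dataclass
class VariableMeta:
    """Per-variable metadata: measurement kind, categories, applied transform."""

    name: str
    kind: str = CONTINUOUS
    categories: list = field(default_factory=list)
    merge_map: dict = field(default_factory=dict)
    transform: str = "none"     # none | log | zscore | log+zscore

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, ORDINAL):
            raise ValueError(f"unknown variable kind {self.kind!r}")


@dataclass
class DatasetBundle:
    """Genotypes and phenotypes aligned on sample id.

    ``genotypes``: samples x SNPs, codes {0,1,2} with NaN for missing calls.
    ``snp_info``: per-SNP chromosome / position / alleles, indexed by SNP id.
    ``phenotypes``: samples x traits (continuous z-scored, ordinal integer codes).
    """

    genotypes: pd.DataFrame
    snp_info: pd.DataFrame
    phenotypes: pd.DataFrame
    trait_meta: dict[str, VariableMeta] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("genotype and phenotype rows must align on sample id")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.genotypes.index]

    @property
    def snp_names(self) -> list[str]:
        return [str(c) for c in self.genotypes.columns]

    @property
    def trait_names(self) -> list[str]:
        return [str(c) for c in self.phenotypes.columns]

    def trait_kinds(self) -> dict[str, str]:
        return {t: self.trait_meta[t].kind if t in self.trait_meta else CONTINUOUS
                for t in self.trait_names}

    def subset_samples(self, idx) -> "DatasetBundle":
        return DatasetBundle(self.genotypes.iloc[idx].copy(),
                             self.snp_info.copy(),
                             self.phenotypes.iloc[idx].copy(),
                             dict(self.trait_meta))
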