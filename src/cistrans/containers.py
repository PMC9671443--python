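"""Shared tabular containers used across the pipeline.

The central object is :class:`AlleleCountMatrix`: an integer gene x sample
count table plus per-sample metadata.  Hybrid libraries contribute *two*
columns (one per parental allele) that share a single physical library; the
``library_id`` and ``library_size`` metadata fields record that pairing so the
statistical stage can use the physical library depth as its offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("sim_parent", "sec_parent", "hybrid")
ALLELES = ("sim", "sec", "total")
CONDITIONS = ("control", "challenged")
TISSUES = ("hemocyte", "fat_body")

#: upper-case tokens used in CSV column names, mirroring the convention of
#: published allele-specific count tables (genotype upper case, allele lower).
_GENOTYPE_TOKEN = {"sim_parent": "SIMULANS", "sec_parent": "SECHELLIA", "hybrid": "HYBRID"}
_TOKEN_GENOTYPE = {v: k for k, v in _GENOTYPE_TOKEN.items()}

META_COLUMNS = [
    "sample_id",
    "genotype",
    "allele",
    "condition",
    "tissue",
    "replicate",
    "library_id",
    "library_size",
]


def sample_name(genotype: str, allele: str, condition: str, replicate: int) -> str:
    """Build the canonical ``<GENOTYPE>_<allele>_<condition>_<rep>`` column name."""
    return f"{_GENOTYPE_TOKEN[genotype]}_{allele}_{condition}_{replicate}"


def parse_sample_name(name: str) -> dict | None:
    """Parse a column name of the canonical convention; ``None`` if unparseable."""
    parts = name.split("_")
    if len(parts) < 4:
        return None
    token, allele, condition, rep = parts[0], parts[1], "_".join(parts[2:-1]), parts[-1]
    if token.upper() not in _TOKEN_GENOTYPE or allele not in ALLELES:
        return None
    if condition not in CONDITIONS:
        return None
    try:
        replicate = int(rep)
    except ValueError:
        return None
    return {
        "sample_id": name,
        "genotype": _TOKEN_GENOTYPE[token.upper()],
        "allele": allele,
        "condition": condition,
        "replicate": replicate,
    }


@dataclass
class AlleleCountMatrix:
    """Gene x sample integer counts with aligned per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample.
    meta
        DataFrame with one row per sample (``sample_id`` column matching the
        count columns) carrying genotype/allele/condition/tissue/replicate,
        ``library_id`` (physical library; shared by the two allele columns of
        a hybrid library) and ``library_size`` (total assigned reads of the
        physical library).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        if list(self.counts.columns) != list(self.meta["sample_id"]):
            raise ValueError("count columns and metadata sample_id must align")
        bad = set(self.meta["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        if (self.meta["library_size"] <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "AlleleCountMatrix":
        return AlleleCountMatrix(self.counts.loc[genes], self.meta.copy())

    def subset_samples(self, mask) -> "AlleleCountMatrix":
        mask = np.asarray(mask)
        return AlleleCountMatrix(
            self.counts.loc[:, self.counts.columns[mask]], self.meta.loc[mask].copy()
        )

    def cpm(self) -> pd.DataFrame:
        """Counts per million of the physical library size."""
        libsize = self.meta.set_index("sample_id")["library_size"]
        return self.counts / libsize.reindex(self.counts.columns).to_numpy() * 1e6

    def to_csv(self, counts_path, meta_path=None, header_comment: str | None = None) -> None:
        counts_path = Path(counts_path)
        with open(counts_path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.counts.rename_axis("gene_id").to_csv(fh)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                if header_comment:
                    fh.write(f"# {header_comment}\n")
                self.meta.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, counts_path, meta_path) -> "AlleleCountMatrix":
        counts = pd.read_csv(counts_path, index_col=0, comment="#")
        meta = pd.read_csv(meta_path, comment="#")
        return cls(counts, meta)
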