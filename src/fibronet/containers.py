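"""Core data containers shared by every analysis stage.

All containers are thin, validated wrappers around pandas/numpy objects.
Conventions: expression matrices are genes x samples; genotype matrices are
SNPs x samples with 1-based inclusive genomic coordinates; module sets map
gene ids to labels with ``"unassigned"`` reserved for the background pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued expression table with a unit tag.

    Parameters
    ----------
    values : pd.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
    unit : str
        One of ``"fpkm"``, ``"log2"``, ``"residual"``.
    """

    values: pd.DataFrame
    unit: str = "log2"

    _UNITS = ("fpkm", "log2", "residual")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {self._UNITS}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("missing values are not accepted; impute or filter upstream")
        if self.unit in ("log2", "residual") and not np.isfinite(arr).all():
            raise ValueError(f"unit={self.unit} requires all values finite")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: List[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[genes], unit=self.unit)


@dataclass
class GenotypeMatrix:
    """SNP x sample dosage table with genomic coordinates.

    ``dosage`` rows are indexed by SNP id, columns by sample id. Values are
    {0,1} for inbred panels (two founder alleles) or {0,1,2} for diploids;
    downstream regression treats both as numeric dosage. ``block_id`` groups
    SNPs into LD blocks (strain-distribution-pattern blocks in an RI panel).
    """

    dosage: pd.DataFrame
    chrom: pd.Series
    pos: pd.Series
    block_id: Optional[pd.Series] = None
    ploidy: int = 1

    def __post_init__(self) -> None:
        if not self.dosage.index.is_unique:
            raise ValueError("snp ids must be unique")
        if not self.dosage.columns.is_unique:
            raise ValueError("sample ids must be unique")
        for name, s in (("chrom", self.chrom), ("pos", self.pos)):
            if not s.index.equals(self.dosage.index):
                raise ValueError(f"{name} index must match snp ids")
        if self.block_id is not None and not self.block_id.index.equals(self.dosage.index):
            raise ValueError("block_id index must match snp ids")
        allowed = {0, 1} if self.ploidy == 1 else {0, 1, 2}
        vals = set(np.unique(self.dosage.to_numpy()).tolist())
        if not vals <= allowed:
            raise ValueError(f"dosage values {vals - allowed} outside the declared code set {allowed}")
        # positions nondecreasing within each chromosome
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for _, grp in df.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be nondecreasing within a chromosome")

    @property
    def snp_ids(self) -> List[str]:
        return list(self.dosage.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.dosage.columns)

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[0]


@dataclass
class PhenotypeTable:
    """Sample-level quantitative traits plus covariates.

    ``data`` is samples x columns; ``trait_cols`` and ``covariate_cols`` name
    the two roles (e.g. fibrosis traits vs a blood-pressure covariate).
    """

    data: pd.DataFrame
    trait_cols: List[str] = field(default_factory=list)
    covariate_cols: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")
        for c in list(self.trait_cols) + list(self.covariate_cols):
            if c not in self.data.columns:
                raise ValueError(f"column {c!r} not in phenotype table")
        for c in self.trait_cols:
            if self.data[c].isna().all():
                raise ValueError(f"trait column {c!r} entirely missing")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)


@dataclass
class ModuleSet:
    """Partition of genes into labeled co-expression modules.

    ``assignments`` maps every gene id to a module label; the label
    ``"unassigned"`` holds the background pool. Proper modules are renamed
    M1..Mk by decreasing size once detection finishes.
    """

    assignments: Dict[str, str]
    module_order: List[str] = field(default_factory=list)
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [l for l in set(self.assignments.values()) if l != UNASSIGNED]
        if not self.module_order:
            sizes = {l: sum(1 for v in self.assignments.values() if v == l) for l in labels}
            self.module_order = sorted(labels, key=lambda l: (-sizes[l], l))
        min_size = self.params.get("min_size")
        if min_size:
            for l in self.module_order:
                n = sum(1 for v in self.assignments.values() if v == l)
                if n < int(min_size):
                    raise ValueError(f"module {l} has size {n} < min_size {min_size}")

    def members(self, label: str) -> List[str]:
        return [g for g, l in self.assignments.items() if l == label]

    def sizes(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for l in self.module_order:
            out[l] = len(self.members(l))
        return out

    def as_gene_sets(self) -> Dict[str, List[str]]:
        """Modules as GMT-style gene sets, excluding the unassigned pool."""
        return {l: self.members(l) for l in self.module_order}


@dataclass
class Eigengene:
    """First principal component of a module's expression submatrix."""

    label: str
    loadings: pd.Series  # one per sample, unit norm

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.loadings.to_numpy()))
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError(f"eigengene loadings must be unit norm, got {norm}")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted by the synthetic-data generators."""

    module_assignments: Dict[str, str]
    hotspot_snp: Optional[str] = None
    hotspot_block: Optional[str] = None
    hotspot_effect: float = 0.0
    module_corr_cases: float = 0.0
    module_corr_controls: float = 0.0
    trait_loading: float = 0.0
    confounder_loading: float = 0.0
    seed: int = 0

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)

    def module_genes(self, label: str) -> List[str]:
        return [g for g, l in self.module_assignments.items() if l == label]


@dataclass
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def span(self) -> int:
        """Width as end - start (the printed ``start..end`` convention)."""
        return self.end - self.start

    def center(self) -> int:
        return int(self.start + (self.end - self.start) / 2)
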