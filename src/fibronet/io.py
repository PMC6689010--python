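"""Readers and writers for the pipeline's plain-text formats.

Expression TSV: first column gene id, header row of sample ids.
Genotype TSV: columns snp_id, chrom, pos, [block_id,] then sample dosages.
Phenotype TSV: first column sample id, then trait/covariate columns.
Gene sets: GMT (set name, description, members, tab-separated).
Intervals: BED written half-open 0-based from the internal 1-based
inclusive convention (start-1, end).
Truth and reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenomicInterval,
    GenotypeMatrix,
    PhenotypeTable,
    SyntheticTruth,
)

PathLike = Union[str, Path]
_FLOAT_FMT = "%.17g"  # full round-trip precision


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression(path: PathLike, unit: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).to_numpy().argmax()) + 2
        raise ValueError(f"missing value in expression table near line {bad}")
    return ExpressionMatrix(df, unit=unit)


def write_genotypes(geno: GenotypeMatrix, path: PathLike) -> None:
    meta = pd.DataFrame({"chrom": geno.chrom, "pos": geno.pos})
    if geno.block_id is not None:
        meta["block_id"] = geno.block_id
    out = pd.concat([meta, geno.dosage], axis=1)
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t")


def read_genotypes(path: PathLike, ploidy: int = 1) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"genotype table missing column {col!r}")
    block = df["block_id"] if "block_id" in df.columns else None
    meta_cols = ["chrom", "pos"] + (["block_id"] if block is not None else [])
    dosage = df.drop(columns=meta_cols)
    return GenotypeMatrix(
        dosage=dosage.astype(int),
        chrom=df["chrom"].astype(str),
        pos=df["pos"].astype(int),
        block_id=None if block is None else block.astype(str),
        ploidy=ploidy,
    )


def write_phenotypes(pheno: PhenotypeTable, path: PathLike) -> None:
    df = pheno.data.copy()
    df.index.name = "sample_id"
    header = {
        "traits": list(pheno.trait_cols),
        "covariates": list(pheno.covariate_cols),
    }
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)


def read_phenotypes(path: PathLike) -> PhenotypeTable:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# "):
            header = json.loads(first[2:])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            header = {"traits": [], "covariates": []}
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    traits = header.get("traits") or [c for c in df.columns]
    covs = header.get("covariates") or []
    return PhenotypeTable(df, trait_cols=traits, covariate_cols=covs)


def write_gmt(gene_sets: Dict[str, Sequence[str]], path: PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: PathLike) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need name, description, members")
            sets[parts[0]] = parts[2:]
    return sets


def write_module_assignments(assignments: Dict[str, str], path: PathLike) -> None:
    pd.Series(assignments, name="module").rename_axis("gene_id").to_csv(path, sep="\t")


def write_bed(intervals: Sequence[GenomicInterval], path: PathLike, names: Sequence[str] = ()) -> None:
    """BED output: half-open 0-based, converted from 1-based inclusive."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if i < len(names) else f"interval{i+1}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def read_bed(path: PathLike) -> List[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}")
            out.append(GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


def write_truth(truth: SyntheticTruth, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: PathLike) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth(**json.load(fh))


def write_ortholog_map(pairs: Sequence[Sequence[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_ortholog_map(path: PathLike) -> List[tuple]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError("ortholog map must have exactly two columns")
    return [tuple(r) for r in df.itertuples(index=False)]
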