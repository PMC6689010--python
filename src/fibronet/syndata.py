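"""Synthetic data generators with planted ground truth.

The generators emulate the statistical structure the downstream analyses
assume:

* a recombinant-inbred-like strain panel with binary strain-distribution-
  pattern genotypes grouped into LD blocks, and one planted trans-acting
  hotspot driving a gene module;
* case/control cohorts in which the planted module is strongly co-expressed
  in cases and decorrelated in controls (equicorrelated single-factor
  construction);
* fibrosis-like quantitative traits loaded on the module eigengene with a
  blood-pressure-like confounder.

Expression is generated at the already-normalized matrix level; no reads,
isoforms, or library-size effects are simulated. Every generator is
deterministic given its seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    SyntheticTruth,
    UNASSIGNED,
)

# Synthetic genome layout: one chromosome per 100 blocks, blocks tiled every
# 50 kb, SNPs inside a block spaced 100 bp, 1-based positions.
BLOCKS_PER_CHROM = 100
BLOCK_SPACING = 50_000
SNP_SPACING = 100

# Gene loadings drawn in [0.4, 0.9]: co-expressed but not collinear.
LOADING_LOW, LOADING_HIGH = 0.4, 0.9


def _rng(seed: int, tag: int) -> np.random.Generator:
    """Generator-specific stream: distinct tags decouple the generators so
    that equal seeds never replay the same draws across generators."""
    return np.random.default_rng([tag, seed])


def _check_positive(**kwargs: int) -> None:
    for name, val in kwargs.items():
        if val < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")


def generate_genotypes(
    n_strains: int, n_blocks: int, snps_per_block: int, seed: int
) -> GenotypeMatrix:
    """Binary strain-distribution-pattern genotypes grouped into LD blocks.

    Every SNP in a block shares one strain distribution pattern (the blocks
    mimic groups of adjacent SNPs with identical patterns across an RI
    panel). Each block's pattern has minor-allele frequency in [0.2, 0.5].
    """
    _check_positive(n_strains=n_strains, n_blocks=n_blocks, snps_per_block=snps_per_block)
    rng = _rng(seed, 1)
    strains = [f"S{i+1:03d}" for i in range(n_strains)]

    lo = int(np.ceil(0.2 * n_strains))
    hi = int(np.floor(0.5 * n_strains))
    lo = max(lo, 1)
    hi = max(hi, lo)

    rows, snp_ids, chroms, positions, blocks = [], [], [], [], []
    for b in range(n_blocks):
        m = int(rng.integers(lo, hi + 1))
        pattern = np.zeros(n_strains, dtype=int)
        pattern[rng.choice(n_strains, size=m, replace=False)] = 1
        chrom = f"chr{b // BLOCKS_PER_CHROM + 1}"
        block_start = (b % BLOCKS_PER_CHROM) * BLOCK_SPACING + 1
        for s in range(snps_per_block):
            rows.append(pattern.copy())
            snp_ids.append(f"snp_b{b+1}_{s+1}")
            chroms.append(chrom)
            positions.append(block_start + s * SNP_SPACING)
            blocks.append(f"block{b+1}")

    idx = pd.Index(snp_ids, name="snp_id")
    return GenotypeMatrix(
        dosage=pd.DataFrame(np.asarray(rows), index=idx, columns=strains),
        chrom=pd.Series(chroms, index=idx),
        pos=pd.Series(positions, index=idx),
        block_id=pd.Series(blocks, index=idx),
        ploidy=1,
    )


def generate_panel_expression(
    genotypes: GenotypeMatrix,
    n_genes: int,
    module_sizes: Sequence[int],
    hotspot_spec: Tuple[str, float],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Panel expression with module factors and a planted hotspot.

    Each module m has a latent factor f_m ~ N(0,1) per strain. The first
    module's factor gains ``effect x dosage`` of the hotspot block's
    pattern. Gene g in module m is lambda_g * f_m + eps with lambda_g drawn
    uniformly in [0.4, 0.9] and eps ~ N(0, noise_sd). Genes outside modules
    are independent N(0,1) noise.
    """
    if sum(module_sizes) > n_genes:
        raise ValueError(
            f"sum of module sizes {sum(module_sizes)} exceeds n_genes {n_genes}"
        )
    hotspot_block, effect = hotspot_spec
    if genotypes.block_id is None or hotspot_block not in set(genotypes.block_id):
        raise ValueError(f"hotspot block {hotspot_block!r} not in genotypes")

    rng = _rng(seed, 2)
    samples = genotypes.sample_ids
    n = len(samples)

    block_snps = genotypes.block_id[genotypes.block_id == hotspot_block].index
    hotspot_snp = block_snps[0]
    dose = genotypes.dosage.loc[hotspot_snp].to_numpy(dtype=float)

    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]
    values = np.empty((n_genes, n))
    assignments: Dict[str, str] = {g: UNASSIGNED for g in gene_ids}

    row = 0
    for mi, size in enumerate(module_sizes):
        f = rng.standard_normal(n)
        if mi == 0:
            f = f + effect * dose
        lam = rng.uniform(LOADING_LOW, LOADING_HIGH, size=size)
        eps = rng.normal(0.0, noise_sd, size=(size, n))
        values[row : row + size] = lam[:, None] * f[None, :] + eps
        for g in gene_ids[row : row + size]:
            assignments[g] = f"M{mi+1}"
        row += size
    n_bg = n_genes - row
    if n_bg:
        values[row:] = rng.standard_normal((n_bg, n))

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        unit="log2",
    )
    truth = SyntheticTruth(
        module_assignments=assignments,
        hotspot_snp=hotspot_snp,
        hotspot_block=hotspot_block,
        hotspot_effect=float(effect),
        seed=seed,
    )
    return expr, truth


def generate_case_control(
    n_cases: int,
    n_controls: int,
    module_sizes: Sequence[int],
    corr_cases: float,
    corr_controls: float,
    n_background: int,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Case and control cohorts with planted differential co-expression.

    Module genes are equicorrelated: gene = sqrt(rho) * f + sqrt(1-rho) * eps
    with rho = ``corr_cases`` in cases and ``corr_controls`` in controls.
    Background genes are independent N(0,1). Both matrices share gene ids.
    """
    _check_positive(n_cases=n_cases, n_controls=n_controls)
    for name, rho in (("corr_cases", corr_cases), ("corr_controls", corr_controls)):
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rho}")
    if corr_controls > corr_cases:
        raise ValueError("corr_controls must not exceed corr_cases")

    rng = _rng(seed, 3)
    n_module = int(sum(module_sizes))
    n_genes = n_module + n_background
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]

    def _cohort(n_samples: int, prefix: str, rho_by_module: List[float]) -> pd.DataFrame:
        vals = np.empty((n_genes, n_samples))
        row = 0
        for size, rho in zip(module_sizes, rho_by_module):
            f = rng.standard_normal(n_samples)
            eps = rng.standard_normal((size, n_samples))
            vals[row : row + size] = np.sqrt(rho) * f[None, :] + np.sqrt(1.0 - rho) * eps
            row += size
        if n_background:
            vals[row:] = rng.standard_normal((n_background, n_samples))
        cols = [f"{prefix}{i+1:03d}" for i in range(n_samples)]
        return pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"), columns=cols)

    k = len(module_sizes)
    cases = ExpressionMatrix(_cohort(n_cases, "case", [corr_cases] * k), unit="log2")
    controls = ExpressionMatrix(_cohort(n_controls, "ctrl", [corr_controls] * k), unit="log2")

    assignments: Dict[str, str] = {g: UNASSIGNED for g in gene_ids}
    row = 0
    for mi, size in enumerate(module_sizes):
        for g in gene_ids[row : row + size]:
            assignments[g] = f"M{mi+1}"
        row += size
    truth = SyntheticTruth(
        module_assignments=assignments,
        module_corr_cases=float(corr_cases),
        module_corr_controls=float(corr_controls),
        seed=seed,
    )
    return cases, controls, truth


def generate_phenotype(
    expr: ExpressionMatrix,
    truth: SyntheticTruth,
    trait_loading: float = 1.0,
    confounder_loading: float = 0.5,
    noise_sd: float = 0.3,
    module: str = "M1",
    seed: int = 0,
) -> Tuple[PhenotypeTable, SyntheticTruth]:
    """Fibrosis-like traits loaded on the module eigengene plus a BP confounder.

    Emits two traits (interstitial and perivascular fibrosis analogues), each
    ``trait_loading x eigengene + confounder_loading x BP + noise``, together
    with the blood-pressure-like covariate.
    """
    genes = truth.module_genes(module)
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"module genes missing from expression: {missing[:10]}")
    from .coexnet import module_eigengene  # local import avoids a cycle

    rng = _rng(seed, 4)
    eig = module_eigengene(expr, genes, label=module).loadings.to_numpy()
    # standardize the eigengene so loadings are on the SD scale
    eig = (eig - eig.mean()) / eig.std()
    n = expr.n_samples
    bp = rng.standard_normal(n)
    traits = {}
    for name in ("interstitial_fibrosis", "perivascular_fibrosis"):
        traits[name] = (
            trait_loading * eig + confounder_loading * bp + rng.normal(0.0, noise_sd, n)
        )
    data = pd.DataFrame(
        {**traits, "bp": bp}, index=pd.Index(expr.sample_ids, name="sample_id")
    )
    pheno = PhenotypeTable(
        data,
        trait_cols=["interstitial_fibrosis", "perivascular_fibrosis"],
        covariate_cols=["bp"],
    )
    truth_out = SyntheticTruth(
        module_assignments=truth.module_assignments,
        hotspot_snp=truth.hotspot_snp,
        hotspot_block=truth.hotspot_block,
        hotspot_effect=truth.hotspot_effect,
        module_corr_cases=truth.module_corr_cases,
        module_corr_controls=truth.module_corr_controls,
        trait_loading=float(trait_loading),
        confounder_loading=float(confounder_loading),
        seed=seed,
    )
    return pheno, truth_out
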