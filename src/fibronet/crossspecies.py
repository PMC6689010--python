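"""Cross-species module conservation and differential co-expression.

Conservation is tested by one-sided Fisher's exact tests of module overlap
over a one-to-one ortholog background, corrected by Benjamini-Yekutieli.
Differential co-expression between two cohorts uses the dispersion
statistic (root-mean-square difference of pairwise biweight
midcorrelations) against a null of equally sized random gene sets, with the
empirical P value (r + 1)/(n + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .coexnet import CorrelationMatrix, bicor_matrix
from .containers import ExpressionMatrix, ModuleSet


@dataclass
class OrthologMap:
    """One-to-one ortholog pairs between species A and species B."""

    pairs: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        a_genes = [a for a, _ in self.pairs]
        b_genes = [b for _, b in self.pairs]
        if len(set(a_genes)) != len(a_genes) or len(set(b_genes)) != len(b_genes):
            raise ValueError("ortholog map must be one-to-one on both sides")

    def a_to_b(self) -> Dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> Dict[str, str]:
        return {b: a for a, b in self.pairs}


def build_background(
    ortho: OrthologMap, genes_a: Sequence[str], genes_b: Sequence[str]
) -> List[Tuple[str, str]]:
    """Ortholog pairs robustly expressed in both species."""
    set_a, set_b = set(genes_a), set(genes_b)
    background = [(a, b) for a, b in ortho.pairs if a in set_a and b in set_b]
    if not background:
        raise ValueError("empty ortholog background: no pair expressed in both species")
    return background


def conservation_test(
    modules_a: ModuleSet,
    modules_b: ModuleSet,
    background: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """One-sided FET of every module pair's overlap over the background.

    Modules are first restricted to the background; the 2x2 table counts
    ortholog pairs by membership in the A-module and B-module, and the
    enrichment (alternative "greater") P values across all |A| x |B| pairs
    are adjusted by Benjamini-Yekutieli.
    """
    a_of = {a for a, _ in background}
    b_of = {b for _, b in background}
    pair_by_a = {a: b for a, b in background}
    M = len(background)

    rows = []
    for la in modules_a.module_order:
        mem_a = set(modules_a.members(la)) & a_of
        if not mem_a:
            warnings.warn(f"A-module {la} empty after background restriction, skipped")
            continue
        mapped_a = {pair_by_a[a] for a in mem_a}
        for lb in modules_b.module_order:
            mem_b = set(modules_b.members(lb)) & b_of
            if not mem_b:
                warnings.warn(f"B-module {lb} empty after background restriction, skipped")
                continue
            overlap = len(mapped_a & mem_b)
            n_a, n_b = len(mem_a), len(mem_b)
            table = [
                [overlap, n_a - overlap],
                [n_b - overlap, M - n_a - n_b + overlap],
            ]
            _, p = fisher_exact(table, alternative="greater")
            rows.append(
                {
                    "module_a": la,
                    "module_b": lb,
                    "size_a": n_a,
                    "size_b": n_b,
                    "overlap": overlap,
                    "background_size": M,
                    "fet_p": float(p),
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        result["adjusted_p"] = multipletests(result["fet_p"], method="fdr_by")[1]
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
    return result


def dispersion_statistic(
    corr_cases: CorrelationMatrix,
    corr_controls: CorrelationMatrix,
    genes: Sequence[str],
) -> float:
    """RMS difference of pairwise correlations between two cohorts.

    D = sqrt(mean over unordered pairs i<j of (r_cases - r_controls)^2);
    symmetric in the cohorts, zero iff the module's correlation structures
    coincide.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    for name, cm in (("cases", corr_cases), ("controls", corr_controls)):
        missing = [g for g in genes if g not in cm.gene_ids]
        if missing:
            raise ValueError(f"genes missing from {name} correlation matrix: {missing[:10]}")
    ia = [corr_cases.gene_ids.index(g) for g in genes]
    ib = [corr_controls.gene_ids.index(g) for g in genes]
    ca = corr_cases.values[np.ix_(ia, ia)]
    cb = corr_controls.values[np.ix_(ib, ib)]
    iu = np.triu_indices(len(genes), k=1)
    diff = ca[iu] - cb[iu]
    return float(np.sqrt(np.mean(diff**2)))


@dataclass
class DispersionResult:
    """Permutation test result for one module."""

    module: str
    size: int
    dispersion: float
    n_perm: int
    r_exceed: int
    empirical_p: float
    bonferroni_p: float

    def __post_init__(self) -> None:
        expected = (self.r_exceed + 1) / (self.n_perm + 1)
        if not np.isclose(self.empirical_p, expected):
            raise ValueError("empirical_p must equal (r + 1)/(n + 1)")


def _null_dispersions(
    delta: np.ndarray, universe_size: int, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    iu = np.triu_indices(set_size, k=1)
    out = np.empty(n_perm)
    for p in range(n_perm):
        idx = rng.choice(universe_size, size=set_size, replace=False)
        sub = delta[np.ix_(idx, idx)]
        out[p] = np.sqrt(np.mean(sub[iu] ** 2))
    return out


def differential_coexpression_tests(
    expr_cases: ExpressionMatrix,
    expr_controls: ExpressionMatrix,
    modules: Dict[str, Sequence[str]],
    n_perm: int = 100_000,
    seed: int = 0,
) -> List[DispersionResult]:
    """Dispersion permutation test for each module in a batch.

    All pairwise biweight midcorrelations over the shared gene universe are
    computed once per cohort; the null for a module of size m draws
    ``n_perm`` random m-gene sets from the universe without replacement.
    The empirical P is (r + 1)/(n + 1) with r the count of null dispersions
    strictly exceeding the observed one; the Bonferroni factor is the
    number of modules in the batch.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = [g for g in expr_cases.gene_ids if g in set(expr_controls.gene_ids)]
    if not universe:
        raise ValueError("no shared gene universe between cohorts")
    for name, genes in modules.items():
        extra = [g for g in genes if g not in set(universe)]
        if extra:
            raise ValueError(f"module {name}: genes outside the shared universe: {extra[:10]}")
        if len(genes) > len(universe):
            raise ValueError(f"module {name} larger than the universe")

    ca = bicor_matrix(expr_cases.subset_genes(universe))
    cb = bicor_matrix(expr_controls.subset_genes(universe))
    delta = ca.values - cb.values
    pos = {g: i for i, g in enumerate(universe)}

    rng = np.random.default_rng(seed)
    n_modules = len(modules)
    results = []
    for name, genes in modules.items():
        genes = list(genes)
        idx = [pos[g] for g in genes]
        iu = np.triu_indices(len(idx), k=1)
        sub = delta[np.ix_(idx, idx)]
        observed = float(np.sqrt(np.mean(sub[iu] ** 2)))
        null = _null_dispersions(delta, len(universe), len(idx), n_perm, rng)
        r_exceed = int((null > observed).sum())
        emp_p = (r_exceed + 1) / (n_perm + 1)
        results.append(
            DispersionResult(
                module=name,
                size=len(idx),
                dispersion=observed,
                n_perm=n_perm,
                r_exceed=r_exceed,
                empirical_p=emp_p,
                bonferroni_p=min(1.0, emp_p * n_modules),
            )
        )
    return results


def differential_coexpression_test(
    expr_cases: ExpressionMatrix,
    expr_controls: ExpressionMatrix,
    module_genes: Sequence[str],
    n_perm: int = 100_000,
    seed: int = 0,
    module_name: str = "module",
) -> DispersionResult:
    """Dispersion permutation test for a single module (batch of one)."""
    return differential_coexpression_tests(
        expr_cases, expr_controls, {module_name: list(module_genes)}, n_perm=n_perm, seed=seed
    )[0]
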