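"""Module-trait association: Spearman gene ranking and pre-ranked GSEA.

Genes are ranked by the Student P value of their Spearman correlation with a
trait (largest P first), each co-expression module is treated as a gene set,
and a classic (unweighted) pre-ranked GSEA with gene-label permutations
assigns ES/NES/nominal P/FDR q. Because the ranking metric is a P value,
trait association appears as a significant NEGATIVE normalized enrichment
score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .containers import ExpressionMatrix, ModuleSet, PhenotypeTable


@dataclass
class RankedGeneList:
    """Genes ordered by ranking metric, largest first.

    ``metric`` holds correlation P values aligned with ``gene_ids``; the
    list is sorted descending, so trait-associated genes (small P) sit at
    the bottom.
    """

    gene_ids: List[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.metric):
            raise ValueError("gene ids and metric lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        m = np.asarray(self.metric, dtype=float)
        if np.isnan(m).any():
            raise ValueError("metric contains missing values")
        if (np.diff(m) > 1e-12).any():
            raise ValueError("metric must be sorted descending")
        self.metric = m


def rank_genes_by_trait(expr: ExpressionMatrix, trait: np.ndarray) -> RankedGeneList:
    """Spearman correlation P value of every gene against a trait.

    P values come from the Student t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom. Genes are
    returned sorted descending by P. Constant genes (or a constant trait)
    get P = 1 with a warning.
    """
    trait = np.asarray(trait, dtype=float)
    n = expr.n_samples
    if len(trait) != n:
        raise ValueError("trait length must equal the number of samples")
    if n < 5:
        raise ValueError("need at least 5 samples")
    X = expr.values.to_numpy(dtype=float)
    trait_const = np.ptp(trait) == 0

    rx = np.apply_along_axis(rankdata, 1, X)
    ry = rankdata(trait)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum(axis=1)) * np.sqrt((ryc**2).sum())
    gene_const = (rxc**2).sum(axis=1) == 0
    safe = np.where(denom == 0, 1.0, denom)
    rho = np.clip(rxc @ ryc / safe, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        tt = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    pvals = 2.0 * t_dist.sf(np.abs(tt), df=n - 2)
    if trait_const or gene_const.any():
        warnings.warn("constant gene or trait: P set to 1")
        if trait_const:
            pvals[:] = 1.0
        pvals[gene_const] = 1.0
    order = np.argsort(-pvals, kind="stable")
    return RankedGeneList(
        gene_ids=[expr.gene_ids[i] for i in order], metric=pvals[order]
    )


def enrichment_score(ranked_ids: Sequence[str], gene_set: Sequence[str]) -> float:
    """Classic (unweighted) GSEA enrichment score.

    Walking down the ranked list, hits add 1/N_h and misses subtract
    1/(N - N_h); the ES is the signed maximum deviation of the running sum
    from zero.
    """
    hits = set(gene_set)
    is_hit = np.fromiter((g in hits for g in ranked_ids), dtype=bool, count=len(ranked_ids))
    return _es_from_mask(is_hit)


def _es_from_mask(is_hit: np.ndarray) -> float:
    N = is_hit.size
    Nh = int(is_hit.sum())
    if Nh == 0 or Nh == N:
        raise ValueError("gene set must be a proper nonempty subset of the list")
    inc = np.where(is_hit, 1.0 / Nh, -1.0 / (N - Nh))
    cs = np.cumsum(inc)
    hi, lo = float(cs.max()), float(cs.min())
    # positive deviation wins an exact-magnitude tie
    return hi if hi >= -lo else lo


def _es_from_positions(pos: np.ndarray, N: int) -> float:
    """ES from sorted 0-based hit positions (sparse running-sum walk)."""
    Nh = pos.size
    miss = 1.0 / (N - Nh)
    k = np.arange(1, Nh + 1)
    after = k / Nh - (pos + 1 - k) * miss  # running sum just after each hit
    before = (k - 1) / Nh - (pos + 1 - k) * miss  # just before each hit
    hi = after.max()
    lo = min(before.min(), -(N - pos[-1] - 1) * miss + after[-1]) if Nh else 0.0
    lo = min(lo, 0.0)
    hi = max(hi, 0.0)
    return float(hi if hi >= -lo else lo)


@dataclass
class GseaResult:
    """Per-set enrichment results."""

    table: pd.DataFrame  # columns: set, size, es, nes, nominal_p, fdr_q

    def significant(self, fdr: float = 0.05, negative: bool = True) -> List[str]:
        t = self.table
        mask = t["fdr_q"] < fdr
        if negative:
            mask &= t["nes"] < 0
        return list(t.loc[mask, "set"])


def gsea_preranked(
    ranked: RankedGeneList,
    gene_sets: Dict[str, Sequence[str]],
    n_perm: int = 10_000,
    min_size: int = 10,
    max_size: int = 5_000,
    seed: int = 0,
) -> GseaResult:
    """Classic pre-ranked GSEA with gene-label permutation nulls.

    Gene sets are intersected with the ranked universe before size
    filtering; null enrichment scores come from ``n_perm`` random same-size
    gene sets. NES divides ES by the mean magnitude of same-sign null ES;
    the FDR q follows the positive/negative-tail normalized procedure of
    the reference method, with a running minimum enforcing monotonicity
    within each sign class.
    """
    rng = np.random.default_rng(seed)
    ids = ranked.gene_ids
    N = len(ids)
    index = {g: i for i, g in enumerate(ids)}

    kept: List[Tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        pos = np.array(sorted({index[g] for g in members if g in index}), dtype=int)
        if pos.size == 0:
            warnings.warn(f"gene set {name!r}: empty intersection with the ranked universe, skipped")
            continue
        if not (min_size <= pos.size <= max_size) or pos.size == N:
            continue
        kept.append((name, pos))
    if not kept:
        return GseaResult(pd.DataFrame(columns=["set", "size", "es", "nes", "nominal_p", "fdr_q"]))

    # share null ES across sets of identical size
    sizes = sorted({pos.size for _, pos in kept})
    nulls: Dict[int, np.ndarray] = {}
    for s in sizes:
        es = np.empty(n_perm)
        for p in range(n_perm):
            sample = np.sort(rng.choice(N, size=s, replace=False))
            es[p] = _es_from_positions(sample, N)
        nulls[s] = es

    rows = []
    null_nes_pool: List[np.ndarray] = []
    obs_nes: List[float] = []
    for name, pos in kept:
        es = _es_from_positions(pos, N)
        null = nulls[pos.size]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
        else:
            same = neg_null
        if same.size == 0:
            warnings.warn(f"gene set {name!r}: no same-sign null ES; NES undefined")
            nes, nominal_p = np.nan, np.nan
        else:
            mean_mag = np.abs(same).mean()
            nes = es / mean_mag
            nominal_p = float((np.abs(same) >= abs(es)).sum() / same.size)
        rows.append({"set": name, "size": int(pos.size), "es": es, "nes": nes, "nominal_p": nominal_p})
        obs_nes.append(nes)
        # normalize this set's nulls for the pooled FDR null distribution
        nn = np.empty_like(null)
        nn[:] = np.nan
        if pos_null.size:
            nn[null >= 0] = null[null >= 0] / np.abs(pos_null).mean()
        if neg_null.size:
            nn[null < 0] = null[null < 0] / np.abs(neg_null).mean()
        null_nes_pool.append(nn[~np.isnan(nn)])

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs = np.asarray(obs_nes, dtype=float)
    fdr = np.full(len(rows), np.nan)
    for i, nes in enumerate(obs):
        if np.isnan(nes):
            continue
        if nes >= 0:
            p_null = (pool >= nes).sum() / max((pool >= 0).sum(), 1)
            p_obs = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            p_null = (pool <= nes).sum() / max((pool < 0).sum(), 1)
            p_obs = (obs <= nes).sum() / max((obs < 0).sum(), 1)
        fdr[i] = min(1.0, p_null / p_obs) if p_obs > 0 else np.nan

    table = pd.DataFrame(rows)
    table["fdr_q"] = fdr
    # enforce monotone nonincreasing q in |NES| within each sign class
    for sign in (1, -1):
        mask = (table["nes"] * sign) >= 0 if sign > 0 else (table["nes"] * sign) > 0
        idx = table.index[mask & table["nes"].notna()]
        if len(idx):
            order = table.loc[idx, "nes"].abs().sort_values(ascending=False).index
            table.loc[order, "fdr_q"] = np.minimum.accumulate(table.loc[order, "fdr_q"].to_numpy())
    return GseaResult(table.sort_values("nes").reset_index(drop=True))


def associate_modules(
    module_set: ModuleSet,
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    traits: Optional[Sequence[str]] = None,
    n_perm: int = 10_000,
    min_size: int = 10,
    max_size: int = 5_000,
    fdr: float = 0.05,
    seed: int = 0,
) -> Dict[str, GseaResult]:
    """GSEA of every module against every trait.

    Each module is one gene set; per trait the genes are ranked by Spearman
    P value and a module counts as trait-associated when its FDR q < 0.05
    with negative NES. Traits are expected to be covariate-adjusted
    upstream.
    """
    traits = list(traits) if traits is not None else list(pheno.trait_cols)
    results: Dict[str, GseaResult] = {}
    gene_sets = module_set.as_gene_sets()
    pheno_aligned = pheno.data.loc[expr.sample_ids]
    for ti, trait in enumerate(traits):
        if trait not in pheno.data.columns:
            raise ValueError(f"trait {trait!r} not in phenotype table")
        ranked = rank_genes_by_trait(expr, pheno_aligned[trait].to_numpy(dtype=float))
        res = gsea_preranked(
            ranked, gene_sets, n_perm=n_perm, min_size=min_size, max_size=max_size,
            seed=seed + ti,
        )
        res.table["associated"] = (res.table["fdr_q"] < fdr) & (res.table["nes"] < 0)
        results[trait] = res
    return results
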