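"""Bayesian network-eQTL mapping.

A gene module's expression is treated as a multivariate quantitative trait
and regressed on all (LD-pruned) SNPs with sparse Bayesian variable
selection: per-SNP inclusion indicators with prior pi = E(p_g)/p, a Zellner
g-prior (g = n) on included coefficients, and a Metropolis-Hastings sampler
over models with add/delete/swap moves. The marginal posterior inclusion
probability (MPPI) of each gene-SNP pair converts to a Bayes factor

    BF = [MPPI/(1-MPPI)] / [pi/(1-pi)]

and a SNP is called a regulatory locus for the module when the median BF
across module genes exceeds 100. Also provides LD-block representative-SNP
pruning, exact 2^p posterior enumeration (the sampler's oracle), syntenic
window translation between species, and isoform-level cis mapping with
Kruskal-Wallis tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GenomicInterval, GenotypeMatrix
from .crossspecies import OrthologMap

DEFAULT_E_PG = 2.0
BF_CALL_THRESHOLD = 100.0


# ---------------------------------------------------------------------------
# prior / Bayes factor arithmetic
# ---------------------------------------------------------------------------

def prior_inclusion(e_pg: float, p: int) -> float:
    """Prior inclusion probability pi = E(p_g)/p.

    E(p_g) is the a priori expected number of control points per gene
    (default 2); p is the number of SNPs tested.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    pi = e_pg / p
    if not 0 < pi < 1:
        raise ValueError(f"prior pi = {pi} outside (0, 1); check e_pg and p")
    return pi


def mppi_to_bf(mppi: float, prior_pi: float) -> float:
    """Bayes factor as posterior odds over prior odds."""
    if not 0 <= mppi < 1:
        raise ValueError("mppi must be in [0, 1); cap it upstream")
    if not 0 < prior_pi < 1:
        raise ValueError("prior_pi must be in (0, 1)")
    prior_odds = prior_pi / (1.0 - prior_pi)
    return (mppi / (1.0 - mppi)) / prior_odds


# ---------------------------------------------------------------------------
# model marginal likelihood (Zellner g-prior, coefficients integrated out)
# ---------------------------------------------------------------------------

def _standardize_columns(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; returns the matrix and a zero-variance mask."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    return (X - mu) / sd_safe, zero


def _log_marginal(G: np.ndarray, b: np.ndarray, yy: float, idx: np.ndarray, g: float, n: int) -> float:
    """Log marginal likelihood of the model selecting columns ``idx``.

    With centered y and a g-prior on the included coefficients the
    marginal is proportional to
    (1+g)^(-k/2) * (yTy - g/(1+g) * SSR)^(-(n-1)/2).
    """
    k = len(idx)
    if k == 0:
        return -(n - 1) / 2.0 * math.log(yy)
    Gs = G[np.ix_(idx, idx)]
    bs = b[idx]
    try:
        beta = np.linalg.solve(Gs, bs)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(Gs, bs, rcond=None)[0]
    ssr = float(bs @ beta)
    val = yy - g / (1.0 + g) * ssr
    val = max(val, 1e-300)
    return -k / 2.0 * math.log(1.0 + g) - (n - 1) / 2.0 * math.log(val)


def exact_mppi_enumeration(y: np.ndarray, X: np.ndarray, e_pg: float = DEFAULT_E_PG) -> np.ndarray:
    """Exact posterior inclusion probabilities by summing over all 2^p models.

    Serves as the independent oracle for the MCMC sampler; guarded at
    p <= 15.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p > 15:
        raise ValueError("enumeration guarded at p <= 15")
    if p == 0:
        raise ValueError("need at least one predictor")
    if not np.isfinite(y).all():
        raise ValueError("non-finite response")
    Xs, zero = _standardize_columns(X)
    yc = y - y.mean()
    yy = float(yc @ yc)
    if yy == 0:
        raise ValueError("constant response")
    G = Xs.T @ Xs
    b = Xs.T @ yc
    g = float(n)
    pi = prior_inclusion(e_pg, p)
    log_prior_odds = math.log(pi) - math.log(1.0 - pi)

    active = np.flatnonzero(~zero)
    pa = len(active)
    log_posts = np.empty(2**pa)
    masks = []
    for m in range(2**pa):
        idx = active[[j for j in range(pa) if m >> j & 1]]
        masks.append(idx)
        log_posts[m] = _log_marginal(G, b, yy, idx, g, n) + len(idx) * log_prior_odds
    log_posts -= log_posts.max()
    probs = np.exp(log_posts)
    probs /= probs.sum()
    mppi = np.zeros(p)
    for m, idx in enumerate(masks):
        mppi[idx] += probs[m]
    mppi[zero] = pi  # no information: posterior equals prior
    return mppi


# ---------------------------------------------------------------------------
# Metropolis-Hastings sampler over inclusion indicators
# ---------------------------------------------------------------------------

def spike_slab_mppi(
    y: np.ndarray,
    X: np.ndarray,
    e_pg: float = DEFAULT_E_PG,
    n_iter: int = 20_000,
    n_burnin: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-predictor marginal posterior inclusion probabilities.

    Bayesian variable selection with Bernoulli(pi) inclusion priors
    (pi = e_pg/p), a g-prior (g = n) slab and coefficients integrated out;
    the model space is explored by Metropolis-Hastings with add/delete/swap
    moves chosen uniformly among the feasible ones. MPPI_j is the posterior
    frequency of inclusion after burn-in (default 20% of iterations).
    Zero-variance predictors get MPPI equal to the prior with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValueError("need at least one predictor")
    if n < 10:
        raise ValueError("need at least 10 samples")
    if not np.isfinite(y).all():
        raise ValueError("non-finite response")
    if n_burnin is None:
        n_burnin = n_iter // 5
    if not 0 <= n_burnin < n_iter:
        raise ValueError("need 0 <= n_burnin < n_iter")

    Xs, zero = _standardize_columns(X)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance predictor(s): MPPI set to prior")
    yc = y - y.mean()
    yy = float(yc @ yc)
    if yy == 0:
        raise ValueError("constant response")
    G = Xs.T @ Xs
    b = Xs.T @ yc
    g = float(n)
    pi = prior_inclusion(e_pg, p)
    log_prior_odds = math.log(pi) - math.log(1.0 - pi)

    active = np.flatnonzero(~zero)
    pa = len(active)
    if pa == 0:
        return np.full(p, pi)

    rng = np.random.default_rng(seed)
    included: List[int] = []  # indices into `active`
    in_set = np.zeros(pa, dtype=bool)
    current = _log_marginal(G, b, yy, active[included], g, n)

    counts = np.zeros(pa)
    n_kept = 0

    def _feasible(k: int) -> List[str]:
        moves = []
        if k < pa:
            moves.append("add")
        if k > 0:
            moves.append("delete")
        if 0 < k < pa:
            moves.append("swap")
        return moves

    excluded = list(range(pa))
    for it in range(n_iter):
        k = len(included)
        moves = _feasible(k)
        move = moves[rng.integers(len(moves))]
        if move == "add":
            j = excluded[rng.integers(len(excluded))]
            new_included = included + [j]
            # forward: choose add (1/len(moves)) x choose j (1/(pa-k))
            log_q_fwd = -math.log(len(moves)) - math.log(pa - k)
            rev_moves = _feasible(k + 1)
            log_q_rev = -math.log(len(rev_moves)) - math.log(k + 1)
            dk = 1
        elif move == "delete":
            pos = int(rng.integers(k))
            j = included[pos]
            new_included = included[:pos] + included[pos + 1 :]
            log_q_fwd = -math.log(len(moves)) - math.log(k)
            rev_moves = _feasible(k - 1)
            log_q_rev = -math.log(len(rev_moves)) - math.log(pa - k + 1)
            dk = -1
        else:  # swap
            pos = int(rng.integers(k))
            j_out = included[pos]
            j_in = excluded[rng.integers(len(excluded))]
            new_included = included[:pos] + included[pos + 1 :] + [j_in]
            log_q_fwd = -math.log(len(moves)) - math.log(k) - math.log(pa - k)
            log_q_rev = log_q_fwd  # same k, same feasible set
            dk = 0
            j = j_in

        proposal = _log_marginal(G, b, yy, active[new_included], g, n)
        log_alpha = (proposal - current) + dk * log_prior_odds + (log_q_rev - log_q_fwd)
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            if move == "add":
                included = new_included
                in_set[j] = True
                excluded.remove(j)
            elif move == "delete":
                included = new_included
                in_set[j] = False
                excluded.append(j)
            else:
                included = new_included
                in_set[j_out] = False
                in_set[j_in] = True
                excluded.remove(j_in)
                excluded.append(j_out)
            current = proposal
        if it >= n_burnin:
            counts[in_set] += 1
            n_kept += 1

    mppi = np.full(p, pi)
    mppi[active] = counts / n_kept
    return mppi


class SpikeSlabRegression(BaseEstimator):
    """Sparse Bayesian variable selection as a scikit-learn estimator.

    Fits inclusion indicators over the columns of X for a single response
    with prior pi = e_pg / n_features and a Zellner g-prior slab; the
    fitted attributes expose MPPI and the derived Bayes factors.

    Parameters
    ----------
    e_pg : float
        A priori expected number of included predictors.
    n_iter, n_burnin : int
        MCMC length and burn-in (default burn-in: 20% of n_iter).
    random_state : int
        Sampler seed.

    Attributes
    ----------
    mppi_ : ndarray (n_features,)
        Marginal posterior inclusion probabilities.
    bf_ : ndarray (n_features,)
        Bayes factors, with MPPI capped at 1 - 1/(2 n_iter).
    prior_pi_ : float
    n_features_in_ : int
    """

    def __init__(
        self,
        e_pg: float = DEFAULT_E_PG,
        n_iter: int = 20_000,
        n_burnin: Optional[int] = None,
        random_state: int = 0,
    ) -> None:
        self.e_pg = e_pg
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y sample counts differ")
        self.n_features_in_ = X.shape[1]
        self.prior_pi_ = prior_inclusion(self.e_pg, X.shape[1])
        self.mppi_ = spike_slab_mppi(
            y, X, e_pg=self.e_pg, n_iter=self.n_iter, n_burnin=self.n_burnin,
            seed=self.random_state,
        )
        cap = 1.0 - 1.0 / (2.0 * self.n_iter)
        self.capped_ = self.mppi_ > cap
        clipped = np.minimum(self.mppi_, cap)
        self.bf_ = np.array([mppi_to_bf(m, self.prior_pi_) for m in clipped])
        return self

    def get_support(self, threshold: float = 0.5) -> np.ndarray:
        """Predictors with MPPI above ``threshold``."""
        if not hasattr(self, "mppi_"):
            raise AttributeError("fit the estimator first")
        return self.mppi_ > threshold


# ---------------------------------------------------------------------------
# LD-block pruning
# ---------------------------------------------------------------------------

def prune_ld_blocks(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """One representative SNP per LD block.

    Within each block the representative is the SNP with the highest mean
    Spearman correlation to the other block members (input-order tie
    break); SNPs without a block pass through unchanged, appended after the
    block representatives.
    """
    if genotypes.block_id is None:
        raise ValueError("block_id required for LD pruning")
    blocks = genotypes.block_id
    dosage = genotypes.dosage

    keep: List[str] = []
    seen: List[str] = []
    for snp, blk in blocks.items():
        if pd.isna(blk) or blk == "":
            continue
        if blk in seen:
            continue
        seen.append(blk)
        members = blocks.index[blocks == blk].tolist()
        if len(members) == 1:
            keep.append(members[0])
            continue
        sub = dosage.loc[members].to_numpy(dtype=float)
        ranks = np.apply_along_axis(rankdata, 1, sub)
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((rc**2).sum(axis=1))
        norms[norms == 0] = 1.0
        R = rc / norms[:, None]
        C = R @ R.T
        np.fill_diagonal(C, 0.0)
        means = C.sum(axis=1) / (len(members) - 1)
        keep.append(members[int(np.argmax(means))])
    blockless = [s for s, blk in blocks.items() if pd.isna(blk) or blk == ""]
    order = keep + blockless
    return GenotypeMatrix(
        dosage=dosage.loc[order],
        chrom=genotypes.chrom.loc[order],
        pos=genotypes.pos.loc[order],
        block_id=blocks.loc[order],
        ploidy=genotypes.ploidy,
    )


# ---------------------------------------------------------------------------
# network mapping
# ---------------------------------------------------------------------------

@dataclass
class EqtlPosterior:
    """Per gene-SNP posterior inclusion probabilities and Bayes factors."""

    prior_pi: float
    e_pg: float
    mppi: pd.DataFrame  # genes x SNPs
    bf: pd.DataFrame  # genes x SNPs
    sampler_diag: Dict[str, object] = field(default_factory=dict)
    failed_genes: List[str] = field(default_factory=list)


def _summarize_loci(bf: pd.DataFrame, threshold: float = BF_CALL_THRESHOLD) -> pd.DataFrame:
    summary = pd.DataFrame(
        {
            "median_bf": bf.median(axis=0),
            "n_genes_bf_gt_threshold": (bf > threshold).sum(axis=0),
        }
    )
    summary["called"] = summary["median_bf"] > threshold
    summary.index.name = "snp_id"
    return summary


def network_eqtl_map(
    expr: ExpressionMatrix,
    module_genes: Sequence[str],
    genotypes: GenotypeMatrix,
    e_pg: float = DEFAULT_E_PG,
    n_iter: int = 20_000,
    n_burnin: Optional[int] = None,
    seed: int = 0,
    bf_call_threshold: float = BF_CALL_THRESHOLD,
) -> Tuple[EqtlPosterior, pd.DataFrame]:
    """Map a module's joint expression to the genome.

    Runs the spike-and-slab sampler independently for every module gene
    against the full SNP matrix under the shared prior pi = e_pg/p,
    converts MPPI to Bayes factors, and summarizes each SNP by the median
    BF across module genes; a SNP is called when median BF > 100.
    """
    module_genes = list(module_genes)
    missing = [g for g in module_genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"module genes missing from expression: {missing[:10]}")
    shared = [s for s in expr.sample_ids if s in set(genotypes.sample_ids)]
    if len(shared) < 10:
        raise ValueError("fewer than 10 samples shared between expression and genotypes")
    X = genotypes.dosage.loc[:, shared].to_numpy(dtype=float).T  # samples x p
    p = X.shape[1]
    pi = prior_inclusion(e_pg, p)
    cap = 1.0 - 1.0 / (2.0 * n_iter)

    mppi_rows, bf_rows, failed = [], [], []
    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.generate_state(len(module_genes)) % (2**31)
    for gi, gene in enumerate(module_genes):
        y = expr.values.loc[gene, shared].to_numpy(dtype=float)
        try:
            mppi = spike_slab_mppi(
                y, X, e_pg=e_pg, n_iter=n_iter, n_burnin=n_burnin, seed=int(gene_seeds[gi])
            )
        except Exception as exc:  # noqa: BLE001 - flagged, summary over the rest
            warnings.warn(f"sampler failed for gene {gene}: {exc}")
            failed.append(gene)
            continue
        mppi_rows.append(pd.Series(mppi, index=genotypes.snp_ids, name=gene))
        bf_rows.append(
            pd.Series(
                [mppi_to_bf(min(m, cap), pi) for m in mppi],
                index=genotypes.snp_ids,
                name=gene,
            )
        )
    if not mppi_rows:
        raise ValueError("sampler failed for every module gene")
    posterior = EqtlPosterior(
        prior_pi=pi,
        e_pg=e_pg,
        mppi=pd.DataFrame(mppi_rows),
        bf=pd.DataFrame(bf_rows),
        sampler_diag={"n_iter": n_iter, "n_burnin": n_burnin if n_burnin is not None else n_iter // 5, "seed": seed},
        failed_genes=failed,
    )
    summary = _summarize_loci(posterior.bf, threshold=bf_call_threshold)
    return posterior, summary


# ---------------------------------------------------------------------------
# syntenic window translation
# ---------------------------------------------------------------------------

def syntenic_window(
    rat_block: GenomicInterval,
    rat_genes: pd.DataFrame,
    ortholog_map: OrthologMap,
    other_genes: pd.DataFrame,
    window_mb: float = 10.0,
) -> GenomicInterval:
    """Translate a mapped interval into the other species via orthology.

    Steps: (1) center of the source haplotype, start + (end-start)/2;
    (2) nearest source gene to that center (gene midpoints; walking outward
    to the nearest gene with an ortholog; smaller start coordinate on
    distance ties); (3) its ortholog's center in the other species;
    (4) a window of ``window_mb`` Mb (+/- half) around that center, clipped
    at 1.

    Gene tables need columns gene_id, chrom, start, end (1-based inclusive).
    """
    for name, df in (("rat_genes", rat_genes), ("other_genes", other_genes)):
        for col in ("gene_id", "chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"{name} must have column {col!r}")
    center = rat_block.center()
    cand = rat_genes[rat_genes["chrom"] == rat_block.chrom].copy()
    if cand.empty:
        raise ValueError(f"no gene on chromosome {rat_block.chrom}")
    cand["mid"] = cand["start"] + (cand["end"] - cand["start"]) // 2
    cand["dist"] = (cand["mid"] - center).abs()
    cand = cand.sort_values(["dist", "start"], kind="stable")

    a2b = ortholog_map.a_to_b()
    other_by_id = other_genes.set_index("gene_id")
    target = None
    for _, row in cand.iterrows():
        ortho = a2b.get(row["gene_id"])
        if ortho is not None and ortho in other_by_id.index:
            target = other_by_id.loc[ortho]
            break
    if target is None:
        raise ValueError("no mappable gene with an ortholog on the chromosome")

    gene_center = int(target["start"] + (target["end"] - target["start"]) // 2)
    half = int(round(window_mb * 1e6 / 2))
    return GenomicInterval(
        chrom=str(target["chrom"]),
        start=max(1, gene_center - half),
        end=gene_center + half,
    )


# ---------------------------------------------------------------------------
# isoform-level cis mapping
# ---------------------------------------------------------------------------

def restrict_to_window(genotypes: GenotypeMatrix, window: GenomicInterval) -> GenotypeMatrix:
    """SNPs inside a 1-based inclusive interval."""
    mask = (
        (genotypes.chrom == window.chrom)
        & (genotypes.pos >= window.start)
        & (genotypes.pos <= window.end)
    )
    ids = genotypes.dosage.index[mask]
    if len(ids) == 0:
        raise ValueError("no SNP inside the window")
    return GenotypeMatrix(
        dosage=genotypes.dosage.loc[ids],
        chrom=genotypes.chrom.loc[ids],
        pos=genotypes.pos.loc[ids],
        block_id=None if genotypes.block_id is None else genotypes.block_id.loc[ids],
        ploidy=genotypes.ploidy,
    )


def kruskal_by_genotype(values: np.ndarray, dosage: np.ndarray) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square P across dosage groups.

    Genotype groups with fewer than 2 samples are dropped with a warning;
    if fewer than 2 groups remain, H = 0 and P = 1 (flagged via warning).
    """
    values = np.asarray(values, dtype=float)
    dosage = np.asarray(dosage)
    groups = []
    for lvl in np.unique(dosage):
        grp = values[dosage == lvl]
        if grp.size < 2:
            warnings.warn(f"genotype group {lvl} has < 2 samples, dropped")
            continue
        groups.append(grp)
    if len(groups) < 2:
        warnings.warn("fewer than 2 usable genotype groups; P set to 1")
        return 0.0, 1.0
    if np.ptp(np.concatenate(groups)) == 0:
        # identical values everywhere: no rank variation, H = 0
        return 0.0, 1.0
    h, p = kruskal(*groups)
    return float(h), float(p)


def cis_isoform_eqtl(
    isoform_expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    window: GenomicInterval,
    e_pg: float = DEFAULT_E_PG,
    n_iter: int = 20_000,
    n_burnin: Optional[int] = None,
    seed: int = 0,
) -> Tuple[EqtlPosterior, pd.DataFrame]:
    """Isoform-level cis mapping inside a window.

    Each isoform (row) is mapped with the spike-and-slab sampler against
    the windowed SNPs (prior recomputed with the windowed p); its lead SNP
    is the one with the highest MPPI, tested by Kruskal-Wallis across
    genotype groups, and the KW P values are BH-corrected across isoforms.
    """
    geno = restrict_to_window(genotypes, window)
    posterior, _ = network_eqtl_map(
        isoform_expr,
        isoform_expr.gene_ids,
        geno,
        e_pg=e_pg,
        n_iter=n_iter,
        n_burnin=n_burnin,
        seed=seed,
    )
    shared = [s for s in isoform_expr.sample_ids if s in set(geno.sample_ids)]
    rows = []
    for iso in posterior.mppi.index:
        lead = posterior.mppi.loc[iso].idxmax()
        vals = isoform_expr.values.loc[iso, shared].to_numpy(dtype=float)
        dose = geno.dosage.loc[lead, shared].to_numpy()
        h, p = kruskal_by_genotype(vals, dose)
        rows.append({"isoform": iso, "lead_snp": lead, "kw_h": h, "kw_p": p})
    kw = pd.DataFrame(rows)
    kw["fdr"] = multipletests(kw["kw_p"], method="fdr_bh")[1]
    kw["n_isoforms_tested"] = len(kw)
    return posterior, kw
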