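"""Co-expression module inference.

Robust pairwise correlation (Tukey biweight midcorrelation), soft-threshold
selection against a scale-free topology criterion, topological overlap,
static-cut hierarchical module detection with eigengene merging, and a
scikit-learn-style ``ModuleDetector`` estimator wrapping the full chain.

The network is unsigned: adjacency a_ij = |bicor_ij|^beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import Eigengene, ExpressionMatrix, ModuleSet, UNASSIGNED

# R's mad() consistency constant; bicor's tuning window is 9 x mad.
MAD_CONSTANT = 1.4826


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene correlation matrix with unit diagonal."""

    gene_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.gene_ids):
            raise ValueError("matrix shape must match gene ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(v).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("correlation entries must be in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


def _biweight_rows(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight-standardized deviations.

    Returns the normalized rows (so that the correlation is a plain inner
    product) and a boolean mask of constant rows (MAD = 0 and SD = 0), whose
    correlations are undefined and reported as 0.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    d = X - med
    mad = np.median(np.abs(d), axis=1, keepdims=True) * MAD_CONSTANT
    with np.errstate(divide="ignore", invalid="ignore"):
        u = d / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    a = d * w

    # MAD = 0: fall back to Pearson-style centering for that gene.
    mad_zero = mad[:, 0] == 0
    if mad_zero.any():
        dc = X[mad_zero] - X[mad_zero].mean(axis=1, keepdims=True)
        a[mad_zero] = dc

    norms = np.sqrt((a**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    return a / safe[:, None], constant


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Tukey biweight midcorrelation of two vectors.

    Observations further than 9 x mad from the median get zero weight;
    within the window the weight is (1 - u^2)^2. Falls back to Pearson for a
    vector whose MAD is zero.
    """
    rows, constant = _biweight_rows(np.vstack([x, y]))
    if constant.any():
        warnings.warn("constant input: correlation undefined, returning 0")
        return 0.0
    return float(np.clip(rows[0] @ rows[1], -1.0, 1.0))


def bicor_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """All-pairs biweight midcorrelation of the expression matrix rows."""
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples for correlation estimation")
    rows, constant = _biweight_rows(expr.values.to_numpy())
    C = np.clip(rows @ rows.T, -1.0, 1.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): correlations set to 0"
        )
        C[constant, :] = 0.0
        C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    return CorrelationMatrix(expr.gene_ids, C)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) against log10 k over equal-count connectivity bins.

    p(k) is the empirical density (count / (N x bin width)); with
    quantile-based bins the distribution shape lives in the unequal bin
    widths. Returns NaN when fewer than 3 non-empty bins remain.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 4:
        return float("nan")
    counts, edges = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    keep = counts > 0
    if keep.sum() < 3:
        return float("nan")
    # mean connectivity inside each kept bin
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(counts) - 1)
    sums = np.bincount(which, weights=k, minlength=len(counts))
    mean_k = sums[keep] / counts[keep]
    density = counts[keep] / (k.size * widths[keep])
    x = np.log10(mean_k)
    y = np.log10(density)
    if np.ptp(x) == 0:
        return float("nan")
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - (resid**2).sum() / ss_tot)


def pick_soft_threshold(
    corr: CorrelationMatrix,
    candidate_betas: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_cut: float = 0.8,
) -> Tuple[int, pd.DataFrame]:
    """Choose the soft threshold beta for the unsigned adjacency |corr|^beta.

    Among all candidates whose scale-free fit R^2 exceeds ``r2_cut``, the one
    with the highest mean connectivity is returned (smallest beta on ties).
    If none qualifies, the beta with the highest R^2 is returned and the
    diagnostics table carries ``flagged=True``.
    """
    if not candidate_betas:
        raise ValueError("candidate_betas must be non-empty")
    if any(b < 1 for b in candidate_betas):
        raise ValueError("all candidate betas must be >= 1")
    absC = np.abs(corr.values).copy()
    np.fill_diagonal(absC, 0.0)
    rows = []
    for beta in candidate_betas:
        A = absC**beta
        k = A.sum(axis=1)
        rows.append(
            {
                "beta": int(beta),
                "scale_free_r2": scale_free_fit(k),
                "mean_connectivity": float(k.mean()),
            }
        )
    diag = pd.DataFrame(rows)
    ok = diag[diag["scale_free_r2"] > r2_cut]
    if len(ok):
        best_k = ok["mean_connectivity"].max()
        chosen = int(ok.loc[ok["mean_connectivity"] == best_k, "beta"].min())
        diag["flagged"] = False
    else:
        with_r2 = diag.dropna(subset=["scale_free_r2"])
        if with_r2.empty:
            chosen = int(diag["beta"].iloc[0])
        else:
            chosen = int(with_r2.loc[with_r2["scale_free_r2"].idxmax(), "beta"])
        diag["flagged"] = True
        warnings.warn(
            f"no candidate beta reached scale-free R^2 > {r2_cut}; "
            f"falling back to beta={chosen} with the highest R^2"
        )
    return chosen, diag


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: direct adjacency plus shared-neighbor agreement.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), where the
    shared-neighbor sum excludes u in {i, j} and k is the connectivity
    excluding the diagonal. TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float).copy()
    if (A < 0).any():
        raise ValueError("adjacency entries must be nonnegative")
    if A.max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("adjacency entries must be in [0, 1]")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # includes u = i and u = j terms only via zero diagonal
    num = shared + A
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def module_eigengene(
    expr: ExpressionMatrix, genes: Sequence[str], label: str = "ME"
) -> Eigengene:
    """First principal component of the gene-standardized module submatrix.

    The sign is oriented so the mean correlation with member genes is
    nonnegative; loadings have unit norm.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.values.index]
    if len(present) < 2:
        raise ValueError("need at least 2 module genes present in the expression matrix")
    sub = expr.values.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    # orientation: nonnegative mean correlation with member genes; with
    # standardized gene rows the sign of mean(Z @ centered v) decides it
    vc = v - v.mean()
    score = float(np.mean(Z @ (vc if np.linalg.norm(vc) > 0 else v)))
    if score < 0:
        v = -v
    return Eigengene(label=label, loadings=pd.Series(v, index=expr.sample_ids))


def _eigengene_corr(e1: Eigengene, e2: Eigengene) -> float:
    a = e1.loadings.to_numpy()
    b = e2.loadings.to_numpy()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def detect_modules(
    tom: np.ndarray,
    min_size: int = 30,
    cut_quantile: float = 0.5,
    merge_height: float = 0.25,
    expr: Optional[ExpressionMatrix] = None,
    gene_ids: Optional[Sequence[str]] = None,
) -> Tuple[ModuleSet, List[Eigengene]]:
    """Static-cut hierarchical module detection with eigengene merging.

    Average-linkage clustering on the dissimilarity 1 - TOM; the tree is cut
    at the ``cut_quantile`` of its merge heights; clusters smaller than
    ``min_size`` fall into the unassigned pool. Module pairs whose eigengene
    dissimilarity (1 - correlation) is below ``merge_height`` are merged
    iteratively; surviving modules are relabeled M1..Mk by decreasing size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if expr is None:
        raise ValueError("expression matrix required for eigengene computation")
    ids = list(gene_ids) if gene_ids is not None else expr.gene_ids
    n = len(ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape must match the gene list")

    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, cut_quantile))
    labels = fcluster(Z, t=cut, criterion="distance")

    clusters: Dict[int, List[str]] = {}
    for g, l in zip(ids, labels):
        clusters.setdefault(int(l), []).append(g)
    modules = {l: gs for l, gs in clusters.items() if len(gs) >= min_size}
    if not modules:
        warnings.warn("no cluster reached min_size; all genes unassigned")
        return (
            ModuleSet(assignments={g: UNASSIGNED for g in ids}, params=_params(min_size, merge_height)),
            [],
        )
    # provisional labels, then eigengene merging
    groups: List[List[str]] = [sorted(gs, key=ids.index) for gs in modules.values()]
    while True:
        if len(groups) < 2:
            break
        eigs = [module_eigengene(expr, gs) for gs in groups]
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = 1.0 - _eigengene_corr(eigs[i], eigs[j])
                if d < merge_height and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        groups[i] = groups[i] + groups[j]
        del groups[j]

    groups.sort(key=lambda gs: (-len(gs), gs[0]))
    assignments = {g: UNASSIGNED for g in ids}
    eigengenes: List[Eigengene] = []
    for mi, gs in enumerate(groups):
        label = f"M{mi+1}"
        for g in gs:
            assignments[g] = label
        eig = module_eigengene(expr, gs, label=label)
        eigengenes.append(eig)
    mset = ModuleSet(
        assignments=assignments,
        module_order=[f"M{i+1}" for i in range(len(groups))],
        params=_params(min_size, merge_height),
    )
    return mset, eigengenes


def _params(min_size: int, merge_height: float, beta: Optional[int] = None) -> Dict[str, object]:
    out: Dict[str, object] = {"min_size": int(min_size), "merge_height": float(merge_height)}
    if beta is not None:
        out["beta"] = int(beta)
    return out


class ModuleDetector(ClusterMixin, BaseEstimator):
    """Co-expression module detection as a scikit-learn clusterer.

    Builds an unsigned weighted network from biweight midcorrelations,
    selects (or accepts) a soft threshold, computes topological overlap, and
    clusters 1 - TOM by average linkage with a static cut and eigengene
    merging.

    Parameters
    ----------
    beta : int or None
        Soft threshold; ``None`` selects it from ``candidate_betas`` by the
        scale-free topology criterion.
    candidate_betas : sequence of int
        Candidates for automatic soft-threshold selection.
    r2_cut : float
        Minimum scale-free fit R^2 for a beta to qualify.
    min_size : int
        Smallest cluster kept as a module.
    cut_quantile : float
        Quantile of the dendrogram merge heights at which the tree is cut;
        the default 0.5 sits between the within-module merges (low) and the
        background merges (near 1).
    merge_height : float
        Eigengene dissimilarity below which two modules are merged.

    Attributes
    ----------
    labels_ : ndarray of str, shape (n_features,)
        Module label per gene (column of the fitted matrix).
    modules_ : ModuleSet
    eigengenes_ : list of Eigengene
    beta_ : int
        The soft threshold actually used.
    soft_threshold_diagnostics_ : pd.DataFrame
    """

    def __init__(
        self,
        beta: Optional[int] = None,
        candidate_betas: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
        r2_cut: float = 0.8,
        min_size: int = 30,
        cut_quantile: float = 0.5,
        merge_height: float = 0.25,
    ) -> None:
        self.beta = beta
        self.candidate_betas = candidate_betas
        self.r2_cut = r2_cut
        self.min_size = min_size
        self.cut_quantile = cut_quantile
        self.merge_height = merge_height

    def fit(self, X, y=None):
        """Fit on samples x genes data (or an ExpressionMatrix)."""
        expr = self._as_expression(X)
        corr = bicor_matrix(expr)
        if self.beta is None:
            beta, diag = pick_soft_threshold(corr, self.candidate_betas, self.r2_cut)
        else:
            beta, diag = int(self.beta), pd.DataFrame()
        A = np.abs(corr.values) ** beta
        np.fill_diagonal(A, 0.0)
        tom = tom_similarity(A)
        mset, eigs = detect_modules(
            tom,
            min_size=self.min_size,
            cut_quantile=self.cut_quantile,
            merge_height=self.merge_height,
            expr=expr,
        )
        mset.params["beta"] = beta
        self.beta_ = beta
        self.soft_threshold_diagnostics_ = diag
        self.modules_ = mset
        self.eigengenes_ = eigs
        self.gene_ids_ = expr.gene_ids
        self.labels_ = np.array([mset.assignments[g] for g in expr.gene_ids])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @staticmethod
    def _as_expression(X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            # samples x genes, sklearn orientation -> transpose to genes x samples
            return ExpressionMatrix(X.T, unit="log2")
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(
            X.T,
            index=[f"g{i+1}" for i in range(X.shape[1])],
            columns=[f"s{j+1}" for j in range(X.shape[0])],
        )
        return ExpressionMatrix(df, unit="log2")
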