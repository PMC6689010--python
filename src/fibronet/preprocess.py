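"""Expression and phenotype preprocessing preceding network analysis.

Covers low-expression filtering (FPKM > 1 in at least 5% of samples),
zero-replacement + log2 transform, covariate residualization, dendrogram
outlier-sample removal (99th-percentile height cut), and trait adjustment
(rank-based inverse-normal transform followed by covariate residualization).
"""

from __future__ import annotations

import math
import warnings
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm, rankdata

from .containers import ExpressionMatrix, PhenotypeTable


def filter_low_expression(
    expr: ExpressionMatrix, threshold: float = 1.0, min_frac: float = 0.05
) -> ExpressionMatrix:
    """Keep genes exceeding ``threshold`` in at least ``min_frac`` of samples.

    The required sample count is ``max(1, ceil(min_frac * n_samples))``; with
    30 samples and the 5% default this is 2 samples.
    """
    if expr.unit != "fpkm":
        raise ValueError("filtering applies to FPKM-unit matrices")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    required = max(1, math.ceil(min_frac * expr.n_samples))
    counts = (expr.values.to_numpy() > threshold).sum(axis=1)
    keep = counts >= required
    if not keep.any():
        warnings.warn("no gene passed the expression filter")
    return ExpressionMatrix(expr.values.loc[keep], unit="fpkm")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace zeros by the minimum positive value, then log2."""
    if expr.unit != "fpkm":
        raise ValueError("log transform applies to FPKM-unit matrices")
    vals = expr.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative values are not valid FPKM")
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("all-zero matrix: no positive minimum exists")
    floor = positive.min()
    out = np.where(vals == 0, floor, vals)
    return ExpressionMatrix(
        pd.DataFrame(np.log2(out), index=expr.values.index, columns=expr.values.columns),
        unit="log2",
    )


def _design_matrix(
    covariates: PhenotypeTable, columns: Sequence[str], samples: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    """Intercept + named covariates; categoricals become indicator contrasts."""
    data = covariates.data.loc[list(samples)]
    parts = [pd.Series(1.0, index=data.index, name="intercept")]
    for c in columns:
        if c not in data.columns:
            raise ValueError(f"covariate {c!r} not in phenotype table")
        col = data[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.extend(dummies[c2] for c2 in dummies.columns)
    design = pd.concat(parts, axis=1)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, _, piv = scipy.linalg.qr(X, pivoting=True)
        bad = [design.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, list(design.columns)


def residualize(
    expr: ExpressionMatrix, covariates: PhenotypeTable, columns: Sequence[str]
) -> ExpressionMatrix:
    """Replace each gene by OLS residuals against intercept + covariates."""
    missing = [s for s in expr.sample_ids if s not in covariates.data.index]
    if missing:
        raise ValueError(f"samples without covariates: {missing[:10]}")
    X, _ = _design_matrix(covariates, columns, expr.sample_ids)
    Y = expr.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return ExpressionMatrix(
        pd.DataFrame(resid.T, index=expr.values.index, columns=expr.values.columns),
        unit="residual",
    )


def remove_outlier_samples(
    expr: ExpressionMatrix, height_quantile: float = 0.99
) -> Tuple[ExpressionMatrix, List[str]]:
    """Drop samples outside the largest cluster after a static dendrogram cut.

    Samples are clustered by average linkage on Euclidean distance of their
    expression profiles; the tree is cut at the ``height_quantile`` of its
    merge heights and everything outside the single largest cluster is
    removed.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if not 0 < height_quantile < 1:
        raise ValueError("height_quantile must be in (0, 1)")
    profiles = expr.values.to_numpy(dtype=float).T  # samples x genes
    Z = linkage(pdist(profiles, metric="euclidean"), method="average")
    cut = float(np.quantile(Z[:, 2], height_quantile))
    labels = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    if (sizes == 1).all():
        raise ValueError("pathological tree: every sample is a singleton cluster")
    largest = sizes.idxmax()
    keep_mask = labels == largest
    removed = [s for s, k in zip(expr.sample_ids, keep_mask) if not k]
    kept = expr.values.loc[:, keep_mask]
    return ExpressionMatrix(kept, unit=expr.unit), removed


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with offset (rank - 0.5)/n.

    Ties receive average ranks.
    """
    values = np.asarray(values, dtype=float)
    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - 0.5) / len(values))


def adjust_trait_for_covariate(
    pheno: PhenotypeTable, trait: str, covariate: str
) -> PhenotypeTable:
    """Normal-transform a trait, then residualize it on a covariate.

    The trait column is replaced by the rank-based inverse-normal transform
    of its values followed by OLS residuals against intercept + covariate;
    the result is mean-zero and orthogonal to the covariate.
    """
    for c in (trait, covariate):
        if c not in pheno.data.columns:
            raise ValueError(f"column {c!r} not in phenotype table")
        if not pd.api.types.is_numeric_dtype(pheno.data[c]):
            raise ValueError(f"column {c!r} must be numeric")
    t = pheno.data[trait].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError(f"trait {trait!r} is constant")
    z = inverse_normal_transform(t)
    cov = pheno.data[covariate].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(cov), cov])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    data = pheno.data.copy()
    data[trait] = resid
    return PhenotypeTable(data, trait_cols=list(pheno.trait_cols), covariate_cols=list(pheno.covariate_cols))
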