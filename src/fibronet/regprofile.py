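"""Profile a candidate regulator gene against a module.

Per-cohort Spearman correlation of the regulator with every module gene
(BH FDR across the module's genes), a Mann-Whitney shift test between the
case and control correlation distributions, and extraction of the core set
of genes consistently significant across patient cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


@dataclass
class RegulatorProfile:
    """Per-gene Spearman rho / P / FDR of a regulator within one cohort."""

    regulator: str
    table: pd.DataFrame  # index gene, columns: spearman_rho, p, fdr


def regulator_correlations(
    expr: ExpressionMatrix, regulator: str, module_genes: Sequence[str]
) -> RegulatorProfile:
    """Spearman profile of the regulator against the module genes.

    P values use the Student t approximation; the FDR is BH across the
    module genes only (matching a correction denominator equal to the
    module size). The regulator itself is excluded from the target list.
    """
    if regulator not in expr.values.index:
        raise ValueError(f"regulator {regulator!r} not in expression matrix")
    targets = [g for g in module_genes if g != regulator]
    missing = [g for g in targets if g not in expr.values.index]
    if missing:
        raise ValueError(f"module genes missing: {missing[:10]}")
    reg = expr.values.loc[regulator].to_numpy(dtype=float)
    if np.ptp(reg) == 0:
        raise ValueError("constant regulator expression")
    n = expr.n_samples

    X = expr.values.loc[targets].to_numpy(dtype=float)
    rx = np.apply_along_axis(rankdata, 1, X)
    ry = rankdata(reg)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum(axis=1)) * np.sqrt((ryc**2).sum())
    safe = np.where(denom == 0, 1.0, denom)
    rho = np.clip(rxc @ ryc / safe, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tt = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(tt), df=n - 2)
    p[denom == 0] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"spearman_rho": rho, "p": p, "fdr": fdr}, index=pd.Index(targets, name="gene")
    )
    return RegulatorProfile(regulator=regulator, table=table)


def shift_test(
    profile_cases: RegulatorProfile, profile_controls: RegulatorProfile
) -> Tuple[float, int]:
    """Two-sided Mann-Whitney U on the two rho distributions.

    Returns (P, direction) with direction the sign of the median difference
    cases - controls.
    """
    a = profile_cases.table["spearman_rho"]
    b = profile_controls.table["spearman_rho"]
    if set(a.index) != set(b.index):
        raise ValueError("profiles must share the same gene universe")
    if len(a) < 3:
        raise ValueError("need at least 3 genes")
    _, p = mannwhitneyu(a.to_numpy(), b.to_numpy(), alternative="two-sided")
    direction = int(np.sign(a.median() - b.median()))
    return float(p), direction


def core_set(
    profiles: Dict[str, RegulatorProfile],
    fdr_threshold: float = 0.01,
    require_positive: bool = True,
) -> List[str]:
    """Genes significant (and optionally positive) in every cohort.

    Returns genes with FDR < threshold in all supplied cohorts, sorted by
    mean rho descending; an empty intersection is an empty list, not an
    error.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 cohorts")
    tables = list(profiles.values())
    genes = set(tables[0].table.index)
    for prof in tables[1:]:
        genes &= set(prof.table.index)
    selected = []
    for g in genes:
        ok = all(prof.table.loc[g, "fdr"] < fdr_threshold for prof in tables)
        if ok and require_positive:
            ok = all(prof.table.loc[g, "spearman_rho"] > 0 for prof in tables)
        if ok:
            selected.append(g)
    mean_rho = {
        g: float(np.mean([prof.table.loc[g, "spearman_rho"] for prof in tables]))
        for g in selected
    }
    return sorted(selected, key=lambda g: (-mean_rho[g], g))
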