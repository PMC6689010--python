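"""Shared fixtures: small planted datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from fibronet.containers import ExpressionMatrix
from fibronet.syndata import (
    generate_case_control,
    generate_genotypes,
    generate_panel_expression,
)


@pytest.fixture(scope="session")
def ri_panel():
    """30-strain RI-like panel: genotypes + expression with a planted hotspot."""
    geno = generate_genotypes(n_strains=30, n_blocks=100, snps_per_block=2, seed=0)
    expr, truth = generate_panel_expression(
        geno, n_genes=200, module_sizes=[50], hotspot_spec=("block7", 3.0),
        noise_sd=0.5, seed=0,
    )
    return geno, expr, truth


@pytest.fixture(scope="session")
def case_control():
    """100+100-sample cohorts with a 40-gene module at rho 0.8 vs 0.0."""
    return generate_case_control(
        n_cases=100, n_controls=100, module_sizes=[40], corr_cases=0.8,
        corr_controls=0.0, n_background=160, seed=21,
    )


@pytest.fixture
def tiny_expression():
    """Deterministic 6-gene x 12-sample matrix."""
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        rng.standard_normal((6, 12)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(12)],
    )
    return ExpressionMatrix(df, unit="log2")
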