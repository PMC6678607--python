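import numpy as np
import pandas as pd
import pytest

from tnbc_immune.cohort_io import ExpressionMatrix
from tnbc_immune.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture
def tiny_expr():
    """3 genes x 2 samples, hand-enterable values."""
    df = pd.DataFrame(
        [[8.0, 6.0], [6.0, 7.0], [5.0, 9.0]],
        index=["GZMA", "PRF1", "CD8A"],
        columns=["S1", "S2"],
    )
    return ExpressionMatrix(df, scale_tag="log2")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (fixed seed)."""
    return simulate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_panel(default_cohort):
    from tnbc_immune.signatures import compute_panel

    return compute_panel(default_cohort.expression)


def random_expression(rng, n_genes, n_samples, ties=False):
    """Random log2-scale matrix; with ties values come from a small grid."""
    if ties:
        vals = rng.choice(np.arange(4.0, 9.0, 0.5), size=(n_genes, n_samples))
    else:
        vals = rng.normal(6.0, 1.5, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )
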