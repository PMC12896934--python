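import numpy as np
import pandas as pd
import pytest

from hetex import (ExpressionMatrix, SimConfig, filter_expressed,
                   normalize_fpkm, simulate_expression)


def make_expr(values: dict[str, list[float]], genes: list[str], scale: str = "abundance"):
    """Build a small ExpressionMatrix; group inferred from column prefix."""
    df = pd.DataFrame(values, index=genes)
    groups = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return ExpressionMatrix(df, groups, scale)


@pytest.fixture
def toy_expr():
    """3 genes x 6 samples (2 per group), abundance scale, exact values."""
    return make_expr(
        {
            "parentA_1": [10.0, 100.0, 5.0],
            "parentA_2": [10.0, 100.0, 5.0],
            "parentB_1": [20.0, 50.0, 5.0],
            "parentB_2": [20.0, 50.0, 5.0],
            "hybrid_1": [18.0, 75.0, 5.0],
            "hybrid_2": [18.0, 75.0, 5.0],
        },
        ["g1", "g2", "g3"],
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Session-wide 2,000-gene simulation with its truth table."""
    counts, truth = simulate_expression(SimConfig(n_genes=2000, seed=1))
    return counts, truth


@pytest.fixture(scope="session")
def sim_expressed(sim_dataset):
    counts, _ = sim_dataset
    return filter_expressed(normalize_fpkm(counts, library_size="median_ratio"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
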