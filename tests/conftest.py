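import numpy as np
import pandas as pd
import pytest

import budphase as bp


@pytest.fixture(scope="session")
def small_counts():
    """4 genes x 6 samples with hand-checkable filter behaviour."""
    values = pd.DataFrame(
        {
            "s1": [10, 0, 5, 0],
            "s2": [12, 0, 5, 0],
            "s3": [8, 0, 5, 0],
            "s4": [40, 12, 5, 0],
            "s5": [25, 0, 5, 1],
            "s6": [30, 0, 5, 0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    lengths = pd.Series([1000, 2000, 500, 1500],
                        index=values.index, name="length_bp")
    return bp.ExpressionMatrix(values, unit="count", gene_lengths=lengths)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by the slower tests."""
    return bp.simulate_dataset(bp.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline run on the default synthetic dataset (seed 11)."""
    result, dataset = bp.run_synthetic_pipeline(
        bp.SimulationConfig(seed=11), n_splits=8)
    return result, dataset


def random_counts(rng, n_genes=20, n_samples=8):
    values = pd.DataFrame(
        rng.integers(0, 200, size=(n_genes, n_samples)).astype(float),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)])
    lengths = pd.Series(rng.integers(300, 4000, n_genes), index=values.index)
    return bp.ExpressionMatrix(values, unit="count", gene_lengths=lengths)
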