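import numpy as np
import pandas as pd
import pytest

from tics import ExpressionMatrix, GeneratorConfig, SurvivalTable, generate_dataset


def make_survival(times, events, prefix="s") -> SurvivalTable:
    return SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": [f"{prefix}{i}" for i in range(len(times))],
                "time": np.asarray(times, dtype=float),
                "event": np.asarray(events, dtype=int),
            }
        )
    )


def make_expression(values, genes=None, samples=None, scale="log2") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down recovery scenario for fast integration tests."""
    return GeneratorConfig(
        n_cohorts=3,
        samples_per_cohort=80,
        n_genes=200,
        genes_per_cell=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
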