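import numpy as np
import pandas as pd
import pytest

from ovimmune.harmonize import ExpressionMatrix
from ovimmune.synthdata import SimulationConfig, simulate_all


def make_matrix(values: np.ndarray, phenotypes, cohorts=None, preservations=None,
                genes=None, samples=None) -> ExpressionMatrix:
    """Hand-build a small ExpressionMatrix for unit tests."""
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "cohort": cohorts or ["c0"] * n_samples,
            "preservation": preservations or ["FF"] * n_samples,
            "phenotype": list(phenotypes),
        },
        index=samples,
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=400,
        n_chromosomes=3,
        samples_per_cohort=12,
        n_control_cohorts=4,
        n_de_genes=40,
        n_ffpe_genes=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_all(small_config)
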