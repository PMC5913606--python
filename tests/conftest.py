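import numpy as np
import pandas as pd
import pytest

from longewas.config import AnalysisConfig
from longewas.datamodel import LongitudinalDataset
from longewas.simulate import SimulationConfig, simulate_dataset


def make_dataset(
    n_individuals: int = 2,
    ages=(10.0, 12.0),
    beta=None,
    exposure=None,
    rng=None,
    n_cpgs: int = 2,
) -> LongitudinalDataset:
    """Small hand-built balanced dataset for unit tests."""
    m, r = n_individuals, len(ages)
    if exposure is None:
        exposure = np.arange(m) % 2
    samples = pd.DataFrame(
        {
            "observation_id": [f"id{j}_t{k}" for j in range(m) for k in range(r)],
            "individual_id": np.repeat([f"id{j}" for j in range(m)], r),
            "age": np.tile(np.asarray(ages, dtype=float), m),
            "exposure": np.repeat(np.asarray(exposure, dtype=float), r),
        }
    )
    if beta is None:
        rng = rng or np.random.default_rng(0)
        beta = rng.uniform(0.2, 0.8, size=(n_cpgs, m * r))
    beta = np.atleast_2d(beta)
    cpg_ids = [f"cpg{i:04d}" for i in range(beta.shape[0])]
    return LongitudinalDataset(cpg_ids=cpg_ids, beta=beta, samples=samples)


@pytest.fixture
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Reduced cohort for fast end-to-end tests."""
    return SimulationConfig(n_individuals=60, n_cpgs=12, seed=11)


@pytest.fixture(scope="session")
def small_replicate(small_sim_config):
    return simulate_dataset(small_sim_config, replicate_index=0)
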