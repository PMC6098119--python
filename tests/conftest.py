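import numpy as np
import pandas as pd
import pytest

from endfootnet import pipeline
from endfootnet import synthetic_data as synth


@pytest.fixture(scope="session")
def small_sim_config() -> synth.SimulationConfig:
    """A compact cohort: 300 genes, 4 modules, 80 subjects — fast enough for
    unit tests while keeping the planted structure intact."""
    return synth.SimulationConfig(
        seed=20260930,
        n_subjects=100,
        n_genes=300,
        n_modules=4,
        module_size_range=(40, 60),
        loading_range=(0.7, 0.95),
        n_low_expression_genes=30,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config) -> synth.Cohort:
    return synth.generate_cohort(small_sim_config)


@pytest.fixture(scope="session")
def small_run(small_sim_config) -> pipeline.RunResult:
    """Full pipeline result on the compact cohort (computed once per session)."""
    cfg = pipeline.RunConfig(seed=small_sim_config.seed, simulation=small_sim_config)
    return pipeline.run_full(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def expression_frame(rng) -> pd.DataFrame:
    genes = [f"g{i}" for i in range(50)]
    samples = [f"s{j}" for j in range(20)]
    return pd.DataFrame(
        rng.lognormal(3.0, 1.0, (50, 20)), index=genes, columns=samples
    )
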