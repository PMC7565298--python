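import numpy as np
import pytest

from smoltmir.pipeline import run_pipeline
from smoltmir.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-scale pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    summary = run_pipeline({"seed": 1}, out)
    return {"summary": summary, "dir": out}


@pytest.fixture(scope="session")
def small_dataset():
    """Small in-memory synthetic dataset for unit-level checks."""
    cfg = SimulationConfig(
        n_mirnas=24,
        n_genes=80,
        n_de_per_archetype=(5, 3, 5),
        n_anti_per_archetype=(5, 0, 8),
        n_planted_pairs=10,
        mean_count_range=(80.0, 300.0),
        rng_seed=42,
    )
    return simulate_all(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
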