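import pytest

from cofrac.pipeline import PipelineConfig, run_pipeline
from cofrac.synthetic_data import (
    SimulationConfig,
    generate_ground_truth,
    simulate_dataset,
)

#: study-scale dataset used by the classifier and end-to-end checks
DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    truth = generate_ground_truth(default_config)
    matrices = simulate_dataset(truth, default_config)
    return truth, matrices


@pytest.fixture(scope="session")
def small_config():
    """Reduced dataset for fast pipeline-level tests."""
    return SimulationConfig(
        n_complexes=15,
        n_monomers=40,
        experiments=(("SEC", 45), ("IEX", 30)),
        mean_total_counts=200.0,
        dropout_prob=0.1,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    truth = generate_ground_truth(small_config)
    matrices = simulate_dataset(truth, small_config)
    return truth, matrices


@pytest.fixture(scope="session")
def small_pipeline_config(small_config):
    return PipelineConfig(simulation=small_config, seed=small_config.seed)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_pipeline_config):
    out = tmp_path_factory.mktemp("small_run")
    summary = run_pipeline(small_pipeline_config, out)
    return small_pipeline_config, summary, out


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the study-scale dataset (shared across tests)."""
    out = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig.from_dict(
        {"seed": DEFAULT_SEED, "simulation": {"seed": DEFAULT_SEED}}
    )
    summary = run_pipeline(config, out)
    return config, summary, out


@pytest.fixture(scope="session")
def noise_free_sec():
    """Noise-free single-column SEC dataset for apex/Rapp round trips."""
    config = SimulationConfig(
        n_complexes=30,
        n_monomers=60,
        experiments=(("SEC", 45),),
        mean_total_counts=5000.0,
        dropout_prob=0.0,
        background_rate=0.0,
        seed=5,
    )
    truth = generate_ground_truth(config)
    matrices = simulate_dataset(truth, config)
    return config, truth, matrices[0]
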