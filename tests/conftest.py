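import pytest
from hypothesis import settings

from bilnc.pipeline import run_pipeline
from bilnc.synthetic_data import SimulationConfig, simulate_dataset, write_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The study-condition dataset (NB noise at the calibrated dispersion)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    data = tmp_path_factory.mktemp("data_default")
    out = tmp_path_factory.mktemp("out_default")
    write_dataset(default_sim, data)
    results = run_pipeline(data, out)
    return default_sim, results, out


@pytest.fixture(scope="session")
def noiseless_sim():
    """Same dataset with negligible count noise (near-exact correlations)."""
    return simulate_dataset(SimulationConfig(seed=11).noiseless())


@pytest.fixture(scope="session")
def noiseless_run(noiseless_sim, tmp_path_factory):
    data = tmp_path_factory.mktemp("data_noiseless")
    out = tmp_path_factory.mktemp("out_noiseless")
    write_dataset(noiseless_sim, data)
    results = run_pipeline(data, out)
    return noiseless_sim, results, out
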