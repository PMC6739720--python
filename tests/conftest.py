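import pytest

from lncsalt.core import PipelineConfig
from lncsalt.pipeline import simulate_dataset


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """The default synthetic two-species dataset (seed 7)."""
    d = tmp_path_factory.mktemp("simdata")
    truth = simulate_dataset(d, seed=7)
    return d, truth


@pytest.fixture(scope="session")
def sim_truth(sim_dir):
    return sim_dir[1]
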