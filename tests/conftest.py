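import numpy as np
import pytest

from conservomics.pipeline import PipelineInputs
from conservomics.synthetic_data import SimulationConfig, generate_fixture


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_genes_per_species=30,
        n_orthologs=24,
        n_conserved_epi=6,
        n_conserved_fiber=6,
        chrom_length=800_000,
        n_ns_peaks=10,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return generate_fixture(small_config)


@pytest.fixture(scope="session")
def default_fixture():
    """The noise-free planted fixture at seed 1, default parameters."""
    return generate_fixture(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_inputs(default_fixture):
    return PipelineInputs.from_fixture(default_fixture)


@pytest.fixture(scope="session")
def default_result(default_inputs):
    """Full pipeline result on the seed-1 fixture (analysis seed 1)."""
    from conservomics.pipeline import analyze

    return analyze(default_inputs, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
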