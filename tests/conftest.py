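import numpy as np
import pytest
from hypothesis import settings

from m6avar.synthetic_data import (
    SimulationConfig,
    generate_expression,
    generate_genome,
    generate_peaks,
    simulate,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_config():
    """Default study-scale configuration: 2000 genes, fixed seed."""
    return SimulationConfig(seed=STUDY_SEED, n_genes=2000)


@pytest.fixture(scope="session")
def study_data(study_config):
    """In-memory study-scale dataset: (models, seqs, expr, truth, peaksets)."""
    models, seqs = generate_genome(study_config)
    expr, truth = generate_expression(study_config, models)
    peaksets = generate_peaks(study_config, models, truth, seqs=seqs)
    return models, seqs, expr, truth, peaksets


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_genes=300)


@pytest.fixture(scope="session")
def small_data(small_config):
    models, seqs = generate_genome(small_config)
    expr, truth = generate_expression(small_config, models)
    peaksets = generate_peaks(small_config, models, truth, seqs=seqs)
    return models, seqs, expr, truth, peaksets


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_config):
    """An on-disk fixture directory written by simulate()."""
    outdir = tmp_path_factory.mktemp("fixture")
    simulate(small_config, outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
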