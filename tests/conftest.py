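import warnings

import numpy as np
import pytest

from ffpearray.normalization import estimate_frozen_parameters
from ffpearray.pipeline import build_descriptions
from ffpearray.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_reference_batches,
)


@pytest.fixture(scope="session")
def small_config():
    """A compact but fully featured study: every planted pathology present."""
    return SimulationConfig(
        n_genes=120,
        n_samples_per_subgroup=4,
        n_ambiguous_probes=4,
        n_background_probes=22,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def descriptions(small_dataset):
    return build_descriptions(small_dataset.probes, small_dataset.transcripts)


@pytest.fixture(scope="session")
def reference_batches(small_dataset):
    return simulate_reference_batches(small_dataset, n_batches=6, batch_size=4)


@pytest.fixture(scope="session")
def frozen_params_all(small_dataset, descriptions, reference_batches):
    return estimate_frozen_parameters(reference_batches, descriptions["refseq_all"])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
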