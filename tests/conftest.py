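import numpy as np
import pytest

from igdscreen import GeneratorConfig, generate_dataset
from igdscreen.screening import reconstruct_confusion_tables, scores_from_tables


@pytest.fixture(scope="session")
def default_dataset():
    """One study-sized dataset (N = 464) under the default generating model."""
    return generate_dataset(GeneratorConfig(n_persons=464, seed=7))


@pytest.fixture(scope="session")
def large_dataset():
    """A calibration-sized dataset (n = 5000) for sanity-band checks."""
    return generate_dataset(GeneratorConfig(n_persons=5000, seed=7))


@pytest.fixture(scope="session")
def published_tables():
    """The unique integer 2x2 tables behind the published cutoff rows."""
    return reconstruct_confusion_tables()


@pytest.fixture(scope="session")
def published_scan_data(published_tables):
    """Score/reference vectors whose scan reproduces the published tables."""
    return scores_from_tables(published_tables)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)
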