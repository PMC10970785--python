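import numpy as np
import pytest

from ambientms.preprocessing import prepare_dataset
from ambientms.simulate import SyntheticConfig, generate_dataset, scenario_preset


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 2-class dataset for unit-level model tests."""
    cfg = SyntheticConfig(n_classes=2, specimens_per_class=6,
                          events_per_specimen=8, scans_per_event=4,
                          n_bins=60, class_separation=6.0, specimen_sd=2.0,
                          event_sd=5.0, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    return prepare_dataset(small_dataset)


@pytest.fixture(scope="session")
def distinct_dataset():
    """The well-separated three-class study preset (session-cached)."""
    return generate_dataset(scenario_preset("distinct_classes", seed=11))


@pytest.fixture(scope="session")
def distinct_prepared(distinct_dataset):
    return prepare_dataset(distinct_dataset)


@pytest.fixture(scope="session")
def contaminated_dataset():
    return generate_dataset(scenario_preset("contaminated", seed=13))


@pytest.fixture(scope="session")
def contaminated_prepared(contaminated_dataset):
    return prepare_dataset(contaminated_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
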