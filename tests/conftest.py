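import warnings

import pytest

from pulmotransit.synthetic import CohortConfig, TransitPhantomConfig

# lifelines emits formatting/approximation warnings that are irrelevant here
warnings.filterwarnings("ignore", module="lifelines")


@pytest.fixture
def clean_config():
    """Noiseless, dispersion-free, recirculation-free phantom."""
    return TransitPhantomConfig(transit_dispersion=0.0, noise_sd=0.0,
                                recirc_fraction=0.0, seed=0)


@pytest.fixture
def realistic_config():
    """Default phantom: dispersion, recirculation and mild noise."""
    return TransitPhantomConfig(seed=0)


@pytest.fixture
def small_cohort_config():
    return CohortConfig(n_subjects=400, seed=0)
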