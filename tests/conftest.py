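import numpy as np
import pytest

from dropscreen import LibraryDesign, enumerate_library


@pytest.fixture(scope="session")
def design():
    return LibraryDesign()


@pytest.fixture(scope="session")
def library(design):
    """Full 8000-member triad library with FWL as the high-affinity binder."""
    return tuple(enumerate_library(design, {"FWL": 3.2}))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
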