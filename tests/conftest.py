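"""Shared fixtures: the standard synthetic study system and small helpers."""

import numpy as np
import pytest

from rootdepth import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def standard_world():
    """The package's standard synthetic community (canonical seed 0).

    12 canopy species, 25 years of daily forcing, 5-year censuses, a
    20-member hydrological ensemble, growth noise at 25% of signal SD.
    """
    return generate_world(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for cheap structural tests."""
    cfg = SyntheticConfig(
        n_species=4, n_years=20, n_realizations=2, seed=7,
        true_layer_indices=(5, 7, 9, 10),
    )
    return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
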