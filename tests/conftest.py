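import dataclasses

import numpy as np
import pytest

from submort.core import AdjacencyGraph
from submort.synthetic_data import SyntheticConfig, generate_truth


@pytest.fixture(scope="session")
def default_truth():
    """One draw from the default desk-scale fixture (8 provinces, 2005–2017)."""
    return generate_truth(SyntheticConfig())


@pytest.fixture(scope="session")
def flat_truth():
    """Noise-free fixture: rate surface exactly exp(3) = 20.09 everywhere."""
    cfg = SyntheticConfig(
        mean_coefs=(3.0, 0.0, 0.0, 0.0),
        spatial_sd=0.0,
        temporal_sd=0.0,
        interaction_sd=0.0,
        nmr_effect_sd=0.0,
        seed=7,
    )
    return generate_truth(cfg)


@pytest.fixture()
def ring4():
    return AdjacencyGraph(
        ["A", "B", "C", "D"], [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
    )


@pytest.fixture()
def small_config():
    return SyntheticConfig()


def pytest_configure(config):
    np.seterr(over="warn")


def replace_config(cfg: SyntheticConfig, **kw) -> SyntheticConfig:
    return dataclasses.replace(cfg, **kw)
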