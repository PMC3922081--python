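import warnings

import numpy as np
import pytest

from metalphylo.models import lg_model, poisson_model
from metalphylo.simulate import SimConfig, balanced_species_tree, simulate_family


@pytest.fixture(autouse=True)
def _quiet_saturation():
    # saturated-distance warnings are expected in deep-divergence fixtures
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*saturated.*")
        warnings.filterwarnings("ignore", message=".*shared columns.*")
        yield


@pytest.fixture(scope="session")
def lg():
    return lg_model(gamma_shape=1.0)


@pytest.fixture(scope="session")
def lg_plain():
    return lg_model()


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_family():
    """Two-subfamily family on 4 species, modest divergence, no dup/loss."""
    cfg = SimConfig(species_tree=balanced_species_tree(4, 0.2),
                    motif_spec={"IB-2": "CPC", "IB-4": "SPC"},
                    root_sequence_length=200, motif_anchor=100,
                    subfamily_tree="(IB-2:0.35,IB-4:0.35);", seed=42)
    records, truth = simulate_family(cfg)
    return cfg, records, truth
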