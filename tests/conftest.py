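"""Shared fixtures: simulated panels and standard sets are built once per session."""

import numpy as np
import pytest

from voltscreen.peak_library import get_profile, sc_ids
from voltscreen.preprocess import preprocess_trace
from voltscreen.chemometrics import build_matrix
from voltscreen.simulate import SimulationParams, make_fixture_46, simulate_voltammogram

SEED = 1  # top-level seed for every simulated fixture in the suite


@pytest.fixture(scope="session")
def noise_free_params():
    return SimulationParams(noise_sd_fraction=0.0, potential_jitter_sd=0.0)


@pytest.fixture(scope="session")
def panel46():
    """Seized-panel fixture at default (2% noise) conditions."""
    return make_fixture_46(seed=SEED)


@pytest.fixture(scope="session")
def standards_matrix():
    """Preprocessed 15-standard x 3-replicate feature matrix, default noise."""
    pairs = []
    for a_idx, analyte in enumerate(sc_ids()):
        for rep in range(3):
            anodic = simulate_voltammogram(
                [(analyte, 100.0)], "anodic", seed=[SEED, a_idx, rep, 0]
            )
            cathodic = simulate_voltammogram(
                [(analyte, 100.0)], "cathodic", seed=[SEED, a_idx, rep, 1]
            )
            pairs.append(
                (
                    preprocess_trace(anodic, normalized=True),
                    preprocess_trace(cathodic, normalized=True),
                    (analyte, get_profile(analyte).group, rep),
                )
            )
    return build_matrix(pairs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
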