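import numpy as np
import pytest

from chromaglint.design import (
    HUES,
    RELIEFS,
    ROUGHNESS_PC,
    SLANTS,
    build_matching_grid,
    enumerate_conditions,
)
from chromaglint.observers import ObserverParams, simulate_latent_cues


@pytest.fixture(scope="session")
def red_grid_clip():
    """The full-size 22 x 22 matching grid at the red hue, clip-tolerant."""
    return build_matching_grid(HUES[0], validate_gamut="clip")


@pytest.fixture(scope="session")
def small_grid():
    """A fully displayable strict-mode grid (sub-range of the full lattice)."""
    return build_matching_grid(HUES[0], 37.5, 67.5, 22.5, 45.0, 3.75)


@pytest.fixture(scope="session")
def pc_block():
    """One paired-comparison block: 16 relief x roughness conditions."""
    return enumerate_conditions([HUES[0]], RELIEFS, ROUGHNESS_PC, [15.0])


@pytest.fixture(scope="session")
def default_cues():
    """Latent cue surfaces over the full paired-comparison design."""
    conds = enumerate_conditions(HUES, RELIEFS, ROUGHNESS_PC, SLANTS)
    return simulate_latent_cues(ObserverParams(), conds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
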