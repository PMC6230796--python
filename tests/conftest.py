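import numpy as np
import pytest

from contrastgain.stimgen import (
    LevelDistributionSpec,
    draw_chord_levels,
    make_tone_grid,
)
from contrastgain.strf import build_design_tensor


@pytest.fixture(scope="session")
def grid():
    """Standard 1-64 kHz quarter-octave tone grid (25 frequencies)."""
    return make_tone_grid(1000.0, 64000.0, 0.25)


@pytest.fixture(scope="session")
def drc_pair(grid):
    """One low- and one high-contrast DRC (full 1600-chord sequences)."""
    low = draw_chord_levels(LevelDistributionSpec(80.0, 20.0), 1600, grid,
                            seed=11, condition_label="low")
    high = draw_chord_levels(LevelDistributionSpec(80.0, 40.0), 1600, grid,
                             seed=12, condition_label="high")
    return low, high


@pytest.fixture(scope="session")
def design_pair(drc_pair):
    low, high = drc_pair
    return build_design_tensor(low.levels), build_design_tensor(high.levels)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
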