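"""Shared fixtures.

The desk-scale screen (all retained topologies x 7 Latin-hypercube draws,
>= 1e5 circuits) is expensive, so it is computed once per session and shared
by the acceptance tests that consume it.
"""

import warnings

import pytest

from enzscale.screen import ScreenConfig, full_screen

DESK_SEED = 1
DESK_DRAWS = 7  # 16,038 retained topologies x 7 draws = 112,266 circuits


@pytest.fixture(scope="session")
def desk_screen():
    """Scaled-down adaptation/ASI screen over every retained topology."""
    warnings.filterwarnings("ignore", message="Excess work")
    cfg = ScreenConfig(seed=DESK_SEED, n_params=DESK_DRAWS)
    df, summary = full_screen(cfg)
    return cfg, df, summary


@pytest.fixture(scope="session")
def screen_cfg():
    return ScreenConfig(seed=DESK_SEED)
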