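import numpy as np
import pytest

from choicersf import (
    DesignCoding,
    LandscapeConfig,
    MovementConfig,
    generate_landscape,
    simulate_track,
)


@pytest.fixture(scope="session")
def small_grids():
    """32x32 landscape, 3 continuous layers, 8 habitat classes, 30 m cells."""
    cfg = LandscapeConfig(n_rows=32, n_cols=32, n_continuous=3, smoothing_range=2.0)
    return generate_landscape(cfg, seed=101)


@pytest.fixture(scope="session")
def small_coding(small_grids):
    return DesignCoding.from_grids(small_grids)


@pytest.fixture(scope="session")
def short_track(small_grids, small_coding):
    beta = np.zeros(small_coding.n_columns)
    beta[0] = 1.0
    return simulate_track(
        small_grids,
        beta,
        MovementConfig(step_radius=250.0, n_candidates=20),
        n_fixes=120,
        start=(480.0, 480.0),
        seed=7,
        individual_id="elk00",
    )
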