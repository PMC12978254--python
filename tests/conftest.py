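import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tissue():
    """A compact tissue with a macrophage-enriched hotspot."""
    from cinmn.simulate import TissueSimConfig, make_tissue

    cfg = TissueSimConfig(
        n_tumor_cells=1200,
        n_stromal_cells=900,
        n_hotspots=2,
        mn_rate_background=0.03,
        mn_rate_hotspot=0.20,
        hotspot_multiplier={"macrophage": 3.0},
        seed=7,
    )
    return make_tissue(cfg)


@pytest.fixture
def toy_cells():
    """Hand-built segmented-cell table covering all compartments."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "x": [0.0, 1, 2, 3, 4, 5],
            "y": [0.0, 0, 0, 0, 0, 0],
            "compartment": ["tumor", "tumor", "tumor", "stroma", "stroma", "artifact"],
            "cell_type": ["tumor", "tumor", "tumor", "T_cell", "macrophage", "artifact"],
            "cgas": [10.0, 4, 6, 3, 5, 1],
            "af": [2.0, 2, 2, 1, 1, 1],
        }
    )
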