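import pandas as pd
import pytest

from tilescreen.simulate import (
    make_panel_library,
    make_screen_truth,
    make_tiling_library,
    simulate_counts,
    simulate_tiling_truth,
)


@pytest.fixture(scope="session")
def panel_library():
    """Focused-screen fixture: 36 genes x 25 guides + 41 neg + 22 pos."""
    return make_panel_library(seed=11)


@pytest.fixture(scope="session")
def tiling_library():
    """Tiling fixture: 416 guides over a fabricated CDS + 40 neg + 22 pos."""
    lib, cds = make_tiling_library(seed=11)
    return lib, cds


@pytest.fixture(scope="session")
def panel_screen(panel_library):
    """One simulated focused screen with a single essential gene."""
    truth = make_screen_truth(panel_library, {"GENE05": -0.5}, seed=23)
    counts, truth_freq = simulate_counts(panel_library, truth)
    return counts, truth_freq, truth


@pytest.fixture(scope="session")
def tiling_screen(tiling_library):
    """One simulated tiling screen with an essential N-terminal block."""
    lib, cds = tiling_library
    protein_length = len(cds) // 3
    features = pd.DataFrame(
        {
            "label": ["essential_block", "neutral_tail"],
            "start_res": [50, 700],
            "end_res": [400, protein_length],
            "effect": [-1.0, 0.0],
        }
    )
    effects = simulate_tiling_truth(lib, protein_length, features, noise_sd=0.05, seed=23)
    truth = make_screen_truth(lib, tiling_effects=effects, seed=23)
    counts, truth_freq = simulate_counts(lib, truth)
    return lib, counts, features, protein_length
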