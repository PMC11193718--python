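import numpy as np
import pandas as pd
import pytest

import breakbalance as bb
from breakbalance.effect_screen import screen_balance


def run_screen(truth):
    """Simulate a screen and push it through quantification and delta scoring."""
    counts, samples = bb.sim_screen(truth)
    merged = screen_balance(counts, samples)
    return bb.delta_scores(merged, truth.mock_ids)


@pytest.fixture(scope="session")
def small_truth():
    """A small screen with one planted global effect and one planted synergy."""
    return bb.make_screen_truth(
        n_proteins=30,
        n_mock=12,
        n_ipr=19,
        seed=11,
        global_effects={"P001": -1.0, "P002": 0.8},
        synergies={"P003": {"LMNB1": -0.8}, "P004": {"H3K4me3": 0.8}},
    )


@pytest.fixture(scope="session")
def small_screen(small_truth):
    return run_screen(small_truth)


@pytest.fixture(scope="session")
def small_ccd(small_truth, small_screen):
    return bb.ccd_test(small_screen, small_truth.chromatin)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def lad_index():
    intervals = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "start": [0, 1000, 2000, 3000],
            "end": [1000, 2000, 3000, 4000],
            "label": ["cLAD", "ciLAD", "cLAD", "ciLAD"],
        }
    )
    return bb.LadIndex(intervals)
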