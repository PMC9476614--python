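import numpy as np
import pandas as pd
import pytest

from duetibs import SimParams, make_design, simulate_keystrokes


@pytest.fixture(scope="session")
def small_design():
    """2 pairs x 2 trials/cell randomized schedule."""
    return make_design(2, 2, seed=11)


@pytest.fixture(scope="session")
def quiet_params():
    """Deterministic timing: no noise, no bias, no adaptation."""
    return SimParams(motor_noise_sigma=0.0, anticipation_bias=0.0,
                     adaptation_gain=0.0, rng_seed=5)


@pytest.fixture(scope="session")
def quiet_trial(small_design, quiet_params):
    """One noise-free trial's two keystroke streams plus its design row."""
    row = small_design.iloc[0]
    s1, s2 = simulate_keystrokes(row, quiet_params)
    return s1, s2, row


def make_streams(onsets1, onsets2, phrase=1, pitch=60, piece="A"):
    """Hand-built keystroke streams at consecutive positions."""
    frames = []
    for player, onsets in ((1, onsets1), (2, onsets2)):
        frames.append(pd.DataFrame({
            "player": player, "trial": 1, "phrase": phrase,
            "position": np.arange(1, len(onsets) + 1),
            "onset_s": np.asarray(onsets, float),
            "pitch": pitch, "piece": piece,
        }))
    return frames[0], frames[1]
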