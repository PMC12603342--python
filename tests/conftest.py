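import numpy as np
import pandas as pd
import pytest

from odorwords import rates, stimuli, synthetic


@pytest.fixture(scope="session")
def word_list() -> stimuli.WordList:
    return stimuli.default_word_list()


@pytest.fixture(scope="session")
def first_presentation_trials(word_list) -> pd.DataFrame:
    """200 first-presentation trials (100 odor, 100 control) of a standard run."""
    seq = stimuli.make_trial_sequence(word_list, 100, 100, seed=11)
    return seq[seq["presentation"] == 1].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_session() -> synthetic.SimulatedSession:
    """A reduced session (3 units per region, 30 once / 30 twice) for fast tests."""
    cfg = synthetic.SyntheticConfig(
        units_per_region={r: 3 for r in synthetic.REGIONS},
        n_once=30,
        n_twice=30,
        seed=5,
    )
    return synthetic.simulate_session(cfg)


@pytest.fixture(scope="session")
def default_session() -> synthetic.SimulatedSession:
    """A full default-condition session (195 units, 300 trials)."""
    return synthetic.simulate_session(synthetic.SyntheticConfig(seed=3))


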