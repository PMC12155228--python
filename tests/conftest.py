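import numpy as np
import pytest

from ethophys import synth
from ethophys.core import ArenaGeometry


@pytest.fixture(scope="session")
def arena():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def behavior_session():
    """One small simulated session shared by feature/state tests."""
    cfg = synth.BehaviorSimConfig(
        n_trials=6, iti_range_s=(22.0, 26.0), seed=11, trial_attend_p=0.5
    )
    track, trials, states, attend = synth.gen_behavior_session(cfg)
    return cfg, track, trials, states, attend


@pytest.fixture(scope="session")
def calcium_population():
    """Two-archetype multi-animal population with truth labels."""
    cfg = synth.CalciumSimConfig(
        n_animals=3, neurons_per_animal=30, seed=21,
        archetypes={"exc": {"Attending": 2.0, "pinprick": 2.0},
                    "inh": {"Attending": -2.0}},
        proportions=(0.5, 0.5),
    )
    sessions, truth = synth.gen_calcium_population(cfg)
    return cfg, sessions, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
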