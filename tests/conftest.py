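import numpy as np
import pytest

from pupilrl.envs import Session, Trial


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_session(choices, outcomes, task="matching_pennies", computer=None):
    """Build a Session from parallel choice/outcome sequences."""
    trials = []
    for i, (c, r) in enumerate(zip(choices, outcomes), start=1):
        cc = computer[i - 1] if computer is not None else None
        trials.append(Trial(index=i, choice=c, outcome=int(r), computer_choice=cc))
    return Session(trials, task=task)


def random_session(n, rng, p_left=0.5, p_reward=0.5):
    choices = ["L" if rng.random() < p_left else "R" for _ in range(n)]
    outcomes = [int(rng.random() < p_reward) for _ in range(n)]
    return make_session(choices, outcomes)


@pytest.fixture
def session_factory():
    return make_session


@pytest.fixture
def random_session_factory():
    return random_session
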