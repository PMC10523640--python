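import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


class FixedAcceptAgent:
    """Accepts odor o with fixed probability p[o]; no learning."""

    def __init__(self, p_accept):
        self.p = list(p_accept)

    def encounter(self, odor_id, rng):
        return bool(rng.random() < self.p[odor_id])

    def observe_choice(self, odor_id, reward):
        pass


class AlwaysAcceptAgent(FixedAcceptAgent):
    def __init__(self):
        super().__init__([1.0, 1.0])


class AlwaysRejectAgent(FixedAcceptAgent):
    def __init__(self):
        super().__init__([0.0, 0.0])


class RandomChoiceAgent:
    """Memoryless 50/50 direct chooser."""

    def choose(self, rng):
        return int(rng.integers(2))

    def observe_choice(self, odor_id, reward):
        pass


class WSLSAgent:
    """Literal win-stay/lose-switch direct chooser."""

    def __init__(self):
        self.last = None
        self.last_reward = None

    def choose(self, rng):
        if self.last is None:
            return int(rng.integers(2))
        return self.last if self.last_reward else 1 - self.last

    def observe_choice(self, odor_id, reward):
        self.last = odor_id
        self.last_reward = bool(reward)


class RepeatLastAgent:
    """Always repeats its previous choice (first uniform)."""

    def __init__(self):
        self.last = None

    def choose(self, rng):
        if self.last is None:
            return int(rng.integers(2))
        return self.last

    def observe_choice(self, odor_id, reward):
        self.last = odor_id


def alternation_choice_probability(a: float, b: float) -> float:
    """Closed-form P(choice = A) for the alternating encounter loop.

    First encounter uniform; acceptance probabilities a (odor A) and b
    (odor B); rejection leads to the other odor.
    """
    return 0.5 * (a + (1 - b) * a) / (1 - (1 - a) * (1 - b))


@pytest.fixture
def fixed_accept_agent():
    return FixedAcceptAgent


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
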