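import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from capnoseq.states import STATE_ALPHABET, StateSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_sequence(rng, pid, length=None, missing_rate=0.0):
    """A sequence of i.i.d. uniform states, optionally with missing seconds."""
    length = length or int(rng.integers(40, 300))
    states = rng.choice(np.array(STATE_ALPHABET, dtype=object), size=length)
    if missing_rate:
        states[rng.random(length) < missing_rate] = "MISSING"
    return StateSequence(pid, states)


@pytest.fixture
def random_cohort_seqs(rng):
    return [random_sequence(rng, f"P{i:03d}") for i in range(12)]
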