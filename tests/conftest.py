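import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lpivec import Alphabet, Sequence, TokenizedSequence, TrainingConfig, train

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_corpus():
    """50 copies of a 3-word sentence; the standard training fixture."""
    return [TokenizedSequence(f"s{i}", ("AAAA", "AAAC", "AACA"), 0) for i in range(50)]


@pytest.fixture(scope="session")
def tiny_model(tiny_corpus):
    return train(tiny_corpus, TrainingConfig(dim=8, window=5, epochs=30, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_sequence(rng, alphabet: Alphabet, length: int, seq_id: str = "s") -> Sequence:
    symbols = list(alphabet.symbols)
    return Sequence(seq_id, "".join(rng.choice(symbols, size=length)), alphabet)
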