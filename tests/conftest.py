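import numpy as np
import pytest

from enhmotif.scan import BASES, PWM


def indicator_pwm(word: str, motif_id: str = "ind") -> PWM:
    """A PWM assigning probability 1 to one word (deterministic columns)."""
    probs = np.zeros((len(word), 4))
    for j, base in enumerate(word):
        probs[j, BASES.index(base)] = 1.0
    return PWM(motif_id=motif_id, probs=probs)


def soft_pwm(word: str, dominant: float = 0.9, motif_id: str = "soft") -> PWM:
    """A PWM with one dominant base per column and the rest uniform."""
    probs = np.full((len(word), 4), (1 - dominant) / 3)
    for j, base in enumerate(word):
        probs[j, BASES.index(base)] = dominant
    return PWM(motif_id=motif_id, probs=probs)


def random_dirichlet_pwm(rng: np.random.Generator, length: int,
                         motif_id: str = "rand", alpha: float = 0.5) -> PWM:
    probs = rng.dirichlet(np.full(4, alpha), size=length)
    return PWM(motif_id=motif_id, probs=probs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
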