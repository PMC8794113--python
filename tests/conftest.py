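import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "calimb",
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("calimb")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, n_max=50, lattice=None):
    """A random labelled score instance with both classes present."""
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.sum() in (0, n):  # pragma: no cover - construction guarantees both
        labels[0], labels[-1] = 0, 1
    scores = rng.uniform(size=n)
    if lattice:
        scores = np.round(scores, lattice)
    return labels, scores
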