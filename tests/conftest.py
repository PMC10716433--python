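import numpy as np
import pytest

from ecorestore import BipartiteNetwork, GeneratorConfig, generate


def staircase(k: int = 5) -> np.ndarray:
    """Perfectly nested binary matrix: row i has ones in columns 0..k-1-i."""
    return np.array([[1] * (k - i) + [0] * i for i in range(k)], dtype=np.int8)


@pytest.fixture
def nested_net() -> BipartiteNetwork:
    return BipartiteNetwork(
        tuple(f"p{i}" for i in range(5)), tuple(f"a{j}" for j in range(5)), staircase(5)
    )


@pytest.fixture
def small_net() -> BipartiteNetwork:
    """2 plants x 3 pollinators, 3 links: S=5, A=1.5, C=0.5."""
    inc = np.array([[1, 1, 0], [0, 0, 1]], dtype=np.int8)
    return BipartiteNetwork(("p1", "p2"), ("a1", "a2", "a3"), inc)


@pytest.fixture
def star_net() -> BipartiteNetwork:
    """One plant hub linked to 4 pollinators."""
    return BipartiteNetwork(("hub",), ("a1", "a2", "a3", "a4"),
                            np.ones((1, 4), dtype=np.int8))


@pytest.fixture
def pair_net() -> BipartiteNetwork:
    """Single mutualistic plant-pollinator pair."""
    return BipartiteNetwork(("p1",), ("a1",), np.ones((1, 1), dtype=np.int8))


def random_net(rng: np.random.Generator, n: int = 8, m: int = 10,
               c: float = 0.3, bias: float = 0.0) -> BipartiteNetwork:
    return generate(GeneratorConfig(n, m, c, bias, seed=int(rng.integers(2**31))))
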