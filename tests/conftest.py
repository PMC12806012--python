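import numpy as np
import pytest

from spenet.graph_data import Interactome, build_interactome


@pytest.fixture
def path_graph() -> Interactome:
    """P4: g1 - g2 - g3 - g4."""
    return build_interactome(
        ["g1", "g2", "g3", "g4"], [("g1", "g2"), ("g2", "g3"), ("g3", "g4")]
    )


@pytest.fixture
def triangle() -> Interactome:
    return build_interactome(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])


def random_graph(rng: np.random.Generator, n: int, p: float = 0.15) -> Interactome:
    """Erdos-Renyi graph over zero-padded node names."""
    names = [f"n{i:04d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return build_interactome(names, edges)
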