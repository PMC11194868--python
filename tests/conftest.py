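import numpy as np
import pytest

from spatialprev.graph import AreaGraph, generate_lattice
from spatialprev.weights import build_weights


@pytest.fixture(scope="session")
def grid33():
    return generate_lattice(3, 3)


@pytest.fixture(scope="session")
def grid10():
    return generate_lattice(10, 10)


@pytest.fixture(scope="session")
def path3():
    """3-node path graph a-b-c."""
    return AreaGraph(
        ("a", "b", "c"),
        (frozenset({1}), frozenset({0, 2}), frozenset({1})),
    )


@pytest.fixture(scope="session")
def cycle4():
    """4-cycle in cycle order 0-1-2-3-0."""
    return AreaGraph(
        ("a", "b", "c", "d"),
        (
            frozenset({1, 3}),
            frozenset({0, 2}),
            frozenset({1, 3}),
            frozenset({0, 2}),
        ),
    )


@pytest.fixture(scope="session")
def w_grid33_row(grid33):
    return build_weights(grid33, "row_standardised")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)
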