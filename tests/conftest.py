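"""Shared fixtures: small canonical graphs used across the suite."""

import itertools

import numpy as np
import pytest

from volent import WeightedNetwork, normalize_volume, toy_two_module_network


def complete_graph(p: int, length: float = 1.0) -> WeightedNetwork:
    return WeightedNetwork.from_edges(
        [(a, b, length) for a, b in itertools.combinations(range(p), 2)]
    )


def cycle_graph(p: int, length: float = 1.0) -> WeightedNetwork:
    return WeightedNetwork.from_edges(
        [(i, (i + 1) % p, length) for i in range(p)]
    )


def petersen_graph() -> WeightedNetwork:
    outer = [(i, (i + 1) % 5, 1.0) for i in range(5)]
    inner = [(5 + i, 5 + (i + 2) % 5, 1.0) for i in range(5)]
    spokes = [(i, 5 + i, 1.0) for i in range(5)]
    return WeightedNetwork.from_edges(outer + inner + spokes)


@pytest.fixture
def k4() -> WeightedNetwork:
    return complete_graph(4)


@pytest.fixture
def k4_normalized(k4) -> WeightedNetwork:
    return normalize_volume(k4)


@pytest.fixture
def c5() -> WeightedNetwork:
    return cycle_graph(5)


@pytest.fixture
def toy() -> WeightedNetwork:
    return toy_two_module_network()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
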