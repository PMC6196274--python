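"""Shared fixtures and independent reference implementations.

The reference evaluators here deliberately re-derive the update semantics
from first principles (plain Python loops over the edge list) so package
results can be checked against an implementation that shares no code with
the vectorized paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from glionet import (
    LogicTables,
    RegulatoryNetwork,
    SystemState,
    default_logic_tables,
    default_marker_map,
    default_network,
    neuroinflammatory_state,
    ss_signatures,
    typical_health_state,
)


@pytest.fixture(scope="session")
def net() -> RegulatoryNetwork:
    return default_network()


@pytest.fixture(scope="session")
def tables() -> LogicTables:
    return default_logic_tables()


@pytest.fixture(scope="session")
def marker_map():
    return default_marker_map()


@pytest.fixture(scope="session")
def signatures():
    return ss_signatures()


@pytest.fixture(scope="session")
def ss1_state(net):
    return neuroinflammatory_state(net)


@pytest.fixture(scope="session")
def ss0_state(net):
    return typical_health_state(net)


@pytest.fixture()
def toy_mutual_activation() -> RegulatoryNetwork:
    """A <-> B, both stimulatory: a bistable-plus-baseline toy."""
    return RegulatoryNetwork(["A", "B"], [("A", 1, "B"), ("B", 1, "A")])


@pytest.fixture()
def toy_negative_feedback() -> RegulatoryNetwork:
    """A stimulates B, B inhibits A: single baseline steady state."""
    return RegulatoryNetwork(["A", "B"], [("A", 1, "B"), ("B", -1, "A")])


# ---------------------------------------------------------------------------
# independent reference implementations (oracles)


def sign(x: float) -> int:
    return (x > 0) - (x < 0)


def naive_image(values, network: RegulatoryNetwork, tables: LogicTables | None = None):
    """Reference image computation: plain loops straight off the edge list."""
    tables = tables if tables is not None else default_logic_tables()
    by_target: dict[str, dict[int, list[str]]] = {}
    for edge in network.interactions:
        by_target.setdefault(edge.target, {1: [], -1: []})[edge.sign].append(edge.source)
    state = dict(zip(network.entities, values))
    out = []
    for name in network.entities:
        inputs = by_target.get(name, {1: [], -1: []})
        acts = [state[s] for s in inputs[1]]
        inhs = [state[s] for s in inputs[-1]]
        if acts and inhs:
            a, i = sign(sum(acts)), sign(sum(inhs))
            out.append(tables.pass_table[a + 1][i + 1])
        elif acts:
            out.append(sign(sum(acts)))
        elif inhs:
            out.append(-sign(sum(inhs)))
        else:
            out.append(state[name])
    return tuple(out)


def brute_force_fixed_points(network: RegulatoryNetwork, tables=None):
    """All fixed points by exhaustive itertools scan + the naive evaluator."""
    return [
        SystemState(state)
        for state in itertools.product((-1, 0, 1), repeat=network.n)
        if naive_image(state, network, tables) == state
    ]


def random_states(rng: np.random.Generator, n_states: int, n_entities: int):
    return rng.integers(-1, 2, size=(n_states, n_entities))
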