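"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the package's dynamics
machinery: states are updated by interpreting the rule ASTs directly,
attractors are found by naive trajectory following, and the network
measures are recomputed straight from their defining formulas.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bnrevert import load_fixture
from bnrevert.network import BooleanNetwork, evaluate_expression


@pytest.fixture(scope="session")
def fig1():
    return load_fixture("fig1")


@pytest.fixture(scope="session")
def cascade():
    return load_fixture("cascade")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_annotations")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_profiles")


# --------------------------------------------------------------------------
# Naive dynamics (independent of BooleanNetwork.step_function)

def naive_step(net: BooleanNetwork, state: tuple[int, ...]) -> tuple[int, ...]:
    env = dict(zip(net.node_ids, state))
    out = []
    for n in net.node_ids:
        if n in net.rules:
            out.append(evaluate_expression(net.rules[n], env))
        else:
            out.append(env[n])
    return tuple(out)


def naive_attractor(net: BooleanNetwork, state: tuple[int, ...]) -> tuple:
    """Canonical cycle (lexicographically smallest state first) by iteration."""
    seen: dict[tuple[int, ...], int] = {}
    traj: list[tuple[int, ...]] = []
    s = tuple(state)
    while s not in seen:
        seen[s] = len(traj)
        traj.append(s)
        s = naive_step(net, s)
    cycle = traj[seen[s]:]
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def naive_all_attractors(net: BooleanNetwork) -> dict[tuple, int]:
    """Attractor -> basin size over the full state space."""
    basins: dict[tuple, int] = {}
    for s in itertools.product((0, 1), repeat=net.n_nodes):
        att = naive_attractor(net, s)
        basins[att] = basins.get(att, 0) + 1
    return basins


def naive_primary(basins: dict[tuple, int]) -> tuple:
    """Largest basin; ties -> lexicographically smallest canonical cycle."""
    best = max(basins, key=lambda a: (basins[a], tuple(-x for b in a for x in b)))
    return best


def random_nets(count: int, seed: int, n_min: int = 5, n_max: int = 10):
    """Seeded stream of small random canalizing networks with IO roles."""
    from bnrevert.ensemble import random_canalizing_network

    rng = np.random.default_rng(seed)
    nets = []
    while len(nets) < count:
        n = int(rng.integers(n_min, n_max + 1))
        n_inputs = int(rng.integers(1, 3))
        net = random_canalizing_network(
            n, n_inputs=n_inputs, n_outputs=1, mean_in_degree=2.0, rng_seed=rng
        )
        nets.append(net)
    return nets
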