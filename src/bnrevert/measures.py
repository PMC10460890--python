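"""Network-level reversibility, redundancy and robustness measures.

* Reversibility ``V = 1 - N_T / N``: fraction of internal nodes that are
  not C3 (N_T = number of C3 nodes among the N classified nodes).
* Redundancy ``D = N_sp / N_p``: simple paths from input nodes to matched
  output nodes (paths shorter than twice the shortest path), per matched
  (input node, input state, output node) instance.
* Robustness to mutation ``B_m``: average fraction of primary-attractor
  states retained across all 2N single-node fixations.
* Robustness to perturbation ``B_p``: fraction of (initial state, node
  flip) pairs whose flipped trajectory converges to the same attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import networkx as nx

from .network import (
    BnrevertError,
    BooleanNetwork,
    Intervention,
    apply_interventions,
    control,
    find_attractor,
    node_roles,
    sample_attractors,
)
from .iomatch import IOMatching, infer_io_matching
from .reversion import ClassificationReport

__all__ = [
    "UndefinedMeasureError",
    "MeasureReport",
    "reversibility",
    "redundancy",
    "robustness_mutation",
    "robustness_perturbation",
    "interaction_graph",
    "measure_network",
]


class UndefinedMeasureError(BnrevertError):
    """The measure is undefined (e.g. no deterministic IO matching)."""


@dataclass
class MeasureReport:
    """All four measures of one network plus the counts behind them."""

    V: float
    N_T: int
    n_internal: int
    D: float
    N_sp: int
    N_p: int
    B_m: float
    B_p: float
    n_samples: int
    seed: int | None

    def as_dict(self) -> dict:
        return asdict(self)


def reversibility(report: ClassificationReport) -> float:
    """V = 1 - N_T/N over the classified (internal) nodes."""
    if report.n_internal == 0:
        raise UndefinedMeasureError("reversibility of an empty classification")
    n_t = len(report.nodes_in_class("C3"))
    return 1.0 - n_t / report.n_internal


def interaction_graph(net: BooleanNetwork) -> nx.DiGraph:
    """Directed regulator -> target graph of the Boolean network."""
    g = nx.DiGraph()
    g.add_nodes_from(net.node_ids)
    for target, regs in net.regulators.items():
        for r in regs:
            g.add_edge(r, target)
    return g


def redundancy(
    net: BooleanNetwork, wt: IOMatching | None = None
) -> tuple[float, int, int]:
    """Redundancy D = N_sp / N_p over matched input-output instances.

    An (input node, input state, output node) instance is *matched* when
    the output is inferred as 0 or 1 for at least one profile with that
    input at that state (so each input-output pair can be matched twice,
    once per input state).  N_sp counts, per matched instance, the
    directed simple paths from the input to the output that are shorter
    than twice the shortest path (edge count, strict).  Undefined when
    the matching has no deterministic profile.
    """
    if wt is None:
        wt = infer_io_matching(net)
    if not wt.has_deterministic_profile:
        raise UndefinedMeasureError(
            "redundancy requires at least one deterministic IO matching"
        )
    g = interaction_graph(net)
    inputs = wt.input_nodes
    outputs = wt.output_nodes
    n_p = 0
    n_sp = 0
    path_count_cache: dict[tuple[str, str], int] = {}
    for ii, inp in enumerate(inputs):
        for state in (0, 1):
            profiles = [p for p in wt.values if p[ii] == state]
            for jo, out in enumerate(outputs):
                if not any(wt.values[p][jo] != 0.5 for p in profiles):
                    continue
                n_p += 1
                if (inp, out) not in path_count_cache:
                    try:
                        shortest = nx.shortest_path_length(g, inp, out)
                    except nx.NetworkXNoPath:
                        path_count_cache[(inp, out)] = 0
                    else:
                        cutoff = 2 * shortest - 1  # strict: length < 2 * shortest
                        count = sum(
                            1
                            for path in nx.all_simple_paths(g, inp, out, cutoff=cutoff)
                        )
                        path_count_cache[(inp, out)] = count
                n_sp += path_count_cache[(inp, out)]
    if n_p == 0:
        raise UndefinedMeasureError("no matched input-output instances")
    return n_sp / n_p, n_sp, n_p


def robustness_mutation(
    net: BooleanNetwork,
    n_samples: int = 1024,
    seed: int | None = 0,
    all_attractors: bool = False,
    mask_mutated: bool = False,
) -> float:
    """B_m: mean fraction of primary-attractor states retained per mutation.

    For each of the 2N single-node fixations (each node to 1 and to 0),
    primary attractors of the original (A_o) and mutated (A_k) network
    are sampled from ``n_samples`` initial states; the retained fraction
    is |A_o ∩ A_k| / |A_o| on raw states (states only reachable in the
    mutated network are thereby ignored).  ``all_attractors`` compares
    the union of all sampled attractor states instead of the primary
    one; ``mask_mutated`` drops the mutated node's coordinate before
    intersecting.
    """
    base = sample_attractors(net, n_samples, seed)
    a_o = base.all_states() if all_attractors else base.primary_states()
    total = 0.0
    count = 0
    for k, node in enumerate(net.node_ids):
        for value in (1, 0):
            mutated = apply_interventions(net, [control(node, value)])
            samp = sample_attractors(mutated, n_samples, seed)
            a_k = samp.all_states() if all_attractors else samp.primary_states()
            if mask_mutated:
                idx = net.index[node]
                masked_o = {s[:idx] + s[idx + 1 :] for s in a_o}
                masked_k = {s[:idx] + s[idx + 1 :] for s in a_k}
                retained = len(masked_o & masked_k) / len(masked_o)
            else:
                retained = len(a_o & a_k) / len(a_o)
            total += retained
            count += 1
    return total / count


def robustness_perturbation(
    net: BooleanNetwork, n_samples: int = 1024, seed: int | None = 0
) -> float:
    """B_p: fraction of (state, flipped node) pairs reaching the same attractor.

    Initial states are sampled as in :func:`sample_attractors`
    (exhaustive when the state space is small enough); each sampled
    state is compared against its N single-bit flips.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    import numpy as np

    n = net.n_nodes
    exhaustive = n <= 30 and 2 ** n <= n_samples
    if exhaustive:
        initials = list(net.all_states())
    else:
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 2 ** n, size=n_samples) if n <= 62 else None
        if codes is not None:
            initials = [net.state_from_int(int(c)) for c in codes]
        else:
            initials = [
                tuple(int(b) for b in row)
                for row in rng.integers(0, 2, size=(n_samples, n))
            ]
    cache: dict = {}
    same = 0
    for s in initials:
        a_s = find_attractor(net, s, _cache=cache)
        for k in range(n):
            flipped = s[:k] + (1 - s[k],) + s[k + 1 :]
            if find_attractor(net, flipped, _cache=cache) == a_s:
                same += 1
    return same / (n * len(initials))


def measure_network(
    net: BooleanNetwork,
    n_samples: int = 1024,
    seed: int | None = 0,
    budget: int = 1,
) -> MeasureReport:
    """Classification-derived V plus D, B_m and B_p in one report."""
    from .reversion import classify_nodes

    wt = infer_io_matching(net)
    report = classify_nodes(net, budget=budget, wt=wt)
    v = reversibility(report)
    d, n_sp, n_p = redundancy(net, wt)
    b_m = robustness_mutation(net, n_samples, seed)
    b_p = robustness_perturbation(net, n_samples, seed)
    return MeasureReport(
        V=v,
        N_T=len(report.nodes_in_class("C3")),
        n_internal=report.n_internal,
        D=d,
        N_sp=n_sp,
        N_p=n_p,
        B_m=b_m,
        B_p=b_p,
        n_samples=n_samples,
        seed=seed,
    )
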