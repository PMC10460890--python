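"""Input-output matching of Boolean networks via the LDOI.

The IO relationship of a network maps each combination of input-node
states to the long-run behavior of the output nodes.  Enumerating
attractors for that is NP-hard, so the matching inferred here uses the
LDOI instead: holding one input profile (plus any mutations) fixed, an
output is inferred ON (1) or OFF (0) when the corresponding literal lies
in the LDOI, and *undetermined* (0.5) otherwise.  Because the LDOI is a
sufficient set of stabilized states, an inferred 0 or 1 is guaranteed to
hold in every reachable attractor.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping

from .network import (
    Attractor,
    BnrevertError,
    BooleanNetwork,
    Intervention,
    apply_interventions,
    check_conflict_free,
    find_attractor,
    node_roles,
)
from .expanded import build_expanded, ldoi

__all__ = [
    "NoInputOutputError",
    "NetworkTooLargeError",
    "IOMatching",
    "infer_io_matching",
    "is_deterministic",
    "matchings_equal",
    "oracle_io_relationship",
    "matching_to_table",
]

InputProfile = tuple[int, ...]  # one bit per input node, in input order


class NoInputOutputError(BnrevertError):
    """The network lacks an input or an output node."""


class NetworkTooLargeError(BnrevertError):
    """Exhaustive enumeration was requested for too large a network."""


@dataclass
class IOMatching:
    """Map from every input profile to inferred output values in {0, 0.5, 1}.

    A profile is *deterministic* when at least one output is inferred as
    0 or 1; it is nondeterministic when every output is 0.5.
    """

    input_nodes: tuple[str, ...]
    output_nodes: tuple[str, ...]
    values: dict[InputProfile, tuple[float, ...]]

    def output_value(self, profile: InputProfile, output: str) -> float:
        return self.values[tuple(profile)][self.output_nodes.index(output)]

    def deterministic_profiles(self) -> list[InputProfile]:
        return [p for p in self.values if any(v != 0.5 for v in self.values[p])]

    @property
    def has_deterministic_profile(self) -> bool:
        return len(self.deterministic_profiles()) > 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "inputs": list(self.input_nodes),
                "outputs": list(self.output_nodes),
                "matching": {
                    "".join(map(str, p)): list(v) for p, v in sorted(self.values.items())
                },
            },
            indent=2,
        )


def infer_io_matching(
    net: BooleanNetwork, interventions: Iterable[Intervention] = ()
) -> IOMatching:
    """Infer the IO matching of a (possibly mutated) network.

    For each of the 2^l input profiles, the LDOI is seeded with the
    input literals plus the intervened-node literals on the
    intervention-applied network; each output node is read off the
    closure (0/1 when stabilized, 0.5 otherwise).
    """
    interventions = list(interventions)
    fixed = check_conflict_free(interventions)
    inputs, outputs, _ = node_roles(net)
    if not inputs or not outputs:
        raise NoInputOutputError("IO matching needs >= 1 input and >= 1 output node")
    working = apply_interventions(net, interventions)
    expanded = build_expanded(working)
    base_seeds = [(n, v) for n, v in fixed.items()]
    values: dict[InputProfile, tuple[float, ...]] = {}
    for profile in itertools.product((0, 1), repeat=len(inputs)):
        seeds = list(base_seeds)
        for n, v in zip(inputs, profile):
            if n in fixed:  # an intervened input stays at its fixed value
                continue
            seeds.append((n, v))
        closure = ldoi(expanded, seeds)
        values[profile] = tuple(closure.value_of(o) for o in outputs)
    return IOMatching(inputs, outputs, values)


def is_deterministic(matching: IOMatching, profile: InputProfile) -> bool:
    """True iff at least one output is inferred as 0 or 1 at this profile."""
    key = tuple(profile)
    if key not in matching.values:
        raise KeyError(f"unknown input profile {profile!r}")
    return any(v != 0.5 for v in matching.values[key])


def matchings_equal(m1: IOMatching, m2: IOMatching) -> bool:
    """True iff the inferred output vectors agree at every input profile.

    0.5 entries are compared literally; differing input or output node
    sets are an error, not inequality.
    """
    if m1.input_nodes != m2.input_nodes or m1.output_nodes != m2.output_nodes:
        raise ValueError("matchings defined over different input/output node sets")
    return m1.values == m2.values


def oracle_io_relationship(
    net: BooleanNetwork,
    interventions: Iterable[Intervention] = (),
    max_nodes: int = 20,
) -> dict[InputProfile, tuple[float, ...]]:
    """Exact IO relationship by exhaustive attractor enumeration.

    For each input profile, every assignment of the free (non-input,
    non-intervened) nodes is followed to its attractor; the returned
    value per output is the mean output state over initial states and
    attractor cycle states.  Intended as an independent oracle for small
    networks only.
    """
    interventions = list(interventions)
    fixed = check_conflict_free(interventions)
    inputs, outputs, _ = node_roles(net)
    if not inputs or not outputs:
        raise NoInputOutputError("IO relationship needs >= 1 input and >= 1 output")
    if net.n_nodes > max_nodes:
        raise NetworkTooLargeError(
            f"{net.n_nodes} nodes exceeds the exhaustive-enumeration bound {max_nodes}"
        )
    working = apply_interventions(net, interventions)
    free = [
        n for n in net.node_ids if n not in inputs and n not in fixed
    ]
    out_idx = [net.index[o] for o in outputs]
    result: dict[InputProfile, tuple[float, ...]] = {}
    for profile in itertools.product((0, 1), repeat=len(inputs)):
        cache: dict = {}
        totals = [0.0] * len(outputs)
        count = 0
        for assignment in itertools.product((0, 1), repeat=len(free)):
            state = [0] * net.n_nodes
            for n, v in zip(inputs, profile):
                state[net.index[n]] = fixed.get(n, v)
            for n, v in fixed.items():
                state[net.index[n]] = v
            for n, v in zip(free, assignment):
                state[net.index[n]] = v
            att = find_attractor(working, tuple(state), _cache=cache)
            for j, oi in enumerate(out_idx):
                totals[j] += sum(s[oi] for s in att.states) / att.L
            count += 1
        result[profile] = tuple(t / count for t in totals)
    return result


def matching_to_table(matching: IOMatching) -> str:
    """Render a matching as a text table: rows = input profiles, columns = outputs."""
    header = ["profile(" + ",".join(matching.input_nodes) + ")"] + list(
        matching.output_nodes
    )
    widths = [max(len(h), 8) for h in header]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    for profile in sorted(matching.values):
        cells = ["".join(map(str, profile))] + [
            ("0.5" if v == 0.5 else str(int(v))) for v in matching.values[profile]
        ]
        lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
    return "\n".join(lines)
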