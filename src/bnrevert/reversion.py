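"""Mutation effectiveness, C0-C3 node classification and reverse control.

A mutation (GOF fixes a node to 1, LOF to 0) is *effective* when it
changes the network's inferred IO matching, and *reverse-controllable*
when some set of node fixations applied on top of it restores the
wild-type matching exactly.  Internal nodes fall into four classes:

* C0 - both mutations ineffective;
* C1 - exactly one mutation effective (fixing the node to its
  ineffective value restores the matching, so C1 nodes are always
  reverse-controllable by targeting the node itself);
* C2 - both mutations effective, every effective mutation reversible
  within the search budget (via C1-node fixations and/or overriding the
  mutated node);
* C3 - some effective mutation is not reversible within the budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .network import (
    BnrevertError,
    BooleanNetwork,
    Intervention,
    check_conflict_free,
    control,
    gof,
    lof,
    node_roles,
)
from .iomatch import IOMatching, infer_io_matching, matchings_equal

__all__ = [
    "MutationOnIONodeError",
    "ControlSet",
    "ClassificationReport",
    "mutation_effect",
    "find_reverse_controls",
    "classify_nodes",
]


class MutationOnIONodeError(BnrevertError):
    """Effectiveness is only defined for internal-node mutations."""


@dataclass(frozen=True)
class ControlSet:
    """A conflict-free set of control fixations restoring the wild type.

    ``minimal`` is True when no proper subset of the controls also
    restores the wild-type matching.
    """

    controls: tuple[Intervention, ...]
    minimal: bool = True

    def __post_init__(self) -> None:
        check_conflict_free(self.controls)

    @property
    def size(self) -> int:
        return len(self.controls)

    def sort_key(self):
        return (self.size, tuple((c.node, c.value) for c in self.controls))

    def as_dict(self) -> dict[str, int]:
        return {c.node: c.value for c in self.controls}

    def __str__(self) -> str:
        return "{" + ", ".join(f"{c.node}:={c.value}" for c in self.controls) + "}"


def mutation_effect(
    net: BooleanNetwork, mutation: Intervention, wt: IOMatching | None = None
) -> bool:
    """True iff the mutation disrupts the wild-type IO matching."""
    inputs, outputs, internals = node_roles(net)
    if mutation.node not in internals:
        raise MutationOnIONodeError(
            f"mutation target {mutation.node!r} is not an internal node"
        )
    if wt is None:
        wt = infer_io_matching(net)
    mutated = infer_io_matching(net, [mutation])
    return not matchings_equal(wt, mutated)


def _apply_controls(
    mutations: Sequence[Intervention], controls: Sequence[Intervention]
) -> list[Intervention]:
    """Controls on a mutated node override the mutation on that node."""
    controlled = {c.node for c in controls}
    kept = [m for m in mutations if m.node not in controlled]
    return kept + list(controls)


def default_candidates(
    net: BooleanNetwork,
    mutations: Sequence[Intervention],
    wt: IOMatching | None = None,
) -> list[Intervention]:
    """Default control candidates: C1-node fixations plus mutation overrides."""
    report = classify_nodes(net, wt=wt)
    cands: list[Intervention] = []
    for node in report.nodes_in_class("C1"):
        cands.append(control(node, 0))
        cands.append(control(node, 1))
    for m in mutations:
        cands.append(control(m.node, 1 - m.value))
    # dedupe, keep order
    seen = set()
    out = []
    for c in cands:
        key = (c.node, c.value)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def find_reverse_controls(
    net: BooleanNetwork,
    mutations: Iterable[Intervention],
    candidates: Iterable[Intervention] | None = None,
    budget: int = 1,
    wt: IOMatching | None = None,
    max_total_fixed: int | None = None,
) -> list[ControlSet]:
    """All minimal control sets (size <= budget) restoring the wild type.

    A control on a mutated node replaces that mutation (fixation to the
    opposite value = override).  ``max_total_fixed`` optionally bounds
    the number of simultaneously fixed nodes (surviving mutations plus
    controls), mirroring a double-mutation-style search.  Results are
    sorted by (size, lexicographic) and contain no supersets of smaller
    restoring sets.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    mutations = list(mutations)
    check_conflict_free(mutations)
    if wt is None:
        wt = infer_io_matching(net)
    if candidates is None:
        candidates = default_candidates(net, mutations, wt=wt)
    else:
        candidates = list(candidates)

    found: list[ControlSet] = []
    found_keys: list[frozenset] = []
    for size in range(1, budget + 1):
        for combo in itertools.combinations(candidates, size):
            nodes = {c.node for c in combo}
            if len(nodes) < size:
                continue  # two values on one node
            key = frozenset((c.node, c.value) for c in combo)
            if any(prev < key for prev in found_keys):
                continue  # a proper subset already restores: not minimal
            effective_ivs = _apply_controls(mutations, combo)
            if max_total_fixed is not None and len(effective_ivs) > max_total_fixed:
                continue
            if matchings_equal(wt, infer_io_matching(net, effective_ivs)):
                found.append(ControlSet(tuple(sorted(combo))))
                found_keys.append(key)
    return sorted(found, key=lambda cs: cs.sort_key())


@dataclass
class ClassificationReport:
    """Per-internal-node class with witness reverse-control sets.

    ``effects[node]`` is (GOF effective, LOF effective); ``witnesses``
    maps a node to per-mutation lists of minimal restoring control sets
    found during the C2 search.
    """

    classes: dict[str, str]
    effects: dict[str, tuple[bool, bool]]
    witnesses: dict[str, dict[str, list[ControlSet]]] = field(default_factory=dict)
    budget: int = 1

    def nodes_in_class(self, cls: str) -> list[str]:
        return [n for n, c in self.classes.items() if c == cls]

    def class_counts(self) -> dict[str, int]:
        return {c: len(self.nodes_in_class(c)) for c in ("C0", "C1", "C2", "C3")}

    def class_ratios(self) -> dict[str, float]:
        n = len(self.classes)
        return {c: k / n for c, k in self.class_counts().items()}

    @property
    def n_internal(self) -> int:
        return len(self.classes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node, cls in self.classes.items():
            ge, le = self.effects[node]
            wit = self.witnesses.get(node, {})
            rows.append(
                {
                    "node": node,
                    "class": cls,
                    "gof_effective": ge,
                    "lof_effective": le,
                    "gof_controls": "; ".join(map(str, wit.get("GOF", []))),
                    "lof_controls": "; ".join(map(str, wit.get("LOF", []))),
                }
            )
        return pd.DataFrame(rows)


def classify_nodes(
    net: BooleanNetwork,
    budget: int = 1,
    wt: IOMatching | None = None,
    allow_any_candidates: bool = False,
) -> ClassificationReport:
    """Two-pass C0-C3 classification of all internal nodes.

    Pass 1 tests GOF/LOF effectiveness against the wild-type matching
    (C0: both ineffective, C1: exactly one).  Pass 2 searches reverse
    controls for nodes with both mutations effective, with candidates
    restricted to C1-node fixations plus the self-override and the total
    number of simultaneously fixed nodes bounded by ``1 + budget``
    (``budget`` = controls beyond the self-override; the default 1
    matches a double-fixation search).  ``allow_any_candidates`` widens
    the candidate pool to fixations of every internal node.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if wt is None:
        wt = infer_io_matching(net)
    _, _, internals = node_roles(net)
    effects: dict[str, tuple[bool, bool]] = {}
    for node in internals:
        ge = not matchings_equal(wt, infer_io_matching(net, [gof(node)]))
        le = not matchings_equal(wt, infer_io_matching(net, [lof(node)]))
        effects[node] = (ge, le)

    classes: dict[str, str] = {}
    c1_nodes = [
        n for n, (ge, le) in effects.items() if ge != le
    ]
    for node, (ge, le) in effects.items():
        if not ge and not le:
            classes[node] = "C0"
        elif ge != le:
            classes[node] = "C1"

    c1_fixations: list[Intervention] = []
    for n in (internals if allow_any_candidates else c1_nodes):
        c1_fixations.append(control(n, 0))
        c1_fixations.append(control(n, 1))

    witnesses: dict[str, dict[str, list[ControlSet]]] = {}
    for node, (ge, le) in effects.items():
        if node in classes:
            continue  # C0 or C1 already assigned
        node_wit: dict[str, list[ControlSet]] = {}
        reversible = True
        for label, mutation in (("GOF", gof(node)), ("LOF", lof(node))):
            cands = [c for c in c1_fixations if c.node != node]
            cands.append(control(node, 1 - mutation.value))
            sets = find_reverse_controls(
                net,
                [mutation],
                candidates=cands,
                budget=budget + 1,
                wt=wt,
                max_total_fixed=1 + budget,
            )
            node_wit[label] = sets
            if not sets:
                reversible = False
        witnesses[node] = node_wit
        classes[node] = "C2" if reversible else "C3"

    ordered = {n: classes[n] for n in internals}
    return ClassificationReport(ordered, effects, witnesses, budget)
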