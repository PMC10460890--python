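"""Expanded network construction and the logical domain of influence (LDOI).

The expanded network is a graphical encoding of a Boolean network's logic:
each original node contributes two *literal* nodes (node ON, node OFF), and
each multi-literal prime implicant of a rule (or of its complement)
contributes a *composite* node acting as an AND gate.  Every edge encodes a
sufficiency relation, so reachability-with-AND-gates on this graph — the
LDOI of a set of fixed node states — yields node states guaranteed to
stabilize when the seed states are held fixed, without enumerating
attractors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .network import (
    BooleanNetwork,
    ConflictingInterventionError,
    Expr,
    evaluate_expression,
)

__all__ = [
    "Literal",
    "prime_implicants",
    "ExpandedNetwork",
    "build_expanded",
    "LDOIResult",
    "ldoi",
    "expanded_to_dot",
    "expanded_to_graphml",
]

# A literal is (node, bit); an implicant is a frozenset of literals.
Literal = tuple[str, int]
Implicant = frozenset


def _negate(lit: Literal) -> Literal:
    return (lit[0], 1 - lit[1])


# --------------------------------------------------------------------------
# Prime implicants (complete set = Blake canonical form)

def _qm_primes(n_vars: int, minterms: Sequence[int]) -> list[tuple[int, int]]:
    """Quine-McCluskey merge phase: all prime implicants of a truth table.

    Implicants are (mask, value) pairs over variable bit positions: bit i
    of ``mask`` is set when variable i is fixed (to bit i of ``value``).
    The merge phase alone already yields the complete prime set (the
    Blake canonical form); no cover-minimization is applied, on purpose.
    """
    current = {(((1 << n_vars) - 1), m) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        by_mask: dict[int, list[int]] = {}
        for mask, val in current:
            by_mask.setdefault(mask, []).append(val)
        for mask, vals in by_mask.items():
            vset = set(vals)
            for val in vals:
                for i in range(n_vars):
                    bit = 1 << i
                    if mask & bit and (val ^ bit) in vset:
                        used.add((mask, val))
                        used.add((mask, val ^ bit))
                        merged.add((mask & ~bit, val & ~bit))
        primes |= current - used
        current = merged
    return sorted(primes)


def prime_implicants(
    rule: Expr, regulators: Sequence[str], *, negate: bool = False
) -> set[Implicant]:
    """Complete prime-implicant set of a rule (or its complement).

    Each implicant is a frozenset of ``(regulator, bit)`` literals whose
    conjunction forces the function to 1 (0 when ``negate``).  A constant
    function returns ``{frozenset()}`` if it equals the requested value,
    else the empty set.
    """
    k = len(regulators)
    target = 0 if negate else 1
    if k == 0:
        value = evaluate_expression(rule, {})
        return {frozenset()} if value == target else set()
    minterms = []
    for m in range(2 ** k):
        env = {regulators[i]: (m >> i) & 1 for i in range(k)}
        if evaluate_expression(rule, env) == target:
            minterms.append(m)
    if not minterms:
        return set()
    if len(minterms) == 2 ** k:
        return {frozenset()}
    out: set[Implicant] = set()
    for mask, val in _qm_primes(k, minterms):
        lits = frozenset(
            (regulators[i], (val >> i) & 1) for i in range(k) if mask & (1 << i)
        )
        out.add(lits)
    return out


# --------------------------------------------------------------------------
# Expanded network

@dataclass
class ExpandedNetwork:
    """Literal nodes plus composite AND nodes, with sufficiency edges.

    ``single_edges[p]`` lists literal children reachable from literal
    ``p`` alone; ``composites`` maps each composite (frozenset of member
    literals) to its literal targets, and ``literal_to_composites[p]``
    lists the composites ``p`` feeds.  ``constant_literals`` are literals
    forced by constant rules; they belong to every LDOI.
    """

    net: BooleanNetwork
    literals: tuple[Literal, ...]
    single_edges: dict[Literal, tuple[Literal, ...]]
    composites: dict[Implicant, tuple[Literal, ...]]
    literal_to_composites: dict[Literal, tuple[Implicant, ...]]
    constant_literals: tuple[Literal, ...]

    @property
    def n_literals(self) -> int:
        return len(self.literals)

    @property
    def n_composites(self) -> int:
        return len(self.composites)

    @property
    def n_nodes(self) -> int:
        return self.n_literals + self.n_composites

    def n_edges(self) -> int:
        e = sum(len(v) for v in self.single_edges.values())
        e += sum(len(c) + len(t) for c, t in self.composites.items())
        return e

    def in_degree(self, lit: Literal) -> int:
        """Incoming edges of a literal (one per implicant of its rule side)."""
        deg = sum(lit in kids for kids in self.single_edges.values())
        deg += sum(lit in targets for targets in self.composites.values())
        return deg


def build_expanded(net: BooleanNetwork) -> ExpandedNetwork:
    """Build the expanded network from the prime implicants of every rule.

    For each non-input node v: implicants of f_v feed literal (v, 1) and
    implicants of the complement feed (v, 0).  Single-literal implicants
    become direct literal->literal edges; larger ones become composite
    nodes (deduplicated by member set).  Input literals have no incoming
    edges.
    """
    literals: list[Literal] = []
    for n in net.node_ids:
        literals.append((n, 0))
        literals.append((n, 1))
    single: dict[Literal, list[Literal]] = {}
    composites: dict[Implicant, list[Literal]] = {}
    constants: list[Literal] = []
    for v in net.node_ids:
        if v not in net.rules:
            continue
        rule = net.rules[v]
        regs = net.regulators[v]
        for bit in (1, 0):
            for imp in prime_implicants(rule, regs, negate=(bit == 0)):
                if len(imp) == 0:
                    constants.append((v, bit))
                elif len(imp) == 1:
                    (p,) = imp
                    single.setdefault(p, []).append((v, bit))
                else:
                    composites.setdefault(imp, []).append((v, bit))
    lit_order = {l: i for i, l in enumerate(literals)}
    single_edges = {
        p: tuple(sorted(kids, key=lit_order.__getitem__)) for p, kids in single.items()
    }
    comp = {c: tuple(sorted(t, key=lit_order.__getitem__)) for c, t in composites.items()}
    lit_to_comp: dict[Literal, list[Implicant]] = {}
    for c in sorted(comp, key=lambda c: sorted(lit_order[l] for l in c)):
        for member in c:
            lit_to_comp.setdefault(member, []).append(c)
    return ExpandedNetwork(
        net=net,
        literals=tuple(literals),
        single_edges=single_edges,
        composites=comp,
        literal_to_composites={p: tuple(v) for p, v in lit_to_comp.items()},
        constant_literals=tuple(sorted(set(constants), key=lit_order.__getitem__)),
    )


# --------------------------------------------------------------------------
# LDOI

@dataclass
class LDOIResult:
    """Closure of literals stabilized by a seed set, plus conflict flags.

    ``conflicts`` lists literals that were derivable but contradict a
    seed (or an earlier-derived literal) and were therefore excluded.
    """

    seeds: frozenset[Literal]
    literals: frozenset[Literal]
    conflicts: tuple[Literal, ...] = ()

    def __contains__(self, lit: Literal) -> bool:
        return lit in self.literals

    def value_of(self, node: str) -> float:
        """0/1 when the node is stabilized in the closure, else 0.5."""
        if (node, 1) in self.literals:
            return 1
        if (node, 0) in self.literals:
            return 0
        return 0.5


def ldoi(expanded: ExpandedNetwork, seeds: Iterable[Literal]) -> LDOIResult:
    """Logical domain of influence of a conflict-free seed literal set.

    Modified breadth-first search on the expanded network: a literal
    joins the closure when one of its single-literal parents is in, or
    when every member of one of its composite parents is in.  A literal
    whose negation is a seed is never added (recorded as a conflict);
    a derived contradiction between two non-seed literals keeps the
    earlier-derived literal (deterministic BFS order: declaration order,
    bit 0 before 1).  Constant-rule literals are roots of every closure.
    """
    seed_set = frozenset(seeds)
    by_node: dict[str, int] = {}
    for node, bit in seed_set:
        if node not in expanded.net.index:
            raise KeyError(f"seed literal on unknown node {node!r}")
        if node in by_node and by_node[node] != bit:
            raise ConflictingInterventionError(
                f"conflicting seed literals on node {node!r}"
            )
        by_node[node] = bit

    lit_order = {l: i for i, l in enumerate(expanded.literals)}
    result: set[Literal] = set()
    conflicts: list[Literal] = []
    queue: list[Literal] = []
    satisfied: dict[Implicant, int] = {}

    def try_add(lit: Literal, *, is_seed: bool = False) -> None:
        if lit in result:
            return
        neg = _negate(lit)
        if not is_seed and neg in seed_set:
            conflicts.append(lit)
            return
        if neg in result:
            # derived contradiction: keep the earlier literal, flag this one
            conflicts.append(lit)
            return
        result.add(lit)
        queue.append(lit)

    for lit in sorted(seed_set, key=lit_order.__getitem__):
        try_add(lit, is_seed=True)
    for lit in expanded.constant_literals:
        try_add(lit)

    head = 0
    while head < len(queue):
        lit = queue[head]
        head += 1
        for child in expanded.single_edges.get(lit, ()):
            try_add(child)
        for comp in expanded.literal_to_composites.get(lit, ()):
            satisfied[comp] = satisfied.get(comp, 0) + 1
            if satisfied[comp] == len(comp):
                for target in expanded.composites[comp]:
                    try_add(target)

    return LDOIResult(seed_set, frozenset(result), tuple(conflicts))


# --------------------------------------------------------------------------
# Export

def _lit_label(lit: Literal) -> str:
    return lit[0] if lit[1] == 1 else "~" + lit[0]


def _comp_label(comp: Implicant) -> str:
    return " & ".join(sorted(_lit_label(l) for l in comp))


def expanded_to_dot(expanded: ExpandedNetwork) -> str:
    lines = ["digraph expanded {"]
    for lit in expanded.literals:
        lines.append(f'  "{_lit_label(lit)}" [shape=ellipse];')
    for comp in expanded.composites:
        lines.append(f'  "{_comp_label(comp)}" [shape=box];')
    for p, kids in expanded.single_edges.items():
        for k in kids:
            lines.append(f'  "{_lit_label(p)}" -> "{_lit_label(k)}";')
    for comp, targets in expanded.composites.items():
        for member in sorted(comp, key=_lit_label):
            lines.append(f'  "{_lit_label(member)}" -> "{_comp_label(comp)}";')
        for t in targets:
            lines.append(f'  "{_comp_label(comp)}" -> "{_lit_label(t)}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def expanded_to_graphml(expanded: ExpandedNetwork):
    """Expanded network as a networkx DiGraph (writable with write_graphml)."""
    import networkx as nx

    g = nx.DiGraph()
    for lit in expanded.literals:
        g.add_node(_lit_label(lit), kind="literal", node=lit[0], bit=lit[1])
    for comp in expanded.composites:
        g.add_node(_comp_label(comp), kind="composite")
    for p, kids in expanded.single_edges.items():
        for k in kids:
            g.add_edge(_lit_label(p), _lit_label(k))
    for comp, targets in expanded.composites.items():
        for member in comp:
            g.add_edge(_lit_label(member), _comp_label(comp))
        for t in targets:
            g.add_edge(_comp_label(comp), _lit_label(t))
    return g
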