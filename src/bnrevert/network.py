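"""Boolean network data model, rule parsing and synchronous dynamics.

A Boolean network is a set of nodes, each holding a binary state, where
every non-input node is updated synchronously by a logic rule over its
regulators.  Rules are written in the BoolNet ``targets, factors`` dialect
with the operators ``!`` (not), ``&`` (and), ``|`` (or), parentheses and
the constants ``0``/``1``.  Nodes that never appear as a target are input
nodes; under synchronous update they hold their value (sustained stimuli).
"""

from __future__ import annotations

import itertools
import json
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "BnrevertError",
    "RuleSyntaxError",
    "DuplicateTargetError",
    "EmptyNetworkError",
    "UnknownNodeError",
    "IsolatedNodeError",
    "ConflictingInterventionError",
    "Expr",
    "parse_expression",
    "expression_to_string",
    "expression_variables",
    "Intervention",
    "gof",
    "lof",
    "control",
    "BooleanNetwork",
    "Attractor",
    "AttractorSample",
    "parse_network",
    "read_bnet",
    "write_bnet",
    "node_roles",
    "apply_interventions",
    "synchronous_step",
    "find_attractor",
    "sample_attractors",
    "attractors_to_json",
]


# --------------------------------------------------------------------------
# Errors

class BnrevertError(Exception):
    """Base class for all package errors."""


class RuleSyntaxError(BnrevertError):
    """A rule expression could not be parsed."""


class DuplicateTargetError(BnrevertError):
    """Two rule lines assign the same target node."""


class EmptyNetworkError(BnrevertError):
    """The rule file contains no rules."""


class UnknownNodeError(BnrevertError):
    """A referenced node does not exist in the network."""


class IsolatedNodeError(BnrevertError):
    """A node has neither regulators nor downstream targets."""


class ConflictingInterventionError(BnrevertError):
    """Two interventions assign different values to one node."""


# --------------------------------------------------------------------------
# Expression AST: nested tuples
#   ("var", name) | ("const", 0 or 1) | ("not", x) | ("and", a, b) | ("or", a, b)

Expr = tuple


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "!&|()":
            tokens.append(c)
            i += 1
        elif c.isalnum() or c == "_":
            j = i
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(text[i:j])
            i = j
        else:
            raise RuleSyntaxError(f"unexpected character {c!r} in rule {text!r}")
    return tokens


def parse_expression(text: str) -> Expr:
    """Parse a rule expression into an AST, exactly as written (no simplification)."""
    tokens = _tokenize(text)
    if not tokens:
        raise RuleSyntaxError("empty rule expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expr:
        node = parse_and()
        while peek() == "|":
            take()
            node = ("or", node, parse_and())
        return node

    def parse_and() -> Expr:
        node = parse_factor()
        while peek() == "&":
            take()
            node = ("and", node, parse_factor())
        return node

    def parse_factor() -> Expr:
        tok = peek()
        if tok is None:
            raise RuleSyntaxError(f"unexpected end of rule {text!r}")
        if tok == "!":
            take()
            return ("not", parse_factor())
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise RuleSyntaxError(f"missing ')' in rule {text!r}")
            take()
            return node
        if tok in ("0", "1"):
            take()
            return ("const", int(tok))
        if tok[0].isdigit():
            raise RuleSyntaxError(f"bad literal {tok!r} in rule {text!r}")
        take()
        return ("var", tok)

    node = parse_or()
    if pos != len(tokens):
        raise RuleSyntaxError(f"trailing tokens {tokens[pos:]} in rule {text!r}")
    return node


def expression_variables(expr: Expr) -> list[str]:
    """Variables referenced by an expression, in order of first appearance."""
    out: list[str] = []

    def walk(e: Expr) -> None:
        if e[0] == "var":
            if e[1] not in out:
                out.append(e[1])
        elif e[0] == "not":
            walk(e[1])
        elif e[0] in ("and", "or"):
            walk(e[1])
            walk(e[2])

    walk(expr)
    return out


def expression_to_string(expr: Expr) -> str:
    """Render an AST back to BoolNet syntax (fully parenthesized where needed)."""
    op, *args = expr
    if op == "var":
        return args[0]
    if op == "const":
        return str(args[0])
    if op == "not":
        inner = expression_to_string(args[0])
        if args[0][0] in ("and", "or"):
            inner = f"({inner})"
        return f"!{inner}"
    if op == "and":
        parts = []
        for a in args:
            s = expression_to_string(a)
            if a[0] == "or":
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)
    if op == "or":
        return " | ".join(expression_to_string(a) for a in args)
    raise ValueError(f"unknown AST op {op!r}")


def evaluate_expression(expr: Expr, env: Mapping[str, int]) -> int:
    op = expr[0]
    if op == "var":
        return env[expr[1]]
    if op == "const":
        return expr[1]
    if op == "not":
        return 1 - evaluate_expression(expr[1], env)
    if op == "and":
        return evaluate_expression(expr[1], env) & evaluate_expression(expr[2], env)
    if op == "or":
        return evaluate_expression(expr[1], env) | evaluate_expression(expr[2], env)
    raise ValueError(f"unknown AST op {op!r}")


def _expr_to_python(expr: Expr, index: Mapping[str, int]) -> str:
    """Render an AST as a python int expression over a state tuple ``s``."""
    op = expr[0]
    if op == "var":
        return f"s[{index[expr[1]]}]"
    if op == "const":
        return str(expr[1])
    if op == "not":
        return f"(1-{_expr_to_python(expr[1], index)})"
    if op == "and":
        return f"({_expr_to_python(expr[1], index)}&{_expr_to_python(expr[2], index)})"
    if op == "or":
        return f"({_expr_to_python(expr[1], index)}|{_expr_to_python(expr[2], index)})"
    raise ValueError(f"unknown AST op {op!r}")


# --------------------------------------------------------------------------
# Interventions

@dataclass(frozen=True, order=True)
class Intervention:
    """Fix one node to a constant value.

    ``kind`` distinguishes disease mutations from therapeutic controls:
    a gain-of-function mutation fixes the node to 1, a loss-of-function
    mutation fixes it to 0, and a control may fix either value.
    """

    node: str
    value: int
    kind: str = "control"  # "mutation_GOF" | "mutation_LOF" | "control"

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"intervention value must be 0/1, got {self.value!r}")
        if self.kind == "mutation_GOF" and self.value != 1:
            raise ValueError("a GOF mutation fixes the node to 1")
        if self.kind == "mutation_LOF" and self.value != 0:
            raise ValueError("an LOF mutation fixes the node to 0")
        if self.kind not in ("mutation_GOF", "mutation_LOF", "control"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")


def gof(node: str) -> Intervention:
    return Intervention(node, 1, "mutation_GOF")


def lof(node: str) -> Intervention:
    return Intervention(node, 0, "mutation_LOF")


def control(node: str, value: int) -> Intervention:
    return Intervention(node, value, "control")


def check_conflict_free(interventions: Iterable[Intervention]) -> dict[str, int]:
    """Map node -> fixed value; raise if two interventions disagree on a node."""
    fixed: dict[str, int] = {}
    for iv in interventions:
        if iv.node in fixed and fixed[iv.node] != iv.value:
            raise ConflictingInterventionError(
                f"node {iv.node!r} assigned both {fixed[iv.node]} and {iv.value}"
            )
        fixed[iv.node] = iv.value
    return fixed


# --------------------------------------------------------------------------
# BooleanNetwork

class BooleanNetwork:
    """Nodes, per-node regulators and Boolean update rules.

    ``rules`` maps each non-input node to an expression AST; nodes without
    a rule are inputs and hold their state under synchronous update.
    Node iteration order is declaration order and is deterministic.
    """

    def __init__(self, node_ids: Sequence[str], rules: Mapping[str, Expr]):
        if len(set(node_ids)) != len(node_ids):
            raise DuplicateTargetError("node identifiers must be unique")
        self.node_ids: tuple[str, ...] = tuple(node_ids)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.node_ids)}
        self.rules: dict[str, Expr] = {}
        self.regulators: dict[str, tuple[str, ...]] = {}
        for target, expr in rules.items():
            if target not in self.index:
                raise UnknownNodeError(f"rule target {target!r} not among node ids")
            regs = expression_variables(expr)
            for r in regs:
                if r not in self.index:
                    raise UnknownNodeError(
                        f"rule for {target!r} references unknown node {r!r}"
                    )
            self.rules[target] = expr
            self.regulators[target] = tuple(regs)
        self._step_fn = None

    # -- basic properties ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(n for n in self.node_ids if n not in self.rules)

    def mean_in_degree(self) -> float:
        """Mean number of regulators per node (inputs count 0)."""
        total = sum(len(self.regulators[t]) for t in self.rules)
        return total / len(self.node_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return self.node_ids == other.node_ids and self.rules == other.rules

    def __repr__(self) -> str:
        return f"BooleanNetwork(n={self.n_nodes}, inputs={len(self.inputs)})"

    # -- dynamics -----------------------------------------------------------

    def step_function(self):
        """Compiled synchronous update: tuple state -> tuple state."""
        if self._step_fn is None:
            parts = []
            for i, n in enumerate(self.node_ids):
                if n in self.rules:
                    parts.append(_expr_to_python(self.rules[n], self.index))
                else:
                    parts.append(f"s[{i}]")  # inputs hold their value
            src = "def _step(s):\n    return (" + ",".join(parts) + ("," if parts else "") + ")"
            ns: dict = {}
            exec(src, ns)  # noqa: S102 - generated from validated ASTs
            self._step_fn = ns["_step"]
        return self._step_fn

    def state_from_int(self, code: int) -> tuple[int, ...]:
        """Decode an integer into a state tuple (node 0 = most significant bit)."""
        n = self.n_nodes
        return tuple((code >> (n - 1 - i)) & 1 for i in range(n))

    def all_states(self) -> Iterator[tuple[int, ...]]:
        return itertools.product((0, 1), repeat=self.n_nodes)


# --------------------------------------------------------------------------
# Parsing and writing

def parse_network(rule_text: str) -> BooleanNetwork:
    """Parse BoolNet ``targets, factors`` text into a :class:`BooleanNetwork`.

    Inputs are exactly the identifiers that appear only on right-hand
    sides.  The expression parse is exact: no simplification is applied.
    """
    lines = [ln.strip() for ln in rule_text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if lines and lines[0].lower().replace(" ", "") == "targets,factors":
        lines = lines[1:]
    if not lines:
        raise EmptyNetworkError("no rule lines found")

    order: list[str] = []
    rules: dict[str, Expr] = {}
    raw: dict[str, str] = {}
    for ln in lines:
        if "," not in ln:
            raise RuleSyntaxError(f"rule line without comma: {ln!r}")
        target, rhs = ln.split(",", 1)
        target = target.strip()
        if not target or not all(c.isalnum() or c == "_" for c in target):
            raise RuleSyntaxError(f"bad target identifier in line {ln!r}")
        if target in rules:
            raise DuplicateTargetError(f"duplicate rule for target {target!r}")
        expr = parse_expression(rhs)
        rules[target] = expr
        raw[target] = rhs.strip()
        if target not in order:
            order.append(target)
        for v in expression_variables(expr):
            if v not in order:
                order.append(v)

    net = BooleanNetwork(order, rules)
    net._raw_rules = raw  # original right-hand sides for bit-exact writing
    return net


def read_bnet(path) -> BooleanNetwork:
    with open(path) as fh:
        return parse_network(fh.read())


def network_to_text(net: BooleanNetwork) -> str:
    raw = getattr(net, "_raw_rules", {})
    lines = ["targets, factors"]
    for n in net.node_ids:
        if n in net.rules:
            rhs = raw.get(n, expression_to_string(net.rules[n]))
            lines.append(f"{n}, {rhs}")
    return "\n".join(lines) + "\n"


def write_bnet(net: BooleanNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(network_to_text(net))


# --------------------------------------------------------------------------
# Roles

def node_roles(net: BooleanNetwork) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Partition nodes into (inputs, outputs, internals).

    An input node has no regulators; an output node has no downstream
    targets.  A node with neither raises :class:`IsolatedNodeError`.
    """
    has_downstream: set[str] = set()
    for regs in net.regulators.values():
        has_downstream.update(regs)
    inputs, outputs, internals = [], [], []
    for n in net.node_ids:
        is_input = n not in net.rules
        is_output = n not in has_downstream
        if is_input and is_output:
            raise IsolatedNodeError(f"node {n!r} has no regulators and no targets")
        if is_input:
            inputs.append(n)
        elif is_output:
            outputs.append(n)
        else:
            internals.append(n)
    return tuple(inputs), tuple(outputs), tuple(internals)


# --------------------------------------------------------------------------
# Interventions on networks

def apply_interventions(
    net: BooleanNetwork, interventions: Iterable[Intervention]
) -> BooleanNetwork:
    """Return a new network with each intervened node's rule replaced by a constant.

    The intervened node keeps no regulators, so no influence propagates
    through it from upstream; the original network is unchanged.
    """
    fixed = check_conflict_free(interventions)
    for node in fixed:
        if node not in net.index:
            raise UnknownNodeError(f"intervention on unknown node {node!r}")
    if not fixed:
        return net
    rules = dict(net.rules)
    for node, value in fixed.items():
        rules[node] = ("const", value)
    out = BooleanNetwork(net.node_ids, rules)
    raw = dict(getattr(net, "_raw_rules", {}))
    for node, value in fixed.items():
        raw[node] = str(value)
    out._raw_rules = raw
    return out


# --------------------------------------------------------------------------
# Dynamics

def synchronous_step(net: BooleanNetwork, state: Sequence[int]) -> tuple[int, ...]:
    """One synchronous update; input nodes hold their value."""
    return net.step_function()(tuple(state))


@dataclass(frozen=True)
class Attractor:
    """A synchronous attractor in canonical rotation.

    ``states`` is the cyclic state sequence rotated so the
    lexicographically smallest state comes first, which makes equality
    and set membership well defined.  ``L`` is the cycle length.
    """

    states: tuple[tuple[int, ...], ...]

    @property
    def L(self) -> int:
        return len(self.states)

    @property
    def is_point(self) -> bool:
        return self.L == 1

    def state_set(self) -> frozenset[tuple[int, ...]]:
        return frozenset(self.states)


def _canonical_cycle(cycle: list[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def find_attractor(
    net: BooleanNetwork,
    initial: Sequence[int],
    _cache: dict | None = None,
) -> Attractor:
    """Iterate the synchronous dynamics from ``initial`` until a cycle closes.

    ``_cache`` (optional, state tuple -> Attractor) memoizes results
    across calls on the same network.
    """
    step = net.step_function()
    s = tuple(initial)
    seen: dict[tuple[int, ...], int] = {}
    trajectory: list[tuple[int, ...]] = []
    while s not in seen:
        if _cache is not None and s in _cache:
            att = _cache[s]
            for t in trajectory:
                _cache[t] = att
            return att
        seen[s] = len(trajectory)
        trajectory.append(s)
        s = step(s)
    cycle = trajectory[seen[s]:]
    att = Attractor(_canonical_cycle(cycle))
    if _cache is not None:
        for t in trajectory:
            _cache[t] = att
    return att


@dataclass
class AttractorSample:
    """Attractors found from sampled initial states, with basin counts.

    ``primary`` is the attractor with the largest basin count; ties break
    by the canonical first state (lexicographic).  Basin counts sum to
    the number of sampled initial states.
    """

    attractors: list[Attractor]
    basin_counts: list[int]
    n_samples: int
    exhaustive: bool
    seed: int | None = None

    @property
    def primary(self) -> Attractor:
        best = max(
            range(len(self.attractors)),
            key=lambda i: (self.basin_counts[i], tuple(-x for x in self.attractors[i].states[0])),
        )
        return self.attractors[best]

    def primary_states(self) -> frozenset[tuple[int, ...]]:
        return self.primary.state_set()

    def all_states(self) -> frozenset[tuple[int, ...]]:
        out: set[tuple[int, ...]] = set()
        for a in self.attractors:
            out |= a.state_set()
        return frozenset(out)


def sample_attractors(
    net: BooleanNetwork, n_samples: int = 1024, seed: int | None = 0
) -> AttractorSample:
    """Sample initial states uniformly and collect the attractors reached.

    When the full state space has at most ``n_samples`` states the
    enumeration is exhaustive (each state once); otherwise ``n_samples``
    initial states are drawn with the seeded generator.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = net.n_nodes
    cache: dict = {}
    counts: dict[Attractor, int] = {}
    exhaustive = n <= 30 and 2 ** n <= n_samples
    if exhaustive:
        initials: Iterable[tuple[int, ...]] = net.all_states()
        total = 2 ** n
    else:
        rng = np.random.default_rng(seed)
        if n <= 62:
            codes = rng.integers(0, 2 ** n, size=n_samples)
            initials = (net.state_from_int(int(c)) for c in codes)
        else:
            bits = rng.integers(0, 2, size=(n_samples, n))
            initials = (tuple(int(b) for b in row) for row in bits)
        total = n_samples
    for s0 in initials:
        att = find_attractor(net, s0, _cache=cache)
        counts[att] = counts.get(att, 0) + 1
    attractors = sorted(counts, key=lambda a: a.states)
    basins = [counts[a] for a in attractors]
    assert sum(basins) == total
    return AttractorSample(attractors, basins, total, exhaustive, seed)


def attractors_to_json(sample: AttractorSample) -> str:
    """Serialize a sample as JSON with states as 0/1 strings in node order."""
    payload = {
        "n_samples": sample.n_samples,
        "exhaustive": sample.exhaustive,
        "attractors": [
            {
                "L": a.L,
                "states": ["".join(map(str, s)) for s in a.states],
                "basin_count": b,
            }
            for a, b in zip(sample.attractors, sample.basin_counts)
        ],
        "primary": ["".join(map(str, s)) for s in sample.primary.states],
    }
    return json.dumps(payload, indent=2)
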