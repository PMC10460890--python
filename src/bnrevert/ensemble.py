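"""Random canalizing networks: generators, logic perturbation, ensemble study.

Random Boolean rules are *canalizing*: one randomly chosen regulator
(the canalizing variable x_c) at one value (the canalizing value b)
forces the output to the canalized value a; the remaining truth-table
rows follow an unbiased random function g (bias 0.5).  Network
topologies come from a directed configuration model preserving a
template network's in/out degree sequences.  The ensemble study
generates many such networks, keeps those with at least one
deterministic IO matching, and correlates reversibility with
redundancy and the two robustness measures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    BnrevertError,
    BooleanNetwork,
    Expr,
    expression_to_string,
    node_roles,
)
from .iomatch import infer_io_matching
from .reversion import classify_nodes
from .measures import (
    UndefinedMeasureError,
    redundancy,
    reversibility,
    robustness_mutation,
    robustness_perturbation,
)

__all__ = [
    "DegreeSequenceError",
    "random_canalizing_function",
    "truth_table_to_expression",
    "configuration_model",
    "perturb_logic",
    "random_canalizing_network",
    "classification_consistency",
    "EnsembleResult",
    "ensemble_study",
]


class DegreeSequenceError(BnrevertError):
    """No collision-free stub pairing was found for the degree sequence."""


# --------------------------------------------------------------------------
# Canalizing rules

def truth_table_to_expression(regulators: list[str], table: np.ndarray) -> Expr:
    """Exact minterm DNF over ``regulators`` for a 2^k truth table.

    Row index m assigns bit (m >> i) & 1 to regulators[i].  Constant
    tables yield tautology/contradiction forms that still reference
    every regulator, so the interaction structure (and hence the degree
    sequence) is preserved even when the drawn logic is degenerate.
    """
    k = len(regulators)
    assert len(table) == 2 ** k
    if k == 0:
        return ("const", int(table[0]))
    ones = [m for m in range(2 ** k) if table[m]]
    if not ones:
        expr: Expr = ("and", ("var", regulators[0]), ("not", ("var", regulators[0])))
        for reg in regulators[1:]:
            expr = ("or", expr, ("and", ("var", reg), ("not", ("var", reg))))
        return expr
    if len(ones) == 2 ** k:
        expr = ("or", ("var", regulators[0]), ("not", ("var", regulators[0])))
        for reg in regulators[1:]:
            expr = ("and", expr, ("or", ("var", reg), ("not", ("var", reg))))
        return expr
    terms: list[Expr] = []
    for m in ones:
        lits: list[Expr] = []
        for i, reg in enumerate(regulators):
            v: Expr = ("var", reg)
            lits.append(v if (m >> i) & 1 else ("not", v))
        term = lits[0]
        for l in lits[1:]:
            term = ("and", term, l)
        terms.append(term)
    expr = terms[0]
    for t in terms[1:]:
        expr = ("or", expr, t)
    return expr


def random_canalizing_function(
    in_degree: int, rng: np.random.Generator | int
) -> tuple[np.ndarray, int, int, int]:
    """Draw a canalizing truth table over ``in_degree`` regulators.

    Returns ``(table, c, b, a)``: rows where regulator ``c`` equals the
    canalizing value ``b`` output the canalized value ``a``; the other
    2^(k-1) rows are independent fair coin flips.
    """
    if in_degree < 1:
        raise ValueError("in_degree must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    c = int(rng.integers(in_degree))
    b = int(rng.integers(2))
    a = int(rng.integers(2))
    k = in_degree
    table = np.empty(2 ** k, dtype=np.int8)
    for m in range(2 ** k):
        if (m >> c) & 1 == b:
            table[m] = a
        else:
            table[m] = rng.integers(2)
    return table, c, b, a


def _assign_random_rules(
    node_ids: list[str], regulators: dict[str, list[str]], rng: np.random.Generator
) -> BooleanNetwork:
    rules: dict[str, Expr] = {}
    for n in node_ids:
        regs = regulators.get(n, [])
        if not regs:
            continue
        table, _, _, _ = random_canalizing_function(len(regs), rng)
        rules[n] = truth_table_to_expression(list(regs), table)
    return BooleanNetwork(node_ids, rules)


# --------------------------------------------------------------------------
# Configuration model

def _pair_stubs(
    out_stubs: list[str], in_stubs: list[str], rng: np.random.Generator, max_tries: int
) -> list[tuple[str, str]] | None:
    """Random pairing of out-stubs to in-stubs, repaired by edge swaps.

    Self-loops and parallel edges are removed by swapping a colliding
    pair with a random other pair (degree-preserving); returns None when
    repair fails.
    """
    order = rng.permutation(len(in_stubs))
    pairs = [(out_stubs[i], in_stubs[order[i]]) for i in range(len(out_stubs))]
    for _ in range(max_tries):
        seen: dict[tuple[str, str], int] = {}
        bad = -1
        for idx, e in enumerate(pairs):
            if e[0] == e[1] or e in seen:
                bad = idx
                break
            seen[e] = idx
        if bad < 0:
            return pairs
        j = int(rng.integers(len(pairs)))
        if j == bad:
            continue
        (u1, v1), (u2, v2) = pairs[bad], pairs[j]
        pairs[bad], pairs[j] = (u1, v2), (u2, v1)
    return None


def configuration_model(
    template: BooleanNetwork,
    rng_seed: int | np.random.Generator = 0,
    max_tries: int = 10000,
) -> BooleanNetwork:
    """Degree-preserving random rewiring of a template, with fresh canalizing rules.

    The generated network has exactly the template's in- and out-degree
    sequences (no self-loops, no parallel regulators); every node with
    regulators receives a rule drawn by :func:`random_canalizing_function`.
    """
    rng = (
        np.random.default_rng(rng_seed)
        if isinstance(rng_seed, (int, np.integer))
        else rng_seed
    )
    out_deg = {n: 0 for n in template.node_ids}
    in_deg = {n: len(template.regulators.get(n, ())) for n in template.node_ids}
    for regs in template.regulators.values():
        for r in regs:
            out_deg[r] += 1
    out_stubs = [n for n in template.node_ids for _ in range(out_deg[n])]
    in_stubs = [n for n in template.node_ids for _ in range(in_deg[n])]
    for _ in range(50):
        pairs = _pair_stubs(out_stubs, in_stubs, rng, max_tries)
        if pairs is not None:
            break
    else:
        raise DegreeSequenceError(
            "could not realize the degree sequence without collisions"
        )
    regulators: dict[str, list[str]] = {n: [] for n in template.node_ids}
    for src, dst in pairs:
        regulators[dst].append(src)
    regulators = {n: regs for n, regs in regulators.items() if regs}
    return _assign_random_rules(list(template.node_ids), regulators, rng)


# --------------------------------------------------------------------------
# Logic perturbation (model-uncertainty analysis)

def perturb_logic(
    net: BooleanNetwork,
    fraction: float,
    rng_seed: int | np.random.Generator = 0,
) -> BooleanNetwork:
    """Replace a fraction of the non-input rules with random canalizing rules.

    ``ceil(fraction * #non-input nodes)`` nodes are chosen uniformly;
    each gets a fresh canalizing rule over its unchanged regulators, so
    the topology is preserved exactly.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = (
        np.random.default_rng(rng_seed)
        if isinstance(rng_seed, (int, np.integer))
        else rng_seed
    )
    targets = [n for n in net.node_ids if n in net.rules and net.regulators[n]]
    n_alter = int(np.ceil(fraction * len(targets)))
    if n_alter == 0:
        return net
    chosen = rng.choice(len(targets), size=n_alter, replace=False)
    rules = dict(net.rules)
    for i in chosen:
        node = targets[int(i)]
        regs = list(net.regulators[node])
        table, _, _, _ = random_canalizing_function(len(regs), rng)
        rules[node] = truth_table_to_expression(regs, table)
    return BooleanNetwork(net.node_ids, rules)


def classification_consistency(
    net: BooleanNetwork,
    fraction: float,
    replicates: int,
    rng_seed: int = 0,
    budget: int = 1,
) -> float:
    """Mean fraction of internal nodes keeping their class under logic noise."""
    rng = np.random.default_rng(rng_seed)
    base = classify_nodes(net, budget=budget)
    agree = []
    for _ in range(replicates):
        perturbed = perturb_logic(net, fraction, rng)
        try:
            rep = classify_nodes(perturbed, budget=budget)
        except BnrevertError:
            continue
        common = [n for n in base.classes if n in rep.classes]
        if not common:
            continue
        agree.append(
            sum(base.classes[n] == rep.classes[n] for n in common) / len(common)
        )
    return float(np.mean(agree)) if agree else float("nan")


# --------------------------------------------------------------------------
# Synthetic templates

def random_canalizing_network(
    n_nodes: int,
    n_inputs: int = 2,
    n_outputs: int = 1,
    mean_in_degree: float = 2.0,
    rng_seed: int | np.random.Generator = 0,
) -> BooleanNetwork:
    """A random Boolean network with canalizing rules and fixed IO roles.

    Nodes n0..: the first ``n_inputs`` are inputs (no regulators), the
    last ``n_outputs`` are outputs (never regulate anyone).  Each
    non-input node draws 1 + Poisson(mean_in_degree - 1) distinct
    regulators from the non-output nodes; any non-output node left
    without a downstream target is wired into a random internal node so
    no node is isolated.
    """
    if n_nodes < n_inputs + n_outputs + 1:
        raise ValueError("need at least one internal node")
    rng = (
        np.random.default_rng(rng_seed)
        if isinstance(rng_seed, (int, np.integer))
        else rng_seed
    )
    names = [f"n{i}" for i in range(n_nodes)]
    inputs = names[:n_inputs]
    outputs = names[-n_outputs:]
    internals = names[n_inputs : n_nodes - n_outputs]
    sources = inputs + internals  # candidate regulators
    regulators: dict[str, list[str]] = {}
    for n in internals + outputs:
        k = 1 + int(rng.poisson(max(mean_in_degree - 1.0, 0.0)))
        k = min(k, len(sources) - (1 if n in internals else 0))
        pool = [s for s in sources if s != n]
        idx = rng.choice(len(pool), size=max(k, 1), replace=False)
        regulators[n] = [pool[int(i)] for i in idx]
    regulated_by_someone: set[str] = set()
    for regs in regulators.values():
        regulated_by_someone.update(regs)
    for s in sources:
        if s not in regulated_by_someone:
            pool = [n for n in internals + outputs if n != s]
            tgt = pool[int(rng.integers(len(pool)))]
            regulators[tgt].append(s)
    return _assign_random_rules(names, regulators, rng)


def default_templates(rng_seed: int = 12345, n_templates: int = 5) -> list[BooleanNetwork]:
    """Synthetic stand-ins for published signaling-network templates.

    Networks of 16-24 nodes with 2-4 sustained inputs, 2 outputs and
    mean in-degree about 2.5, the scale and density typical of curated
    signaling models whose degree sequences seed the configuration
    model.  The fixed default seed makes the template set a stable,
    reproducible reference.
    """
    rng = np.random.default_rng(rng_seed)
    sizes = [18, 20, 22, 24, 16]
    templates = []
    for i in range(n_templates):
        n = sizes[i % len(sizes)]
        templates.append(
            random_canalizing_network(
                n,
                n_inputs=2 + i % 3,
                n_outputs=2,
                mean_in_degree=2.5,
                rng_seed=rng,
            )
        )
    return templates


# --------------------------------------------------------------------------
# Ensemble study

@dataclass
class EnsembleResult:
    """Per-network measures plus cross-network correlations.

    ``table`` has one row per generated network (retained or not);
    measures are NaN for discarded networks.  ``correlations`` maps each
    measure pair to Pearson/Spearman r and p-values over retained
    networks.
    """

    table: pd.DataFrame
    correlations: dict[str, dict[str, float]]

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())


def ensemble_study(
    templates: list[BooleanNetwork],
    replicates: int = 100,
    samples: int = 1024,
    budget: int = 1,
    rng_seed: int = 0,
) -> EnsembleResult:
    """Generate configuration-model networks and correlate their measures.

    Per template, ``replicates`` networks are generated; those without a
    deterministic IO matching are discarded before measure computation.
    V, D, B_m and B_p are computed for each retained network, then
    Pearson and Spearman correlations of V against the other three.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for t_idx, template in enumerate(templates):
        for rep in range(replicates):
            net_seed = int(rng.integers(2 ** 31))
            row = {
                "template": t_idx,
                "replicate": rep,
                "seed": net_seed,
                "retained": False,
                "V": np.nan,
                "D": np.nan,
                "B_m": np.nan,
                "B_p": np.nan,
            }
            try:
                net = configuration_model(template, net_seed)
                wt = infer_io_matching(net)
            except BnrevertError:
                rows.append(row)
                continue
            if not wt.has_deterministic_profile:
                rows.append(row)
                continue
            report = classify_nodes(net, budget=budget, wt=wt)
            try:
                d, _, _ = redundancy(net, wt)
            except UndefinedMeasureError:
                rows.append(row)
                continue
            row.update(
                retained=True,
                V=reversibility(report),
                D=d,
                B_m=robustness_mutation(net, samples, net_seed),
                B_p=robustness_perturbation(net, samples, net_seed),
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    kept = table[table["retained"]]
    if kept.empty:
        raise UndefinedMeasureError("every generated network was discarded")
    correlations: dict[str, dict[str, float]] = {}
    for other in ("D", "B_m", "B_p"):
        pr, pp = stats.pearsonr(kept["V"], kept[other])
        sr, sp = stats.spearmanr(kept["V"], kept[other])
        correlations[f"V_vs_{other}"] = {
            "pearson_r": float(pr),
            "pearson_p": float(pp),
            "spearman_r": float(sr),
            "spearman_p": float(sp),
            "n": int(len(kept)),
        }
    return EnsembleResult(table, correlations)
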