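"""Reversibility V, redundancy D and robustness measures B_m, B_p."""

import itertools

import pytest

from bnrevert import (
    classify_nodes,
    infer_io_matching,
    measure_network,
    parse_network,
    redundancy,
    reversibility,
    robustness_mutation,
    robustness_perturbation,
)
from bnrevert.measures import UndefinedMeasureError
from bnrevert.reversion import ClassificationReport
from conftest import naive_all_attractors, naive_primary, random_nets


def naive_bm(net):
    """B_m straight from its formula with exhaustive basins (oracle)."""
    from bnrevert.network import evaluate_expression

    base = naive_primary(naive_all_attractors(net))
    a_o = set(base)
    total = 0.0
    for node in net.node_ids:
        for value in (1, 0):
            rules = dict(net.rules)
            rules[node] = ("const", value)
            from bnrevert.network import BooleanNetwork

            mutated = BooleanNetwork(net.node_ids, rules)
            a_k = set(naive_primary(naive_all_attractors(mutated)))
            total += len(a_o & a_k) / len(a_o)
    return total / (2 * net.n_nodes)


def naive_bp(net):
    """B_p straight from its formula over the full state space (oracle)."""
    from conftest import naive_attractor

    n = net.n_nodes
    same = 0
    for s in itertools.product((0, 1), repeat=n):
        a_s = naive_attractor(net, s)
        for k in range(n):
            flipped = s[:k] + (1 - s[k],) + s[k + 1 :]
            if naive_attractor(net, flipped) == a_s:
                same += 1
    return same / (n * 2 ** n)


class TestReversibility:
    def test_fig1(self, fig1):
        assert reversibility(classify_nodes(fig1)) == pytest.approx(0.8)

    def test_cascade_is_irreversible(self, cascade):
        assert reversibility(classify_nodes(cascade)) == 0.0

    def test_bladder_arithmetic(self):
        # 11 C3 among 46 internal nodes
        report = ClassificationReport(
            classes={f"n{i}": ("C3" if i < 11 else "C1") for i in range(46)},
            effects={f"n{i}": (True, True) for i in range(46)},
        )
        assert reversibility(report) == pytest.approx(1 - 11 / 46)

    def test_empty_classification_raises(self):
        with pytest.raises(UndefinedMeasureError):
            reversibility(ClassificationReport(classes={}, effects={}))


class TestRedundancy:
    def test_cascade(self, cascade):
        d, n_sp, n_p = redundancy(cascade)
        assert (d, n_sp, n_p) == (1.0, 2, 2)

    def test_fig1_path_counts(self, fig1):
        d, n_sp, n_p = redundancy(fig1)
        assert (d, n_sp, n_p) == (5.0, 10, 2)

    def test_undetermined_everywhere_is_undefined(self):
        net = parse_network("targets, factors\nA, !A\nO, (A & I) | (!A & !I)\n")
        wt = infer_io_matching(net)
        assert not wt.has_deterministic_profile
        with pytest.raises(UndefinedMeasureError):
            redundancy(net, wt)

    def test_second_disjoint_path_increases_nsp(self):
        one = parse_network("targets, factors\nA, I\nO, A\n")
        two = parse_network("targets, factors\nA, I\nB, I\nO, A | B\n")
        _, nsp_one, _ = redundancy(one)
        _, nsp_two, _ = redundancy(two)
        assert nsp_two > nsp_one


class TestRobustnessMutation:
    def test_self_activator_half(self):
        net = parse_network("A, A")
        assert robustness_mutation(net, 1024, seed=0) == pytest.approx(0.5)

    def test_tautology_rules_half(self):
        # GOF mutations retain the all-ones attractor, LOF mutations lose it
        net = parse_network("targets, factors\nA, A | !A\nB, B | !B\n")
        assert robustness_mutation(net, 1024, seed=0) == pytest.approx(0.5)

    def test_seed_determinism(self, fig1):
        a = robustness_mutation(fig1, 64, seed=9)
        assert a == robustness_mutation(fig1, 64, seed=9)

    def test_node_order_invariance(self):
        text_a = "targets, factors\nA, I\nB, A\nO, B\n"
        text_b = "targets, factors\nB, A\nO, B\nA, I\n"
        m_a = robustness_mutation(parse_network(text_a), 1024, seed=0)
        m_b = robustness_mutation(parse_network(text_b), 1024, seed=0)
        assert m_a == pytest.approx(m_b)

    def test_matches_formula_oracle_exhaustive(self):
        for net in random_nets(12, seed=71, n_min=4, n_max=7):
            ours = robustness_mutation(net, 2 ** net.n_nodes, seed=0)
            assert ours == pytest.approx(naive_bm(net))


class TestRobustnessPerturbation:
    def test_self_activator_zero(self):
        net = parse_network("A, A")
        assert robustness_perturbation(net, 1024, seed=0) == 0.0

    def test_tautology_one(self):
        net = parse_network("A, A | !A")
        assert robustness_perturbation(net, 1024, seed=0) == 1.0

    def test_bounds_and_order_invariance(self, fig1):
        b = robustness_perturbation(fig1, 1024, seed=0)
        assert 0.0 <= b <= 1.0
        swapped = parse_network(
            "targets, factors\nO, (E | C) & C\nE, A\nD, B\nC, A & D\nB, I\nA, I | B\n"
        )
        assert robustness_perturbation(swapped, 1024, seed=0) == pytest.approx(b)

    def test_matches_formula_oracle_exhaustive(self):
        for net in random_nets(12, seed=81, n_min=4, n_max=7):
            ours = robustness_perturbation(net, 2 ** net.n_nodes, seed=0)
            assert ours == pytest.approx(naive_bp(net))


class TestMeasureReport:
    def test_full_report_fields(self, fig1):
        rep = measure_network(fig1, n_samples=128, seed=5)
        assert rep.V == pytest.approx(0.8)
        assert rep.D == pytest.approx(5.0)
        assert rep.N_T == 1 and rep.n_internal == 5
        assert 0 <= rep.B_m <= 1 and 0 <= rep.B_p <= 1
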