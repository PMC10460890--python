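"""Prime implicants, expanded-network construction and LDOI closure."""

import itertools

import pytest

from bnrevert import (
    ConflictingInterventionError,
    apply_interventions,
    build_expanded,
    control,
    ldoi,
    parse_network,
    prime_implicants,
)
from bnrevert.network import parse_expression
from conftest import naive_all_attractors, random_nets


def PI(text, regs, negate=False):
    return prime_implicants(parse_expression(text), regs, negate=negate)


class TestPrimeImplicants:
    @pytest.mark.parametrize(
        "text,regs,negate,expected",
        [
            ("(E | C) & C", ["E", "C"], False, {frozenset({("C", 1)})}),
            ("I | B", ["I", "B"], False, {frozenset({("I", 1)}), frozenset({("B", 1)})}),
            ("A & D", ["A", "D"], True, {frozenset({("A", 0)}), frozenset({("D", 0)})}),
            ("A & D", ["A", "D"], False, {frozenset({("A", 1), ("D", 1)})}),
            ("!A", ["A"], False, {frozenset({("A", 0)})}),
            # XOR: all four two-literal primes on the ON side
            (
                "(A & !B) | (!A & B)",
                ["A", "B"],
                False,
                {
                    frozenset({("A", 1), ("B", 0)}),
                    frozenset({("A", 0), ("B", 1)}),
                },
            ),
        ],
    )
    def test_examples(self, text, regs, negate, expected):
        assert PI(text, regs, negate) == expected

    def test_constant_functions(self):
        assert PI("A | !A", ["A"]) == {frozenset()}
        assert PI("A | !A", ["A"], negate=True) == set()
        assert PI("1", []) == {frozenset()}
        assert PI("0", []) == set()

    def test_complete_prime_set_includes_consensus(self):
        # f = AB | !AC has the consensus term BC as a third prime
        got = PI("(A & B) | (!A & C)", ["A", "B", "C"])
        assert frozenset({("B", 1), ("C", 1)}) in got
        assert len(got) == 3


class TestBuildExpanded:
    def test_fig1_counts(self, fig1):
        ex = build_expanded(fig1)
        assert ex.n_literals == 14
        assert ex.n_composites == 2
        assert set(ex.composites) == {
            frozenset({("A", 1), ("D", 1)}),  # C=1 needs A AND D
            frozenset({("I", 0), ("B", 0)}),  # A=0 needs neither I nor B
        }

    def test_cascade_has_no_composites(self, cascade):
        ex = build_expanded(cascade)
        assert ex.n_literals == 6
        assert ex.n_composites == 0

    def test_node_count_at_least_double(self):
        """The expanded network has at least twice the original node count."""
        for net in random_nets(10, seed=5, n_min=4, n_max=8):
            ex = build_expanded(net)
            assert ex.n_nodes >= 2 * net.n_nodes

    def test_input_literals_have_no_incoming_edges(self, fig1):
        ex = build_expanded(fig1)
        assert ex.in_degree(("I", 0)) == 0
        assert ex.in_degree(("I", 1)) == 0

    def test_single_incoming_edge_marks_necessary_and_sufficient(self, fig1):
        # O = (E|C)&C reduces to C: exactly one parent each side
        ex = build_expanded(fig1)
        assert ex.in_degree(("O", 1)) == 1
        assert ex.in_degree(("O", 0)) == 1


class TestLDOI:
    def test_fig1_input_on_determines_output_on(self, fig1):
        ex = build_expanded(fig1)
        res = ldoi(ex, [("I", 1)])
        for lit in [("B", 1), ("A", 1), ("D", 1), ("C", 1), ("E", 1), ("O", 1)]:
            assert lit in res

    def test_fig1_lof_a_closure(self, fig1):
        ex = build_expanded(fig1)
        res = ldoi(ex, [("A", 0)])
        assert res.literals == frozenset({("A", 0), ("E", 0), ("C", 0), ("O", 0)})

    def test_empty_seeds_only_constant_literals(self, fig1):
        ex = build_expanded(fig1)
        assert ldoi(ex, []).literals == frozenset()
        fixed = apply_interventions(fig1, [control("B", 1)])
        res = ldoi(build_expanded(fixed), [])
        assert ("B", 1) in res  # constant rules root every closure

    def test_conflicting_seeds_raise(self, fig1):
        ex = build_expanded(fig1)
        with pytest.raises(ConflictingInterventionError):
            ldoi(ex, [("A", 0), ("A", 1)])

    def test_literal_contradicting_seed_is_excluded_and_flagged(self, fig1):
        # I=1 alone forces A=1; seeding A=0 as well must keep A=0, not add A=1
        ex = build_expanded(fig1)
        res = ldoi(ex, [("I", 1), ("A", 0)])
        assert ("A", 0) in res and ("A", 1) not in res
        assert ("A", 1) in res.conflicts

    def test_monotone_in_seeds(self, fig1):
        ex = build_expanded(fig1)
        small = ldoi(ex, [("B", 1)]).literals
        large = ldoi(ex, [("B", 1), ("E", 1)]).literals
        assert small <= large

    def test_soundness_against_attractor_oracle(self):
        """Every LDOI literal is stabilized in all attractors when seeds are held.

        Seeds are applied as rule-replacing fixations; all attractors of
        the fixed network (from every initial state) must show each LDOI
        node stabilized at its inferred bit.
        """
        import numpy as np

        rng = np.random.default_rng(11)
        for net in random_nets(60, seed=21, n_min=4, n_max=9):
            ex = build_expanded(net)
            names = net.node_ids
            seed_sets = [
                [(names[int(rng.integers(net.n_nodes))], int(rng.integers(2)))],
            ]
            a, b = rng.choice(net.n_nodes, size=2, replace=False)
            seed_sets.append(
                [(names[int(a)], int(rng.integers(2))), (names[int(b)], int(rng.integers(2)))]
            )
            for seeds in seed_sets:
                res = ldoi(ex, seeds)
                fixed = apply_interventions(net, [control(n, v) for n, v in seeds])
                basins = naive_all_attractors(fixed)
                for node, bit in res.literals:
                    idx = net.index[node]
                    for att in basins:
                        assert all(s[idx] == bit for s in att), (
                            f"literal {(node, bit)} not stabilized"
                        )
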