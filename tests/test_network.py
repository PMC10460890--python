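"""Rule parsing, roles, interventions and synchronous dynamics."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from bnrevert import (
    Attractor,
    BooleanNetwork,
    ConflictingInterventionError,
    DuplicateTargetError,
    EmptyNetworkError,
    IsolatedNodeError,
    RuleSyntaxError,
    UnknownNodeError,
    apply_interventions,
    control,
    find_attractor,
    gof,
    lof,
    node_roles,
    parse_network,
    sample_attractors,
    synchronous_step,
)
from bnrevert.network import (
    expression_to_string,
    network_to_text,
    parse_expression,
    evaluate_expression,
)

from conftest import naive_all_attractors, naive_attractor, random_nets


def state_of(net, **kw):
    return tuple(kw.get(n, 0) for n in net.node_ids)


class TestParsing:
    def test_fig1_shape(self, fig1):
        assert fig1.n_nodes == 7
        inputs, outputs, internals = node_roles(fig1)
        assert inputs == ("I",)
        assert outputs == ("O",)
        assert set(internals) == {"A", "B", "C", "D", "E"}

    def test_duplicate_target_raises(self):
        text = "targets, factors\nA, B\nA, !B\n"
        with pytest.raises(DuplicateTargetError):
            parse_network(text)

    def test_empty_file_raises(self):
        with pytest.raises(EmptyNetworkError):
            parse_network("targets, factors\n")

    def test_unparseable_expression_raises(self):
        with pytest.raises(RuleSyntaxError):
            parse_network("targets, factors\nA, B &\n")
        with pytest.raises(RuleSyntaxError):
            parse_network("targets, factors\nA, (B\n")

    def test_self_regulated_single_node(self):
        net = parse_network("A, !A")
        assert net.node_ids == ("A",)
        assert net.inputs == ()

    def test_constant_rule_node_is_not_an_input(self):
        net = parse_network("targets, factors\nA, 1\nB, A\n")
        assert net.inputs == ()

    def test_roundtrip_is_bit_exact(self, fig1, cascade):
        for net in (fig1, cascade):
            text = network_to_text(net)
            again = parse_network(text)
            assert again == net
            assert network_to_text(again) == text

    @settings(max_examples=100, derandomize=True)
    @given(st.recursive(
        st.sampled_from([("var", "x"), ("var", "y"), ("const", 0), ("const", 1)]),
        lambda sub: st.one_of(
            st.tuples(st.just("not"), sub),
            st.tuples(st.just("and"), sub, sub),
            st.tuples(st.just("or"), sub, sub),
        ),
        max_leaves=12,
    ))
    def test_expression_render_parse_roundtrip(self, expr):
        """Rendering then reparsing preserves the truth table."""
        text = expression_to_string(expr)
        again = parse_expression(text)
        for x in (0, 1):
            for y in (0, 1):
                env = {"x": x, "y": y}
                assert evaluate_expression(expr, env) == evaluate_expression(again, env)


class TestRoles:
    def test_cascade_roles(self, cascade):
        assert node_roles(cascade) == (("I",), ("O",), ("A",))

    def test_isolated_node_raises(self):
        net = BooleanNetwork(["A", "B", "C"], {"B": ("var", "A")})
        with pytest.raises(IsolatedNodeError):
            node_roles(net)


class TestInterventions:
    def test_rule_replaced_by_constant(self, fig1):
        mutated = apply_interventions(fig1, [lof("A")])
        assert mutated.rules["A"] == ("const", 0)
        assert mutated.regulators["A"] == ()
        assert fig1.rules["A"] != ("const", 0)  # original untouched

    def test_empty_set_is_identity(self, fig1):
        assert apply_interventions(fig1, []) is fig1

    def test_conflict_raises(self, fig1):
        with pytest.raises(ConflictingInterventionError):
            apply_interventions(fig1, [control("B", 0), control("B", 1)])

    def test_unknown_node_raises(self, fig1):
        with pytest.raises(UnknownNodeError):
            apply_interventions(fig1, [control("Z", 1)])

    def test_gof_lof_value_constraints(self):
        with pytest.raises(ValueError):
            from bnrevert import Intervention

            Intervention("A", 0, "mutation_GOF")

    def test_intervened_node_stays_fixed_after_step(self, fig1):
        mutated = apply_interventions(fig1, [gof("B"), lof("D")])
        s = state_of(fig1, I=1)
        for _ in range(5):
            s = synchronous_step(mutated, s)
            assert s[fig1.index["B"]] == 1
            assert s[fig1.index["D"]] == 0


class TestDynamics:
    def test_fig1_single_step(self, fig1):
        s = state_of(fig1, I=1)
        nxt = synchronous_step(fig1, s)
        assert nxt == state_of(fig1, I=1, A=1, B=1)

    def test_all_ones_is_fixed_point(self, fig1):
        ones = tuple([1] * 7)
        assert synchronous_step(fig1, ones) == ones

    def test_fig1_converges_to_all_ones_from_I1(self, fig1):
        att = find_attractor(fig1, state_of(fig1, I=1))
        assert att.L == 1
        assert att.states[0] == tuple([1] * 7)

    def test_fig1_converges_to_all_zeros_from_I0(self, fig1):
        att = find_attractor(fig1, state_of(fig1))
        assert att == Attractor(((0,) * 7,))

    def test_negation_oscillator(self):
        net = parse_network("A, !A")
        att = find_attractor(net, (0,))
        assert att.L == 2
        assert att.states == ((0,), (1,))

    def test_find_attractor_idempotent(self, fig1):
        att = find_attractor(fig1, state_of(fig1, I=1, C=1))
        for s in att.states:
            assert find_attractor(fig1, s) == att


class TestSampling:
    def test_self_activator_two_point_attractors(self):
        net = parse_network("A, A")
        samp = sample_attractors(net, 4, seed=0)
        assert samp.exhaustive
        assert [a.states for a in samp.attractors] == [((0,),), ((1,),)]
        assert samp.basin_counts == [1, 1]

    def test_same_seed_same_result(self, fig1):
        a = sample_attractors(fig1, 50, seed=42)
        b = sample_attractors(fig1, 50, seed=42)
        assert a.attractors == b.attractors
        assert a.basin_counts == b.basin_counts

    def test_fig1_sampling_matches_exhaustive_enumeration(self, fig1):
        samp = sample_attractors(fig1, 1024, seed=7)  # 2^7 states -> exhaustive
        brute = naive_all_attractors(fig1)
        assert {a.states for a in samp.attractors} == set(brute)
        for a, b in zip(samp.attractors, samp.basin_counts):
            assert brute[a.states] == b

    @pytest.mark.parametrize("seed", [3, 17])
    def test_random_networks_match_brute_force(self, seed):
        """Exhaustive sampling equals the naive follow-every-state oracle."""
        for net in random_nets(12, seed, n_min=4, n_max=8):
            samp = sample_attractors(net, 2 ** net.n_nodes, seed=0)
            brute = naive_all_attractors(net)
            assert {a.states for a in samp.attractors} == set(brute)
            assert sum(samp.basin_counts) == 2 ** net.n_nodes
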