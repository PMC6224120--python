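import itertools

import pytest

from bnts.core import (
    BooleanNetwork,
    Clause,
    ReachResult,
    clause_str,
    meta_successors,
    parse_clause,
    reachable,
    successors,
    support_consistent,
    upstream_closure,
)

Z, O, B = frozenset({0}), frozenset({1}), frozenset({0, 1})


def bn_of(nodes, **funcs):
    return BooleanNetwork(
        tuple(nodes), {v: tuple(parse_clause(c) for c in cs) for v, cs in funcs.items()}
    )


def closure(bn, x, clamp=None):
    seen, stack = {tuple(x)}, [tuple(x)]
    while stack:
        cur = stack.pop()
        for nxt in successors(bn, cur, clamp):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


class TestSuccessors:
    def test_any_subset_update(self):
        bn = bn_of("ab", a=["b"], b=["a"])
        assert successors(bn, (0, 1)) == {(1, 1), (0, 0), (1, 0)}

    def test_fixpoint_has_no_successors(self):
        bn = bn_of("ab", a=["a"], b=["b"])
        assert successors(bn, (1, 0)) == set()

    def test_clamped_node_never_changes(self):
        bn = bn_of("ab", a=["b"], b=[])
        assert successors(bn, (0, 1), clamp={"a": 0}) == set()

    def test_state_violating_clamp_rejected(self):
        bn = bn_of("ab", a=["b"], b=[])
        with pytest.raises(ValueError, match="clamping"):
            successors(bn, (1, 1), clamp={"a": 0})

    def test_sync_and_async_are_subrelations(self):
        bn = bn_of("abc", a=["b"], b=["!c"], c=["a&b"])
        for x in itertools.product((0, 1), repeat=3):
            succ = successors(bn, x)
            from bnts.core import _Compiled

            dyn = _Compiled(bn, None)
            sync = tuple(dyn.target(i, x) for i in range(3))
            if sync != x:
                assert sync in succ
            for i in range(3):
                t = dyn.target(i, x)
                if t != x[i]:
                    y = list(x)
                    y[i] = t
                    assert tuple(y) in succ


class TestReachable:
    def test_reflexive_goal(self):
        bn = bn_of("ab", a=["b"], b=["a"])
        assert reachable(bn, (0, 1), {"a": 0, "b": 1}) is ReachResult.TRUE

    def test_one_step_negation(self):
        bn = bn_of("ab", a=["!a"], b=[])
        assert reachable(bn, (0, 0), {"a": 1}) is ReachResult.TRUE

    def test_unreachable_is_false(self):
        # b unregulated stays 0, so f_a = b can never fire
        bn = bn_of("ab", a=["b"], b=[])
        assert reachable(bn, (0, 0), {"a": 1}) is ReachResult.FALSE

    def test_budget_exceeded_distinct_from_false(self):
        # a..d toggle freely (16 reachable states); e is frozen, so e=1 is
        # unreachable: a tight budget must report the truncation, not False
        bn = bn_of("abcde", a=["!a"], b=["!b"], c=["!c"], d=["!d"], e=[])
        x = (0, 0, 0, 0, 0)
        assert reachable(bn, x, {"e": 1}, budget=3) is ReachResult.BUDGET_EXCEEDED
        assert reachable(bn, x, {"e": 1}) is ReachResult.FALSE

    def test_unknown_goal_node_rejected(self):
        bn = bn_of("ab", a=["b"], b=[])
        with pytest.raises(ValueError, match="unknown node"):
            reachable(bn, (0, 0), {"zz": 1})

    def test_agrees_with_explicit_transitive_closure(self):
        import networkx as nx

        bn = bn_of("abc", a=["b", "!c"], b=["a&c"], c=["!a"])
        g = nx.DiGraph()
        states = list(itertools.product((0, 1), repeat=3))
        g.add_nodes_from(states)
        for x in states:
            for y in successors(bn, x):
                g.add_edge(x, y)
        for x in states:
            reach_nx = nx.descendants(g, x) | {x}
            for y in states:
                expected = ReachResult.TRUE if y in reach_nx else ReachResult.FALSE
                assert reachable(bn, x, dict(zip("abc", y))) is expected


class TestMetaStates:
    def test_fully_widened_has_no_successors(self):
        bn = bn_of("ab", a=["b"], b=["a"])
        assert meta_successors(bn, (B, B)) == set()

    def test_single_widening(self):
        bn = bn_of("ab", a=["b"], b=[])
        assert meta_successors(bn, (Z, O)) == {(B, O)}

    def test_clamped_component_never_widens(self):
        bn = bn_of("ab", a=["b"], b=[])
        assert meta_successors(bn, (Z, O), clamp={"a": 0}) == set()

    def test_chain_length_bounded_by_n(self):
        bn = bn_of("abc", a=["b"], b=["c"], c=["!c"])
        u = (Z, Z, Z)
        length = 0
        while True:
            nxt = meta_successors(bn, u)
            if not nxt:
                break
            u = sorted(nxt)[0]
            length += 1
        assert length <= 3


class TestSupportConsistency:
    def test_reflexive(self):
        bn = bn_of("ab", a=["b"], b=["a"])
        assert support_consistent(bn, (0, 1), (0, 1))

    def test_partial_target(self):
        bn = bn_of("ab", a=["b"], b=[])
        assert support_consistent(bn, (0, 1), {"a": 1})
        assert not support_consistent(bn, (0, 0), {"a": 1})

    def test_clamp_blocks_widening(self):
        bn = bn_of("ab", a=["b"], b=["a"])
        assert not support_consistent(bn, (0, 0), (1, 0), clamp={"a": 0})

    def test_frozen_gap_pair_consistent_but_unreachable(self):
        bn = bn_of("ab", a=["a&b"], b=["!a"])
        x, y = (1, 0), (1, 1)
        assert support_consistent(bn, x, y)
        assert reachable(bn, x, dict(zip("ab", y))) is ReachResult.FALSE

    def test_soundness_on_small_network(self):
        bn = bn_of("abc", a=["b", "!c"], b=["a&c"], c=["!a"])
        for x in itertools.product((0, 1), repeat=3):
            for y in closure(bn, x):
                assert support_consistent(bn, x, y)


class TestTextFormat:
    def test_roundtrip(self):
        bn = bn_of("abc", a=["b&!c", "c"], b=["a"])
        again = BooleanNetwork.from_lines(bn.to_lines(), nodes=bn.nodes)
        assert again.hyperedges() == bn.hyperedges()

    def test_clause_string_forms(self):
        c = parse_clause("x&!y")
        assert c == Clause({("x", 1), ("y", -1)})
        assert parse_clause(clause_str(c)) == c

    def test_duplicate_hyperedge_rejected(self):
        with pytest.raises(ValueError, match="duplicate hyper-edge"):
            BooleanNetwork(("a", "b"), {"a": (parse_clause("b"), parse_clause("b"))})

    def test_contradictory_clause_rejected(self):
        with pytest.raises(ValueError, match="polarities"):
            BooleanNetwork(("a", "b"), {"a": (Clause({("b", 1), ("b", -1)}),)})


def test_upstream_closure_is_ancestor_set():
    bn = bn_of("abcde", b=["a"], c=["b"], e=["d"])
    assert upstream_closure(bn, ["c"]) == {"a", "b", "c"}
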