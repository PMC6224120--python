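import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnts.analysis import (
    AggregatedNetwork,
    BNFamily,
    aggregate,
    downstream_set,
    family_auroc,
    family_similarity,
    hyperedge_frequencies,
    jaccard,
    node_centrality,
    rmse_ratio,
    similarity_matrix,
    tpr_fpr,
)
from bnts.core import BooleanNetwork, parse_clause
from bnts.pkn import PKN


def bn_of(nodes, **funcs):
    return BooleanNetwork(
        tuple(nodes), {v: tuple(parse_clause(c) for c in cs) for v, cs in funcs.items()}
    )


@pytest.fixture
def small_family():
    a = bn_of("xyz", y=["x"], z=["y"])
    b = bn_of("xyz", y=["x"], z=["!x"])
    c = bn_of("xyz", y=["x"])
    return BNFamily("demo", (a, b, c))


class TestAggregation:
    def test_frequencies(self, small_family):
        freqs = hyperedge_frequencies(small_family)
        assert freqs[("y", parse_clause("x"))] == 1.0
        assert freqs[("z", parse_clause("y"))] == pytest.approx(1 / 3)
        assert ("z", parse_clause("x")) not in freqs

    def test_threshold_is_strict(self):
        fam = BNFamily(
            "f",
            tuple(
                bn_of("xyz", y=["x"], z=["y"]) for _ in range(3)
            )
            + tuple(bn_of("xyz", y=["x"]) for _ in range(7)),
        )
        agg = aggregate(fam, threshold=0.3)
        assert ("y", parse_clause("x")) in agg.hyperedges  # freq 1.0
        assert ("z", parse_clause("y")) not in agg.hyperedges  # freq exactly 0.3
        kept = aggregate(fam, threshold=0.29)
        assert ("z", parse_clause("y")) in kept.hyperedges  # 0.3 > 0.29

    def test_zero_threshold_keeps_union(self, small_family):
        agg = aggregate(small_family, threshold=0.0)
        union = set().union(*(bn.hyperedges() for bn in small_family))
        assert agg.hyperedge_set() == union

    def test_thresholds_monotone(self, small_family):
        low = aggregate(small_family, 0.1).hyperedge_set()
        high = aggregate(small_family, 0.5).hyperedge_set()
        assert high <= low

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            BNFamily("empty", ())

    def test_table_and_dot_render(self, small_family):
        agg = aggregate(small_family, 0.0)
        table = agg.to_table()
        assert set(table.columns) == {"target", "clause", "frequency"}
        dot = agg.to_dot({"x": "stimulus"})
        assert dot.startswith("digraph") and '"x" -> "y"' in dot


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0

    def test_hand_value(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_disjoint_and_empty(self):
        assert jaccard({1}, {2}) == 0.0
        assert jaccard(set(), set()) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 8)), st.sets(st.integers(0, 8)))
    def test_symmetric_bounded_identity(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        assert (j == 1.0) == (a == b)


class TestFamilySimilarity:
    def test_identical_family_scores_one(self):
        bn = bn_of("xy", y=["x"])
        fam = BNFamily("f", (bn, bn))
        assert family_similarity(bn.hyperedges(), fam) == 1.0

    def test_arithmetic_mean(self):
        gold = {("y", parse_clause("x")), ("z", parse_clause("y")),
                ("z", parse_clause("x"))}
        a = bn_of("xyz", y=["x"])  # jaccard 1/3
        b = bn_of("xyz", y=["x"], z=["y", "x"])  # jaccard 1.0
        fam = BNFamily("f", (a, b))
        assert family_similarity(gold, fam) == pytest.approx((1 / 3 + 1.0) / 2)

    def test_matrix_diagonal_uses_own_aggregate(self, small_family):
        other = BNFamily("other", (bn_of("xyz", z=["!y"]),))
        mat = similarity_matrix([small_family, other], threshold=0.0)
        assert mat.shape == (2, 2)
        assert mat.loc["other", "other"] == 1.0
        assert 0 <= mat.loc["demo", "other"] <= 1


class TestRatios:
    def test_rmse_ratio_values(self):
        assert rmse_ratio(0.3, 0.3) == 1.0
        assert rmse_ratio(0.3, 0.6) == 0.5
        assert rmse_ratio(0.0, 0.0) == 1.0

    def test_model_zero_with_positive_discrete_impossible(self):
        with pytest.raises(ValueError, match="impossible"):
            rmse_ratio(0.2, 0.0)


class TestTprFpr:
    def test_perfect_inference(self):
        std = {1, 2}
        assert tpr_fpr(std, std, set(range(6))) == (1.0, 0.0)

    def test_hand_values(self):
        universe = set(range(10))
        standard = {0, 1, 2, 3}
        inferred = {0, 1, 2, 8, 9}
        tpr, fpr = tpr_fpr(standard, inferred, universe)
        assert tpr == 0.75 and fpr == pytest.approx(2 / 6)

    def test_empty_inferred(self):
        assert tpr_fpr({1}, set(), {1, 2}) == (0.0, 0.0)

    def test_full_universe_inferred_is_one_one(self):
        u = set(range(5))
        assert tpr_fpr({0, 1}, u, u) == (1.0, 1.0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            tpr_fpr(set(), {1}, {1, 2})
        with pytest.raises(ValueError):
            tpr_fpr({1, 2}, {1}, {1, 2})


class TestAuroc:
    def test_perfect_and_diagonal(self):
        assert family_auroc([(0.0, 1.0)]) == 1.0
        assert family_auroc([(0.5, 0.5)]) == 0.5

    def test_trapezoid_hand_value(self):
        # trapezoids (0,0)->(0.2,0.8)->(1,1): 0.2*0.4 + 0.8*0.9
        assert family_auroc([(0.2, 0.8)]) == pytest.approx(0.80)

    def test_invariant_to_duplication_and_order(self):
        pts = [(0.2, 0.8), (0.6, 0.9), (0.1, 0.4)]
        a = family_auroc(pts)
        assert family_auroc(pts[::-1]) == a
        assert family_auroc(pts + pts) == a

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            family_auroc([(1.2, 0.5)])


class TestGraphMeasures:
    def test_downstream_chain(self):
        agg = AggregatedNetwork(
            {("b", parse_clause("a")): 1.0, ("c", parse_clause("b")): 1.0}, 0.0
        )
        assert downstream_set(agg, "a") == {"b", "c"}

    def test_downstream_excludes_root_in_cycle(self):
        agg = AggregatedNetwork(
            {("b", parse_clause("a")): 1.0, ("a", parse_clause("b")): 1.0}, 0.0
        )
        assert downstream_set(agg, "a") == {"b"}

    def test_downstream_of_sink_is_empty(self):
        agg = AggregatedNetwork({("b", parse_clause("a")): 1.0}, 0.0)
        assert downstream_set(agg, "b") == frozenset()

    def test_downstream_on_pkn(self):
        pkn = PKN(frozenset("abc"), frozenset({("a", "b", 1), ("b", "c", -1)}), {})
        assert downstream_set(pkn, "a") == {"b", "c"}

    def test_unknown_root_rejected(self):
        agg = AggregatedNetwork({("b", parse_clause("a")): 1.0}, 0.0)
        with pytest.raises(ValueError, match="root"):
            downstream_set(agg, "zz")

    def test_centrality_chain_middle_is_one(self):
        agg = AggregatedNetwork(
            {("b", parse_clause("a")): 1.0, ("c", parse_clause("b")): 1.0}, 0.0
        )
        assert node_centrality(agg, "b") == 1.0
        assert node_centrality(agg, "a") == 0.0
        assert node_centrality(agg, "c") == 0.0

    def test_centrality_star_hub_is_maximal(self):
        hes = {("h", parse_clause(s)): 1.0 for s in ("a", "b")}
        hes.update({(t, parse_clause("h")): 1.0 for t in ("x", "y")})
        agg = AggregatedNetwork(hes, 0.0)
        hub = node_centrality(agg, "h")
        assert hub == max(node_centrality(agg, v) for v in agg.nodes)
        assert hub == 1.0  # every connected s-t pair routes through h
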