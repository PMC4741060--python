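"""Interval tree and forest: structure invariants and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from intervaltree import IntervalTree as LibIntervalTree

from gjoin.intervals import (
    GenomicInterval,
    OpCounter,
    build_forest,
    build_interval_tree,
    query_forest,
    query_interval_tree,
    spans_overlap,
)


def linear_scan(items, q):
    """Brute-force overlap filter: the oracle every query is checked against."""
    qs, qe = q
    return {payload for (s, e), payload in items if max(s, qs) <= min(e, qe)}


def walk_nodes(node):
    if node is None:
        return
    yield node
    yield from walk_nodes(node.left)
    yield from walk_nodes(node.right)


def assert_node_invariants(tree, items):
    """Full-traversal structural soundness check."""
    seen = []
    for node in walk_nodes(tree.root):
        for (s, e), payload in node.overlaps:
            assert s <= node.key <= e, "overlap-list span must straddle the key"
            seen.append(((s, e), payload))
        for child, side in ((node.left, "left"), (node.right, "right")):
            for sub in walk_nodes(child):
                for (s, e), _ in sub.overlaps:
                    if side == "left":
                        assert e < node.key
                    else:
                        assert s > node.key
    assert sorted(map(repr, seen)) == sorted(map(repr, items)), \
        "tree must store each input interval exactly once"
    assert tree.size == len(items)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5)

    def test_overlap_is_closed_and_chrom_exact(self):
        a = GenomicInterval("chr1", 20, 25)
        assert a.overlaps(GenomicInterval("chr1", 25, 30))  # shared endpoint
        assert not a.overlaps(GenomicInterval("chr1", 26, 30))
        assert not a.overlaps(GenomicInterval("1", 20, 25))  # no aliasing


class TestBuild:
    def test_empty_input(self):
        tree = build_interval_tree([])
        assert tree.root is None and tree.size == 0
        assert query_interval_tree(tree, (1, 100)) == set()

    def test_five_interval_example_structure(self, fixtures):
        # root overlap list holds exactly [7,15]; the left subtree holds
        # only [1,5] (contents are asserted, never key values)
        items = [(span, span) for span in fixtures["tree_intervals"]]
        tree = build_interval_tree(items)
        assert [p for _, p in tree.root.overlaps] == [(7, 15)]
        left_payloads = [
            p for node in walk_nodes(tree.root.left) for _, p in node.overlaps
        ]
        assert left_payloads == [(1, 5)]
        assert_node_invariants(tree, items)

    def test_invariants_on_random_build(self):
        rng = np.random.default_rng(42)
        items = []
        for i in range(200):
            s = int(rng.integers(1, 5000))
            items.append(((s, s + int(rng.integers(0, 300))), i))
        tree = build_interval_tree(items)
        assert_node_invariants(tree, items)

    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError, match=r"\[9, 4\]"):
            build_interval_tree([((9, 4), 0)])

    def test_duplicates_all_stored_and_returned(self):
        items = [((10, 20), i) for i in range(5)]
        tree = build_interval_tree(items)
        assert tree.size == 5
        assert query_interval_tree(tree, (15, 15)) == {0, 1, 2, 3, 4}


class TestQuery:
    def test_five_interval_example_query(self, fixtures):
        items = [(span, span) for span in fixtures["tree_intervals"]]
        tree = build_interval_tree(items)
        got = query_interval_tree(tree, fixtures["tree_query"])
        assert got == fixtures["tree_query_expected"]

    def test_random_queries_match_linear_scan(self):
        rng = np.random.default_rng(7)
        items = []
        for i in range(500):
            s = int(rng.integers(1, 20_000))
            items.append(((s, s + int(rng.integers(0, 800))), i))
        tree = build_interval_tree(items)
        for _ in range(100):
            qs = int(rng.integers(1, 20_000))
            q = (qs, qs + int(rng.integers(0, 800)))
            assert query_interval_tree(tree, q) == linear_scan(items, q)

    def test_matches_intervaltree_library(self):
        # independent cross-check against a third-party interval tree
        rng = np.random.default_rng(13)
        items = []
        lib = LibIntervalTree()
        for i in range(300):
            s = int(rng.integers(1, 10_000))
            e = s + int(rng.integers(0, 400))
            items.append(((s, e), i))
            lib.addi(s, e + 1, i)  # library is half-open
        tree = build_interval_tree(items)
        for _ in range(50):
            qs = int(rng.integers(1, 10_000))
            qe = qs + int(rng.integers(0, 400))
            expected = {iv.data for iv in lib.overlap(qs, qe + 1)}
            assert query_interval_tree(tree, (qs, qe)) == expected

    def test_completeness_every_stored_interval_finds_itself(self):
        rng = np.random.default_rng(99)
        items = []
        for i in range(150):
            s = int(rng.integers(1, 3000))
            items.append(((s, s + int(rng.integers(0, 100))), i))
        tree = build_interval_tree(items)
        for span, payload in items:
            assert payload in query_interval_tree(tree, span)

    def test_rejects_inverted_query(self):
        tree = build_interval_tree([((1, 5), 0)])
        with pytest.raises(ValueError):
            query_interval_tree(tree, (7, 2))

    def test_key_independence(self):
        # correctness never depends on the key-choice convention
        rng = np.random.default_rng(21)
        items = []
        for i in range(250):
            s = int(rng.integers(1, 8000))
            items.append(((s, s + int(rng.integers(0, 300))), i))

        def leftmost(routed):
            return min(s for (s, _), _ in routed)

        def skewed(routed):
            lo = min(s for (s, _), _ in routed)
            hi = max(e for (_, e), _ in routed)
            return lo + (hi - lo) // 3

        default_tree = build_interval_tree(items)
        for rule in (leftmost, skewed):
            other = build_interval_tree(items, midpoint=rule)
            assert_node_invariants(other, items)
            for _ in range(40):
                qs = int(rng.integers(1, 8000))
                q = (qs, qs + int(rng.integers(0, 300)))
                assert query_interval_tree(other, q) == query_interval_tree(
                    default_tree, q
                )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        spans=st.lists(
            st.tuples(st.integers(1, 1000), st.integers(0, 200)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=60,
        ),
        q=st.tuples(st.integers(1, 1200), st.integers(0, 200)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
    )
    def test_property_query_equals_linear_scan(self, spans, q):
        items = list(enumerate(spans))
        items = [(span, i) for i, span in items]
        tree = build_interval_tree(items)
        assert query_interval_tree(tree, q) == linear_scan(items, q)

    def test_point_query_cost_sublinear(self):
        # instrumented surrogate for the logarithmic search bound
        rng = np.random.default_rng(3)
        n = 10_000
        items = []
        for i in range(n):
            s = int(rng.integers(1, 1_000_000))
            items.append(((s, s + int(rng.integers(50, 200))), i))
        tree = build_interval_tree(items)
        counter = OpCounter()
        n_queries = 200
        for _ in range(n_queries):
            p = int(rng.integers(1, 1_000_000))
            query_interval_tree(tree, (p, p), counter=counter)
        assert counter.nodes / n_queries < 0.05 * n


class TestForest:
    def test_single_chromosome(self):
        forest = build_forest(
            [(GenomicInterval("chr3", 1, 10), 0), (GenomicInterval("chr3", 5, 9), 1)]
        )
        assert set(forest.trees) == {"chr3"}
        assert len(forest) == 2

    def test_worked_gene_keys(self):
        # the two-gene key table: {(chr3,100,1000): 0, (chr3,4000,5000): 1}
        forest = build_forest(
            [(GenomicInterval("chr3", 100, 1000), 0),
             (GenomicInterval("chr3", 4000, 5000), 1)]
        )
        assert len(forest.trees["chr3"]) == 2
        assert query_forest(forest, GenomicInterval("chr3", 150, 250)) == {0}
        assert query_forest(forest, GenomicInterval("chr4", 3000, 3100)) == set()
        assert query_forest(forest, GenomicInterval("chr1", 1000, 1100)) == set()

    def test_per_chromosome_partitioning(self):
        rng = np.random.default_rng(11)
        items = []
        counts = {"chr1": 0, "chr2": 0, "chrX": 0}
        for i in range(300):
            chrom = ("chr1", "chr2", "chrX")[int(rng.integers(0, 3))]
            s = int(rng.integers(1, 5000))
            items.append((GenomicInterval(chrom, s, s + 10), i))
            counts[chrom] += 1
        forest = build_forest(items)
        assert {c: forest.trees[c].size for c in counts} == counts
        assert len(forest) == 300

    def test_absent_chromosomes_have_no_tree(self):
        forest = build_forest([(GenomicInterval("chr1", 1, 5), 0)])
        assert "chr2" not in forest.trees
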