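"""Tests for queue-based growth enumeration: the per-seed size bound,
single-seed family listing, whole-graph enumeration, the sampling
heuristic, and agreement with the brute-force oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scwib.enumeration import (
    enumerate_all,
    list_gene_family,
    max_cluster_size_bound,
)
from scwib.graph_model import (
    ScwibParams,
    SimilarityGraph,
    brute_force_scwibs,
    is_scwib,
    partition_edges,
)

from conftest import random_similarity_graph, strong_clique, strong_path


class TestMaxClusterSizeBound:
    @pytest.mark.parametrize(
        "d,s,expected", [(0, 0.25, 1), (1, 0.25, 2), (2, 0.25, 4), (3, 0.25, 5)]
    )
    def test_closed_form(self, d, s, expected):
        assert max_cluster_size_bound(d, s) == expected

    @pytest.mark.parametrize("d", range(0, 12))
    @pytest.mark.parametrize("s", [0.1, 0.25, 0.35, 0.5])
    def test_bound_is_tight_against_the_degree_condition(self, d, s):
        """m is the largest N such that degree d can meet (1-s)N - 1."""
        m = max_cluster_size_bound(d, s)
        assert d >= (1 - s) * m - 1 - 1e-9
        assert d < (1 - s) * (m + 1) - 1 - 1e-9

    def test_alternative_printed_formula_differs(self):
        # kept for comparison only: collapses as s -> 0
        assert max_cluster_size_bound(10, 0.1, use_printed_bound=True) == 2
        assert max_cluster_size_bound(10, 0.1) == 12


class TestListGeneFamily:
    def test_isolated_vertex_yields_only_its_singleton(self, params):
        g = SimilarityGraph.from_edges([], vertices=["solo"])
        part = partition_edges(g, params)
        out = list_gene_family("solo", part, params)
        assert out.member_sets() == {frozenset({"solo"})}

    def test_triangle_seed_reaches_all_supersets(self, params):
        g = strong_clique(3)
        part = partition_edges(g, params)
        v = sorted(g.vertices)
        out = list_gene_family(v[0], part, params)
        assert out.member_sets() == {
            frozenset({v[0]}), frozenset({v[0], v[1]}),
            frozenset({v[0], v[2]}), frozenset({v[0], v[1], v[2]}),
        }

    def test_path_endpoint_capped_by_size_bound(self, params):
        g = strong_path(5)
        part = partition_edges(g, params)
        v = sorted(g.vertices)
        out = list_gene_family(v[0], part, params)
        assert out.member_sets() == {
            frozenset({v[0]}), frozenset({v[0], v[1]}),
        }

    def test_every_family_contains_the_seed(self, params):
        g = random_similarity_graph(seed=5, n=10, p_edge=0.5)
        part = partition_edges(g, params)
        for seed_vertex in sorted(g.vertices):
            for c in list_gene_family(seed_vertex, part, params):
                assert seed_vertex in c.members

    def test_heuristic_requires_positive_budget(self, params):
        g = strong_clique(3)
        part = partition_edges(g, params)
        with pytest.raises(ValueError, match="budget"):
            list_gene_family(sorted(g.vertices)[0], part, params, mode="heuristic")

    def test_literal_last_vertex_rule_misses_star_growth(self):
        """Growing a star from its hub stalls under the literal rule:
        after hub+leaf the frontier of the leaf is empty, while the
        default any-member expansion reaches the valid hub+2-leaves set."""
        params = ScwibParams(U=0.7, W=0.6, s=0.5)
        g = SimilarityGraph.from_edges(
            [("c", "l1", 0.8), ("c", "l2", 0.8), ("c", "l3", 0.8)]
        )
        part = partition_edges(g, params)
        target = frozenset({"c", "l1", "l2"})
        assert is_scwib(target, part, params)
        full = list_gene_family("c", part, params).member_sets()
        literal = list_gene_family(
            "c", part, params, last_vertex_only=True
        ).member_sets()
        assert target in full
        assert target not in literal
        assert literal <= full


class TestEnumerateAll:
    def test_empty_graph(self, params):
        assert len(enumerate_all(SimilarityGraph(), params)) == 0

    def test_two_disjoint_strong_edges(self, params):
        g = SimilarityGraph.from_edges([("a", "b", 0.8), ("c", "d", 0.9)])
        got = enumerate_all(g, params).member_sets()
        assert got == {
            frozenset({"a"}), frozenset({"b"}), frozenset({"c"}), frozenset({"d"}),
            frozenset({"a", "b"}), frozenset({"c", "d"}),
        }

    def test_singleton_cover_of_all_vertices(self, params):
        g = random_similarity_graph(seed=2, n=9, p_edge=0.4)
        got = enumerate_all(g, params).member_sets()
        for v in g.vertices:
            assert frozenset({v}) in got

    @pytest.mark.parametrize("s", [0.1, 0.25, 0.35, 0.5])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_mode_sound_against_oracle(self, seed, s):
        """Exact enumeration emits only oracle-valid sets.  The converse
        does not hold in general: because the proportional density slack
        grows with size, some valid sets (e.g. strong 4-cycles at s=0.25)
        have no chain of valid subsets and are unreachable by growth; such
        sets may exist in the oracle output but never the reverse."""
        params = ScwibParams(U=0.7, W=0.6, s=s)
        g = random_similarity_graph(seed=seed, n=9, p_edge=0.5)
        oracle = brute_force_scwibs(g, params)
        got = enumerate_all(g, params).member_sets()
        assert got <= oracle
        part = partition_edges(g, params)
        for m in got:
            assert is_scwib(m, part, params)

    def test_unreachable_valid_set_is_the_known_cycle_case(self):
        """A strong 4-cycle is valid at s=0.25 (every degree 2 >= 2) but
        each 3-subset is a path whose endpoints fail, so growth through
        valid intermediates cannot reach it."""
        params = ScwibParams(U=0.7, W=0.6, s=0.25)
        g = SimilarityGraph.from_edges(
            [("a", "b", 0.8), ("b", "c", 0.8), ("c", "d", 0.8), ("d", "a", 0.8)]
        )
        cycle = frozenset({"a", "b", "c", "d"})
        assert cycle in brute_force_scwibs(g, params)
        assert cycle not in enumerate_all(g, params).member_sets()

    def test_heuristic_output_subset_of_exact(self, params):
        g = random_similarity_graph(seed=9, n=11, p_edge=0.6)
        exact = enumerate_all(g, params).member_sets()
        for budget in (1, 2, 3):
            heur = enumerate_all(
                g, params, mode="heuristic", budget=budget, rng_seed=4
            ).member_sets()
            assert heur <= exact

    def test_heuristic_determinism(self, params):
        g = random_similarity_graph(seed=3, n=12, p_edge=0.6)
        runs = [
            [tuple(sorted(c.members)) for c in enumerate_all(
                g, params, mode="heuristic", budget=2, rng_seed=77
            )]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    @pytest.mark.parametrize("seed", range(8))
    def test_size_bound_prunes_no_valid_cluster(self, params, seed):
        g = random_similarity_graph(seed=seed, n=9, p_edge=0.5)
        with_bound = enumerate_all(g, params).member_sets()
        without = enumerate_all(g, params, use_size_bound=False).member_sets()
        assert with_bound == without

    def test_reorder_interval_preserves_soundness(self, params):
        """Refreshing the degree order changes which seed each cluster is
        grown from, and with it the growth-reachable family — but never
        admits an invalid set, and the singleton cover is unaffected."""
        g = random_similarity_graph(seed=6, n=10, p_edge=0.5)
        oracle = brute_force_scwibs(g, params)
        for interval in (1, 3, 1000):
            got = enumerate_all(g, params, reorder_every=interval).member_sets()
            assert got <= oracle
            assert all(frozenset({v}) in got for v in g.vertices)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5_000), n=st.integers(2, 8), s=st.sampled_from([0.25, 0.5]))
def test_growth_soundness_property(seed, n, s):
    """Every emitted cluster passes independent recomputation and belongs
    to the brute-force oracle's valid-set family."""
    params = ScwibParams(U=0.7, W=0.6, s=s)
    g = random_similarity_graph(seed=seed, n=n, p_edge=0.55)
    oracle = brute_force_scwibs(g, params)
    got = enumerate_all(g, params).member_sets()
    assert got <= oracle
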