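"""Pair-score DP: worked-example arithmetic, oracle equivalence, invariants."""

import pytest

from localtag import (PairEnumeration, ReinitializationRequired, backtrack,
                      brute_force_best_score, extend_scores, initialize_scores,
                      run_segment_dp)
from localtag.haplotag_dp import PairScoreTable
from localtag.selftest import demo_graph

from conftest import random_graph_instance


@pytest.fixture(scope="module")
def demo_tables():
    graph = demo_graph()
    init = initialize_scores(graph.positions[0])
    ext = extend_scores(init, graph.positions[1], graph.step_edges(1),
                        graph.step_new_reads(1))
    return graph, init, ext


class TestInitialization:
    def test_worked_example_union_sizes(self, demo_tables):
        _, init, _ = demo_tables
        assert {pair: score for pair, (score, _) in init.entries.items()} == {
            (0, 0): 5, (0, 1): 11, (1, 1): 6}

    def test_canonical_pairs_only_and_no_backpointers(self, demo_tables):
        _, init, _ = demo_tables
        assert all(i <= j for i, j in init.entries)
        assert all(back is None for _, back in init.entries.values())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            initialize_scores([])


class TestRecursion:
    def test_worked_example_scores(self, demo_tables):
        _, _, ext = demo_tables
        scores = {pair: score for pair, (score, _) in ext.entries.items()}
        assert scores[(0, 0)] == 15
        assert scores[(0, 1)] == 19
        assert scores[(1, 0)] == 14

    def test_literal_recursion_value_for_last_pair(self, demo_tables):
        """Applying the recursion literally to the (alt, alt) pair gives
        max{5+2, 11+7, 6+5} = 18 (hand-computed union sizes)."""
        _, _, ext = demo_tables
        assert ext.score(1, 1) == 18

    def test_backpointers_reference_stored_previous_pairs(self, demo_tables):
        _, init, ext = demo_tables
        assert all(back in init.entries for _, back in ext.entries.values())

    def test_no_admissible_pair_signals_reinitialization(self, demo_tables):
        graph, init, _ = demo_tables
        with pytest.raises(ReinitializationRequired):
            extend_scores(init, graph.positions[1], {},
                          graph.step_new_reads(1))


class TestBacktrack:
    def test_worked_example_assignment(self, demo_tables):
        graph, init, ext = demo_tables
        result = backtrack([init, ext])
        assert result.best_score == 19
        assert result.path == [(0, 1), (0, 1)]
        assert result.labels == {(0, 0): {1}, (0, 1): {2},
                                 (1, 0): {1}, (1, 1): {2}}

    def test_single_position_argmax(self):
        table = PairScoreTable(0, {(0, 0): (4, None), (0, 1): (7, None),
                                   (1, 1): (3, None)})
        result = backtrack([table])
        assert result.best_score == 7
        assert result.labels == {(0, 0): {1}, (0, 1): {2}}

    def test_homozygous_like_chain_gets_both_labels(self):
        """One vertex per position: the best pair is (i, i) and the vertex
        carries both haplotype labels (score equals the brute-force optimum)."""
        graph = _single_vertex_chain()
        result, _ = run_segment_dp(graph, (0, 2))
        assert result.labels == {(0, 0): {1, 2}, (1, 0): {1, 2}}
        assert result.best_score == brute_force_best_score(graph, (0, 2))

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            backtrack([])


def _single_vertex_chain():
    from localtag import Candidate, CandidateFilterConfig, build_window_graph

    class R:
        def __init__(s, read_id, start):
            s.read_id, s.start = read_id, start

    reads = [R(f"r{i}", 0) for i in range(4)]
    ids = frozenset(r.read_id for r in reads)
    cands = [Candidate(0, "A", ("C",), {"C": ids, "A": frozenset()}),
             Candidate(100, "A", ("C",), {"C": ids, "A": frozenset()})]
    return build_window_graph(cands, reads,
                              CandidateFilterConfig(min_ref_support=1,
                                                    min_alt_support=1,
                                                    min_alt_fraction=0.0))


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", list(PairEnumeration))
    def test_dp_matches_brute_force_on_random_instances(self, mode):
        checked = 0
        for seed in range(200):
            graph = random_graph_instance(seed)
            for segment in graph.segments:
                result, _ = run_segment_dp(graph, segment, mode=mode)
                assert result.best_score == brute_force_best_score(
                    graph, segment, mode=mode), (seed, segment)
                checked += 1
        assert checked >= 200

    def test_single_vertex_instance(self):
        graph = _single_vertex_chain()
        assert brute_force_best_score(graph, (0, 1)) == 4

    def test_brute_force_refuses_oversized_instances(self):
        from localtag import haplotag_dp

        graph = random_graph_instance(3)
        original = haplotag_dp._MAX_BRUTE_FORCE_SEQUENCES
        haplotag_dp._MAX_BRUTE_FORCE_SEQUENCES = 1
        try:
            with pytest.raises(ValueError):
                brute_force_best_score(graph, graph.segments[0])
        finally:
            haplotag_dp._MAX_BRUTE_FORCE_SEQUENCES = original


class TestScoreInvariants:
    def test_scores_non_negative_integers(self):
        for seed in range(30):
            graph = random_graph_instance(seed)
            for segment in graph.segments:
                _, tables = run_segment_dp(graph, segment)
                for table in tables:
                    for score, _ in table.entries.values():
                        assert isinstance(score, int) and score >= 0

    def test_adding_read_along_existing_path_never_lowers_score(self):
        """Strengthening an existing chain of edges with one more read can
        only grow the read-set unions, so the segment optimum is monotone."""
        import numpy as np

        for seed in range(40):
            graph = random_graph_instance(seed)
            rng = np.random.default_rng(10_000 + seed)
            for segment in graph.segments:
                before, _ = run_segment_dp(graph, segment)
                boosted = _boost_random_path(graph, segment, rng)
                if boosted is None:
                    continue
                after, _ = run_segment_dp(boosted, segment)
                assert after.best_score >= before.best_score, (seed, segment)

    def test_initialization_is_symmetric(self):
        for seed in range(30):
            group = random_graph_instance(seed).positions[0]
            table = initialize_scores(group)
            for (i, j), (score, _) in table.entries.items():
                assert score == len(group[i].reads | group[j].reads)


def _boost_random_path(graph, segment, rng):
    """Rebuild the graph with one extra read tracing a random walk along
    existing real edges; returns None when the segment has no real-edge walk."""
    import copy

    start, end = segment
    walk = []
    options = [m for m in range(len(graph.positions[start]))]
    current = int(rng.choice(options))
    walk.append(current)
    for n in range(start + 1, end):
        step = [m for (pn, k, m), e in graph.edges.items()
                if pn == n and k == current and not e.artificial]
        if not step:
            return None
        current = int(rng.choice(sorted(set(step))))
        walk.append(current)

    boosted = copy.deepcopy(graph)
    new_id = "extra_read"
    for offset, m in enumerate(walk):
        n = start + offset
        vertex = boosted.positions[n][m]
        boosted.positions[n][m] = type(vertex)(
            position_index=vertex.position_index, allele_index=vertex.allele_index,
            position=vertex.position, allele=vertex.allele, is_ref=vertex.is_ref,
            reads=vertex.reads | {new_id})
        if offset > 0:
            key = (n, walk[offset - 1], m)
            edge = boosted.edges[key]
            boosted.edges[key] = type(edge)(
                from_vertex=boosted.positions[n - 1][walk[offset - 1]],
                to_vertex=boosted.positions[n][m],
                reads=edge.reads | {new_id}, artificial=False)
    return boosted
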