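"""Pair-score dynamic program over the allele graph.

The state at a candidate position ``n`` is an ordered vertex pair
``(V_{n,i}, V_{n,j})``: vertex ``i`` carries haplotype label 1 and vertex
``j`` label 2 (``i == j`` is allowed — the position then behaves as
homozygous on the best path). Scores are plain integers, cardinalities of
read-set unions; there is no floating point anywhere.

Initialization, at the first position of a segment::

    S(V_{1,i}, V_{1,j}) = | R(V_{1,i}) ∪ R(V_{1,j}) |

Recursion, for every ordered pair (i, j) at position n, maximizing over
previous pairs (k, l) whose edges E(V_{n-1,k}, V_{n,i}) and
E(V_{n-1,l}, V_{n,j}) exist (artificial edges exist but contribute nothing)::

    S(V_{n,i}, V_{n,j}) = max over (k, l) of
        S(V_{n-1,k}, V_{n-1,l})
        + | R(V_{n-1,k}, V_{n,i}) ∪ R(V_{n-1,l}, V_{n,j})
            ∪ R*(V_{n,i}) ∪ R*(V_{n,j}) |

Two enumeration modes for the previous pairs are provided. The default
("canonical") enumerates each *stored* previous pair exactly once, in its
stored orientation. Initialization stores only canonical pairs (i <= j, the
union being symmetric), so the step after initialization enumerates each
unordered pair once — the arithmetic the published worked example of this
algorithm follows; at later steps, whichever ordered pairs were admissible
are stored and extended, which is what lets the haplotype orientation
survive positions where the best pairing is non-canonical. A fully
symmetric mode that also enumerates the mirror of every stored pair is
available behind a flag; the two modes can print different per-pair scores
but reach the same segment optimum. Ties are broken everywhere by the first
pair in canonical enumeration order, so results are deterministic.

:func:`brute_force_best_score` is an independent oracle: it enumerates every
admissible sequence of pairs outright and scores it with the same cumulative
union formula, never touching the DP tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .haplotag_graph import AlleleVertex, HaplotagGraph


class PairEnumeration(str, enum.Enum):
    """How previous-position pairs are enumerated in the recursion."""

    CANONICAL = "canonical"   # each stored previous pair once, as stored
    SYMMETRIC = "symmetric"   # stored previous pairs plus their mirrors


class ReinitializationRequired(RuntimeError):
    """No admissible previous pair for any current pair; the caller must
    start a new segment (cannot occur after segmentation)."""


@dataclass
class PairScoreTable:
    """Scores and backpointers for all stored pairs at one position.

    ``entries`` maps an ordered pair of allele indices to ``(score, back)``
    where ``back`` is the previous canonical pair achieving the maximum
    (``None`` at initialization).
    """

    position_index: int
    entries: dict[tuple[int, int], tuple[int, Optional[tuple[int, int]]]] = field(
        default_factory=dict)

    def score(self, i: int, j: int) -> int:
        return self.entries[(i, j)][0]

    def best_pair(self) -> tuple[int, int]:
        """Highest-scoring pair; ties go to the first in canonical order."""
        if not self.entries:
            raise ValueError("empty score table")
        return max(sorted(self.entries), key=lambda p: self.entries[p][0])


@dataclass
class AlleleHaplotags:
    """Backtracking result for one segment.

    ``labels`` maps ``(position_index, allele_index)`` to the set of
    haplotype labels the vertex received; a vertex collects both labels when
    the traced pair has ``i == j``. ``path`` is the traced pair per position,
    ``best_score`` the segment optimum.
    """

    labels: dict[tuple[int, int], set[int]]
    path: list[tuple[int, int]]
    best_score: int


def initialize_scores(vertex_group: Sequence[AlleleVertex],
                      position_index: int = 0) -> PairScoreTable:
    """Scores at the first position of a segment: sizes of read-set unions.

    Only canonical pairs ``i <= j`` are stored; the union is symmetric so
    nothing is lost.
    """
    if not vertex_group:
        raise ValueError("cannot initialize scores on an empty vertex group")
    table = PairScoreTable(position_index=position_index)
    for i, vi in enumerate(vertex_group):
        for j in range(i, len(vertex_group)):
            table.entries[(i, j)] = (len(vi.reads | vertex_group[j].reads), None)
    return table


def extend_scores(prev_table: PairScoreTable,
                  vertex_group: Sequence[AlleleVertex],
                  edges: Mapping[tuple[int, int], frozenset[str]],
                  new_reads: Mapping[int, frozenset[str]],
                  mode: PairEnumeration = PairEnumeration.CANONICAL) -> PairScoreTable:
    """One recursion step: scores for all ordered pairs at the next position.

    ``edges`` maps ``(k, m)`` (previous vertex k -> current vertex m) to the
    shared read set (empty for artificial edges); ``new_reads`` maps each
    current vertex to its R* set. Pairs with no admissible previous pair get
    no entry; if no pair at all gets one, :class:`ReinitializationRequired`
    is raised.
    """
    stored_prev = sorted(prev_table.entries)
    if mode is PairEnumeration.SYMMETRIC:
        prev_pairs = sorted({p for kl in stored_prev for p in (kl, kl[::-1])})
    else:
        prev_pairs = stored_prev

    def prev_score(k: int, l: int) -> int:
        entry = prev_table.entries.get((k, l)) or prev_table.entries.get((l, k))
        return entry[0]

    table = PairScoreTable(position_index=prev_table.position_index + 1)
    for i in range(len(vertex_group)):
        for j in range(len(vertex_group)):
            best: Optional[tuple[int, tuple[int, int]]] = None
            for k, l in prev_pairs:
                if (k, i) not in edges or (l, j) not in edges:
                    continue
                gained = edges[(k, i)] | edges[(l, j)] | new_reads[i] | new_reads[j]
                score = prev_score(k, l) + len(gained)
                if best is None or score > best[0]:
                    best = (score, (k, l))
            if best is not None:
                table.entries[(i, j)] = best
    if not table.entries:
        raise ReinitializationRequired(
            f"no admissible pair at position {table.position_index}")
    return table


def backtrack(tables: Sequence[PairScoreTable]) -> AlleleHaplotags:
    """Trace the best final pair back to the segment start, labelling alleles.

    At every traversed pair ``(i, j)``, vertex ``i`` receives haplotype label
    1 and vertex ``j`` label 2.
    """
    if not tables:
        raise ValueError("backtrack requires at least one score table")
    pair = tables[-1].best_pair()
    best_score = tables[-1].score(*pair)
    labels: dict[tuple[int, int], set[int]] = {}
    path: list[tuple[int, int]] = []
    current: Optional[tuple[int, int]] = pair
    for table in reversed(tables):
        assert current is not None
        i, j = current
        labels.setdefault((table.position_index, i), set()).add(1)
        labels.setdefault((table.position_index, j), set()).add(2)
        path.append(current)
        if current in table.entries:
            current = table.entries[current][1]
        else:
            # symmetric enumeration may point at the mirror of a stored pair;
            # follow the stored entry with the orientation flipped back
            back = table.entries[(j, i)][1]
            current = None if back is None else (back[1], back[0])
    path.reverse()
    return AlleleHaplotags(labels=labels, path=path, best_score=best_score)


def run_segment_dp(graph: HaplotagGraph, segment: tuple[int, int],
                   mode: PairEnumeration = PairEnumeration.CANONICAL,
                   ) -> tuple[AlleleHaplotags, list[PairScoreTable]]:
    """Initialize, extend across the segment, backtrack."""
    start, end = segment
    tables = [initialize_scores(graph.positions[start], position_index=start)]
    for n in range(start + 1, end):
        tables.append(extend_scores(tables[-1], graph.positions[n],
                                    graph.step_edges(n), graph.step_new_reads(n),
                                    mode=mode))
    return backtrack(tables), tables


_MAX_BRUTE_FORCE_SEQUENCES = 2_000_000


def brute_force_best_score(graph: HaplotagGraph, segment: tuple[int, int],
                           mode: PairEnumeration = PairEnumeration.CANONICAL) -> int:
    """Exhaustive oracle for the segment optimum.

    Enumerates every sequence of ordered (hap1-vertex, hap2-vertex) choices —
    canonical pairs at the first position, matching initialization, then any
    ordered pair — checks edge existence, and scores each sequence with the
    identical cumulative union formula, independently of the DP tables.
    Refuses instances whose sequence count exceeds a fixed guard.
    """
    del mode  # both enumeration modes reach the same segment optimum
    start, end = segment

    def pairs_at(n: int) -> list[tuple[int, int]]:
        size = len(graph.positions[n])
        ordered = [(i, j) for i in range(size) for j in range(size)]
        if n == start:
            return [(i, j) for i, j in ordered if i <= j]
        return ordered

    total = 1
    for n in range(start, end):
        total *= len(pairs_at(n))
        if total > _MAX_BRUTE_FORCE_SEQUENCES:
            raise ValueError("instance too large for brute-force enumeration")

    allowed = {n: pairs_at(n) for n in range(start, end)}
    steps = {n: (graph.step_edges(n), graph.step_new_reads(n))
             for n in range(start + 1, end)}
    best = -1

    def recurse(n: int, prev_pair: Optional[tuple[int, int]], score: int) -> None:
        nonlocal best
        if n == end:
            best = max(best, score)
            return
        group = graph.positions[n]
        step_edges, step_new = steps[n] if n > start else (None, None)
        for i, j in allowed[n]:
            if n == start:
                gained = len(group[i].reads | group[j].reads)
            else:
                k, l = prev_pair
                if (k, i) not in step_edges or (l, j) not in step_edges:
                    continue
                gained = len(step_edges[(k, i)] | step_edges[(l, j)]
                             | step_new[i] | step_new[j])
            recurse(n + 1, (i, j), score + gained)

    recurse(start, None, 0)
    if best < 0:
        raise ReinitializationRequired("no admissible pair sequence in segment")
    return best
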