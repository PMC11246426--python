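"""Per-window allele graph.

Each retained heterozygous SNP candidate position contributes one vertex per
supported allele (a REF vertex only when the reference allele has adequate
support). Consecutive candidate positions are connected by an edge for every
vertex pair sharing at least one read; a vertex that ends up with no incoming
edge while a sibling at the same position has one is rescued by artificial
(empty-read-set) edges from every vertex of the previous position. Where no
vertex of a position has an incoming edge, the chain cannot be extended and
the window is split into independent segments, each solved and phase-labelled
on its own.

Vertices at a position are ordered REF first, then alt alleles
lexicographically; this canonical order defines pair enumeration in the DP
and all tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignment_io import AlignedRead
from .candidate_finder import Candidate, CandidateFilterConfig


@dataclass(frozen=True)
class AlleleVertex:
    """One allele at one candidate position, with its supporting read set."""

    position_index: int
    allele_index: int
    position: int
    allele: str
    is_ref: bool
    reads: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(f"vertex {self.label} has no supporting reads")

    @property
    def label(self) -> str:
        return f"{self.position}:{self.allele}{'(ref)' if self.is_ref else ''}"


@dataclass(frozen=True)
class OverlapEdge:
    """Edge between vertices at consecutive candidate positions.

    Real edges carry the intersection of their endpoint read sets; artificial
    edges exist only to keep the chain extendable and carry no reads.
    """

    from_vertex: AlleleVertex
    to_vertex: AlleleVertex
    reads: frozenset[str]
    artificial: bool = False

    def __post_init__(self) -> None:
        if self.artificial and self.reads:
            raise ValueError("artificial edges must carry an empty read set")
        if not self.artificial and not self.reads:
            raise ValueError("real edges require a non-empty read set")


@dataclass
class HaplotagGraph:
    """Allele graph for one window.

    ``edges`` is keyed by ``(n, k, m)``: the edge from vertex ``k`` at
    position ``n - 1`` into vertex ``m`` at position ``n``. ``new_reads``
    holds, per vertex ``(n, m)``, the reads overlapping it that start strictly
    after the coordinate of position ``n - 1`` (empty by convention at
    ``n == 0``). ``segments`` lists maximal half-open position-index ranges
    between reinitialization points; it is populated by
    :func:`split_segments`.
    """

    positions: list[list[AlleleVertex]] = field(default_factory=list)
    edges: dict[tuple[int, int, int], OverlapEdge] = field(default_factory=dict)
    new_reads: dict[tuple[int, int], frozenset[str]] = field(default_factory=dict)
    segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def incoming(self, n: int, m: int) -> list[OverlapEdge]:
        return [e for (pn, _, pm), e in self.edges.items() if pn == n and pm == m]

    def step_edges(self, n: int) -> dict[tuple[int, int], frozenset[str]]:
        """Edges crossing from position ``n - 1`` into ``n`` as (k, m) -> reads."""
        return {(k, m): e.reads for (pn, k, m), e in self.edges.items() if pn == n}

    def step_new_reads(self, n: int) -> dict[int, frozenset[str]]:
        return {m: self.new_reads[(n, m)] for m in range(len(self.positions[n]))}

    def to_dot(self) -> str:
        """Graphviz DOT rendering for debugging."""
        lines = ["digraph haplotag {", "  rankdir=LR;"]
        for group in self.positions:
            for v in group:
                lines.append(
                    f'  "{v.position_index}_{v.allele_index}" '
                    f'[label="{v.label}\\n|R|={len(v.reads)}"];'
                )
        for (n, k, m), e in sorted(self.edges.items()):
            style = ' [style=dashed,label="art"]' if e.artificial else f' [label="{len(e.reads)}"]'
            lines.append(f'  "{n - 1}_{k}" -> "{n}_{m}"{style};')
        lines.append("}")
        return "\n".join(lines)


def build_graph(het_candidates: Sequence[Candidate],
                reads: Iterable[AlignedRead | object],
                config: CandidateFilterConfig | None = None) -> HaplotagGraph:
    """Build the allele graph from filtered het-SNP candidates.

    ``reads`` only needs objects exposing ``read_id`` and ``start`` (used for
    the new-read sets R*); alt vertices require ``min_alt_support`` reads and
    a REF vertex is created only with at least ``min_ref_support`` reads.
    """
    config = config or CandidateFilterConfig()
    starts = {r.read_id: r.start for r in reads}

    graph = HaplotagGraph()
    prev_position: Optional[int] = None
    for cand in sorted(het_candidates, key=lambda c: c.position):
        group: list[AlleleVertex] = []
        ref_reads = cand.support.get(cand.ref_allele, frozenset())
        ordered_alleles = []
        if len(ref_reads) >= config.min_ref_support:
            ordered_alleles.append((cand.ref_allele, True, ref_reads))
        for alt in sorted(cand.alt_alleles):
            alt_reads = cand.support.get(alt, frozenset())
            if len(alt_reads) >= config.min_alt_support:
                ordered_alleles.append((alt, False, alt_reads))
        if not ordered_alleles:
            continue
        n = graph.n_positions
        for m, (allele, is_ref, rset) in enumerate(ordered_alleles):
            group.append(AlleleVertex(position_index=n, allele_index=m,
                                      position=cand.position, allele=allele,
                                      is_ref=is_ref, reads=frozenset(rset)))
        graph.positions.append(group)

        for m, vertex in enumerate(group):
            if n == 0:
                new = frozenset()
            else:
                new = frozenset(r for r in vertex.reads
                                if starts.get(r, vertex.position) > prev_position)
            graph.new_reads[(n, m)] = new
        if n > 0:
            for k, prev_vertex in enumerate(graph.positions[n - 1]):
                for m, vertex in enumerate(group):
                    shared = prev_vertex.reads & vertex.reads
                    if shared:
                        graph.edges[(n, k, m)] = OverlapEdge(prev_vertex, vertex,
                                                             frozenset(shared))
        prev_position = cand.position
    return graph


def add_artificial_edges(graph: HaplotagGraph) -> HaplotagGraph:
    """Rescue orphan vertices at positions that are otherwise connected.

    For every position ``n > 0`` where at least one vertex has an incoming
    edge, each vertex without one receives artificial edges from *all*
    vertices of position ``n - 1``. Positions where no vertex has an incoming
    edge are left alone — they become segment boundaries. Idempotent.
    """
    for n in range(1, graph.n_positions):
        has_incoming = [any((n, k, m) in graph.edges
                            for k in range(len(graph.positions[n - 1])))
                        for m in range(len(graph.positions[n]))]
        if not any(has_incoming) or all(has_incoming):
            continue
        for m, connected in enumerate(has_incoming):
            if connected:
                continue
            for k, prev_vertex in enumerate(graph.positions[n - 1]):
                graph.edges[(n, k, m)] = OverlapEdge(prev_vertex,
                                                     graph.positions[n][m],
                                                     frozenset(), artificial=True)
    return graph


def split_segments(graph: HaplotagGraph) -> list[tuple[int, int]]:
    """Partition positions into maximal chains connected by >=1 edge per step.

    Each returned half-open index range is an independent DP problem and an
    independent phase block. Stored on ``graph.segments`` and returned.
    """
    segments: list[tuple[int, int]] = []
    if graph.n_positions:
        start = 0
        for n in range(1, graph.n_positions):
            if not any(key[0] == n for key in graph.edges):
                segments.append((start, n))
                start = n
        segments.append((start, graph.n_positions))
    graph.segments = segments
    return segments


def build_window_graph(het_candidates: Sequence[Candidate],
                       reads: Iterable[AlignedRead],
                       config: CandidateFilterConfig | None = None) -> HaplotagGraph:
    """build_graph + add_artificial_edges + split_segments in one call."""
    graph = build_graph(het_candidates, reads, config)
    add_artificial_edges(graph)
    split_segments(graph)
    return graph
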