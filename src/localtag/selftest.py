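"""The canonical two-position worked example, as a built-in self test.

Eleven reads span two heterozygous SNP positions with two alleles each. The
read incidence is chosen so every score of the pair-score DP can be checked
by hand:

* reads r01-r03 support allele 1 at both positions,
* reads r04-r05 support allele 1 at position 1 and allele 2 at position 2,
* read  r06     supports allele 2 at position 1 and allele 1 at position 2,
* reads r07-r11 support allele 2 at both positions.

Initialization gives pair scores 5 / 11 / 6; the recursion gives 15 / 19 /
14 for (allele1,allele1) / (allele1,allele2) / (allele2,allele1); the best
final score is 19, tagging r01-r03 haplotype 1, r07-r11 haplotype 2 and
leaving r04-r06 untagged. The instance is built from real aligned reads and
run through the public pipeline (pileup, het filter, graph, DP, majority
vote), so the self test exercises every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment_io import AlignedRead, ReferenceSequence
from .candidate_finder import (CandidateFilterConfig, collect_allele_support,
                               select_het_snp_candidates)
from .haplotag_dp import PairEnumeration, run_segment_dp
from .haplotag_graph import HaplotagGraph, build_window_graph
from .read_tagger import ReadHaplotag, Window, WindowConfig, haplotag_window

#: positions of the two het sites on the demo contig
SITE1, SITE2 = 100, 200

#: per-read (allele at site 1, allele at site 2) incidence; allele index 1 is
#: the reference base, allele index 2 the alternate.
READ_ALLELES: dict[str, tuple[int, int]] = {
    **{f"r{k:02d}": (1, 1) for k in (1, 2, 3)},
    **{f"r{k:02d}": (1, 2) for k in (4, 5)},
    "r06": (2, 1),
    **{f"r{k:02d}": (2, 2) for k in range(7, 12)},
}

#: expected read haplotags under the best scoring assignment
EXPECTED_READ_TAGS = {
    **{f"r{k:02d}": 1 for k in (1, 2, 3)},
    **{f"r{k:02d}": 0 for k in (4, 5, 6)},
    **{f"r{k:02d}": 2 for k in range(7, 12)},
}


def demo_reference() -> ReferenceSequence:
    # repeating ACGT: base 'A' at both het sites (100 and 200)
    return ReferenceSequence("demo", ("ACGT" * 75)[:300])


def demo_reads() -> list[AlignedRead]:
    """The eleven reads, spanning [90, 210) with the incidence above."""
    reference = demo_reference()
    alt = {SITE1: "C", SITE2: "T"}
    reads = []
    for read_id, (allele1, allele2) in READ_ALLELES.items():
        pairs = []
        for pos in range(90, 210):
            base = reference.base_at(pos)
            if pos == SITE1 and allele1 == 2:
                base = alt[SITE1]
            elif pos == SITE2 and allele2 == 2:
                base = alt[SITE2]
            pairs.append((pos, base, 30))
        reads.append(AlignedRead(read_id=read_id, contig="demo", start=90,
                                 aligned_pairs=tuple(pairs)))
    return reads


def demo_graph(config: CandidateFilterConfig | None = None) -> HaplotagGraph:
    """The two-position, four-vertex graph built through the real pipeline."""
    config = config or CandidateFilterConfig()
    reads = demo_reads()
    candidates = collect_allele_support(reads, demo_reference(), (0, 300), config)
    het = select_het_snp_candidates(candidates, config)
    return build_window_graph(het, reads, config)


@dataclass(frozen=True)
class SelfTestResult:
    init_scores: dict[tuple[int, int], int]        # pairs at position 1
    extension_scores: dict[tuple[int, int], int]   # ordered pairs at position 2
    best_score: int
    read_tags: dict[str, int]

    def render(self) -> str:
        lines = ["worked example: two het sites, eleven reads", "",
                 "initialization (position 1):"]
        for (i, j), s in sorted(self.init_scores.items()):
            lines.append(f"  S(A1,{i + 1}, A1,{j + 1}) = {s}")
        lines.append("recursion (position 2):")
        for (i, j), s in sorted(self.extension_scores.items()):
            lines.append(f"  S(A2,{i + 1}, A2,{j + 1}) = {s}")
        lines.append(f"best final score: {self.best_score}")
        lines.append("read haplotags: " + ", ".join(
            f"{r}={t}" for r, t in sorted(self.read_tags.items())))
        return "\n".join(lines)


def run_selftest(mode: PairEnumeration = PairEnumeration.CANONICAL) -> SelfTestResult:
    graph = demo_graph()
    allele_tags, tables = run_segment_dp(graph, (0, 2), mode=mode)

    window = Window("demo", 0, 300)
    result = haplotag_window(demo_reads(), demo_reference(), window,
                             WindowConfig(window_size=300, mode=mode))
    return SelfTestResult(
        init_scores={p: s for p, (s, _) in tables[0].entries.items()},
        extension_scores={p: s for p, (s, _) in tables[1].entries.items()},
        best_score=allele_tags.best_score,
        read_tags={t.read_id: t.haplotag for t in result.tags},
    )
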