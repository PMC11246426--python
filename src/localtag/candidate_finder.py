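"""Heterozygous SNP candidate discovery.

From the pileup of a window, find positions where reads disagree with the
reference and keep only the sites that look heterozygous and are pure SNPs:
these are the positions whose alleles become vertices of the haplotag graph.

Two rules define "looks heterozygous":

* a candidate with exactly one alternate allele is dropped when the reference
  allele is supported by fewer than ``min_ref_support`` reads (such a site is
  far more likely homozygous-alt than het);
* any candidate carrying a non-SNP alternate allele is dropped.

Candidate *generation* additionally applies base/mapping-quality floors and,
per alt allele, both a minimum read count and a minimum allele fraction. The
fraction floor matters: heterozygous sites have an expected allele fraction of
0.5, so a 0.20 floor tolerates 2.5x allelic imbalance while rejecting the
recurrent-sequencing-error pileups that would otherwise masquerade as het
sites and corrupt phasing. Site selection for phasing prefers precision over
recall — a missed borderline het costs little when its neighbours carry the
phase, while a false het actively scrambles it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .alignment_io import AlignedRead, ReferenceSequence

SNV_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CandidateFilterConfig:
    """Thresholds for candidate generation and het-SNP selection.

    min_ref_support: reads on the reference allele required to call a
        single-alt candidate heterozygous (and to create a REF graph vertex).
    min_alt_support: reads required on an alt allele for it to exist at all.
    min_alt_fraction: minimum fraction of the eligible coverage an alt allele
        must reach (applied together with min_alt_support).
    min_base_quality / min_mapping_quality: phred floors for a read base to
        enter the pileup.
    """

    min_ref_support: int = 3
    min_alt_support: int = 2
    min_base_quality: int = 10
    min_mapping_quality: int = 5
    min_alt_fraction: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_ref_support", "min_alt_support",
                     "min_base_quality", "min_mapping_quality"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Candidate:
    """An observed non-reference site with per-allele read support.

    ``support`` maps every allele (including the reference allele, possibly
    with an empty read set) to the ids of the reads carrying it; a read
    supports at most one allele at a position.
    """

    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    support: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError("candidate must have at least one alt allele")
        sets = list(self.support.values())
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError(f"support sets at position {self.position} are not disjoint")

    @property
    def ref_support(self) -> int:
        return len(self.support.get(self.ref_allele, frozenset()))


def collect_allele_support(reads: Iterable[AlignedRead],
                           reference: ReferenceSequence,
                           window: tuple[int, int],
                           config: CandidateFilterConfig | None = None) -> list[Candidate]:
    """Pileup-based candidate generation over ``window`` (0-based half-open).

    Returns one :class:`Candidate` per position carrying at least one alt
    allele that passes the support-count and allele-fraction floors, sorted by
    position. Deleted bases support no allele; N bases (read or reference)
    never participate.
    """
    config = config or CandidateFilterConfig()
    start, end = window
    if start >= end:
        return []
    start = max(start, reference.start)
    end = min(end, reference.end)

    columns: dict[int, dict[str, set[str]]] = {}
    for read in reads:
        if read.mapping_quality < config.min_mapping_quality:
            continue
        for pos, base, qual in read.aligned_pairs:
            if not start <= pos < end:
                continue
            if base is None or base == "N":
                continue
            if qual is not None and qual < config.min_base_quality:
                continue
            columns.setdefault(pos, {}).setdefault(base, set()).add(read.read_id)

    candidates: list[Candidate] = []
    for pos in sorted(columns):
        ref_base = reference.base_at(pos)
        if ref_base == "N":
            continue
        column = columns[pos]
        coverage = sum(len(s) for s in column.values())
        min_count = max(config.min_alt_support,
                        math.ceil(config.min_alt_fraction * coverage))
        alts = tuple(b for b in SNV_BASES
                     if b != ref_base and len(column.get(b, ())) >= min_count)
        if not alts:
            continue
        support = {ref_base: frozenset(column.get(ref_base, set()))}
        support.update({b: frozenset(column[b]) for b in alts})
        candidates.append(Candidate(position=pos, ref_allele=ref_base,
                                    alt_alleles=alts, support=support))
    return candidates


def _is_snv(allele: str) -> bool:
    return len(allele) == 1 and allele in SNV_BASES


def select_het_snp_candidates(candidates: Sequence[Candidate],
                              config: CandidateFilterConfig | None = None) -> list[Candidate]:
    """Keep putative heterozygous pure-SNP candidates, preserving order.

    A candidate survives iff every alt allele is a single-base substitution
    and it is NOT the case that it has exactly one alt allele with reference
    support below ``min_ref_support``. Multi-alt candidates are kept
    regardless of reference support (both alleles of the het pair may be
    non-reference). Idempotent.
    """
    config = config or CandidateFilterConfig()
    kept = []
    for cand in candidates:
        if not all(_is_snv(a) for a in cand.alt_alleles):
            continue
        if len(cand.alt_alleles) == 1 and cand.ref_support < config.min_ref_support:
            continue
        kept.append(cand)
    return kept
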