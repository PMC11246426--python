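"""Reference and alignment I/O.

Thin pysam-backed layer: read reference slices, fetch aligned reads from
coordinate-sorted indexed SAM/BAM, and write haplotagged alignments using the
de-facto standard ``HP`` (haplotype) and ``PS`` (phase set) auxiliary tags.
All internal coordinates are 0-based half-open; conversion to the 1-based
conventions of SAM happens only at this boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

VALID_REFERENCE_BASES = frozenset("ACGTN")

#: SAM auxiliary tag names used by WhatsHap, Margin, LongPhase and friends.
HP_TAG = "HP"
PS_TAG = "PS"


class AlignmentFormatError(ValueError):
    """Raised for unindexed or unsorted alignment input."""


@dataclass(frozen=True)
class ReferenceSequence:
    """An uppercase nucleotide slice of one contig.

    ``start`` is the 0-based contig coordinate of ``sequence[0]`` so that a
    window-sized slice can be addressed in contig coordinates via
    :meth:`base_at`.
    """

    name: str
    sequence: str
    start: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - VALID_REFERENCE_BASES
        if bad:
            raise ValueError(f"invalid reference bases: {sorted(bad)!r}")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    def base_at(self, position: int) -> str:
        """Reference base at a 0-based contig coordinate."""
        if not self.start <= position < self.end:
            raise IndexError(f"position {position} outside [{self.start}, {self.end})")
        return self.sequence[position - self.start]


@dataclass
class AlignedRead:
    """One mapped read with per-reference-position base calls.

    ``aligned_pairs`` holds one ``(reference_position, base, base_quality)``
    triple per aligned reference position, in strictly increasing reference
    order; ``base`` is ``None`` where the read carries a deletion. Insertions
    and clipped bases consume no reference position and are not represented.
    """

    read_id: str
    contig: str
    start: int
    aligned_pairs: Sequence[tuple[int, Optional[str], Optional[int]]]
    mapping_quality: int = 60
    _by_position: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.aligned_pairs]
        if not positions:
            raise ValueError(f"read {self.read_id!r} aligns to no reference position")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"read {self.read_id!r}: reference positions not strictly increasing")
        if self.start != positions[0]:
            raise ValueError(
                f"read {self.read_id!r}: start {self.start} != first aligned position {positions[0]}"
            )
        self._by_position = {p: (b, q) for p, b, q in self.aligned_pairs}

    @property
    def end(self) -> int:
        """0-based exclusive end of the alignment on the reference."""
        return self.aligned_pairs[-1][0] + 1

    def base_at(self, position: int) -> Optional[tuple[Optional[str], Optional[int]]]:
        """(base, quality) at a reference position, or None if not aligned there."""
        return self._by_position.get(position)


@dataclass(frozen=True)
class TaggedAlignmentRecord:
    """Final per-read haplotag destined for HP/PS emission.

    ``phase_block`` is the leftmost 1-based reference position of the phase
    segment the read was tagged in; haplotag-0 records carry none.
    """

    read_id: str
    haplotag: int
    phase_block: Optional[int] = None

    def __post_init__(self) -> None:
        if self.haplotag not in (0, 1, 2):
            raise ValueError(f"haplotag must be 0, 1 or 2, got {self.haplotag}")
        if self.haplotag == 0 and self.phase_block is not None:
            raise ValueError("haplotag-0 records must not carry a phase block")
        if self.haplotag in (1, 2) and self.phase_block is None:
            raise ValueError("haplotag 1/2 records require a phase block")


def read_reference(path: str | os.PathLike, contig: str,
                   interval: Optional[tuple[int, int]] = None) -> ReferenceSequence:
    """Read an uppercase slice of ``contig`` from an indexed FASTA.

    ``interval`` is 0-based half-open; omitted means the whole contig.
    """
    with pysam.FastaFile(str(path)) as fasta:
        if contig not in fasta.references:
            raise KeyError(f"contig {contig!r} not found in {path}")
        if interval is None:
            start, end = 0, fasta.get_reference_length(contig)
        else:
            start, end = interval
            if not (0 <= start < end <= fasta.get_reference_length(contig)):
                raise ValueError(f"interval [{start}, {end}) outside contig {contig!r}")
        seq = fasta.fetch(contig, start, end).upper()
    return ReferenceSequence(name=contig, sequence=seq, start=start)


def _read_from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    seq = rec.query_sequence or ""
    quals = rec.query_qualities
    pairs: list[tuple[int, Optional[str], Optional[int]]] = []
    for qpos, rpos in rec.get_aligned_pairs():
        if rpos is None:  # insertion or clip: no reference position
            continue
        if qpos is None:  # deletion on the read
            pairs.append((rpos, None, None))
        else:
            qual = int(quals[qpos]) if quals is not None else None
            pairs.append((rpos, seq[qpos].upper(), qual))
    return AlignedRead(
        read_id=rec.query_name,
        contig=rec.reference_name,
        start=rec.reference_start,
        aligned_pairs=tuple(pairs),
        mapping_quality=rec.mapping_quality,
    )


def read_alignments(path: str | os.PathLike, contig: str,
                    interval: tuple[int, int],
                    keep_secondary: bool = False) -> list[AlignedRead]:
    """All primary mapped reads overlapping a 0-based half-open interval.

    Requires a coordinate-sorted, indexed alignment file. Unmapped, secondary,
    supplementary and duplicate-flagged records are excluded unless
    ``keep_secondary`` is set (which retains secondary/supplementary only).
    """
    start, end = interval
    with pysam.AlignmentFile(str(path)) as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so is not None and so != "coordinate":
            raise AlignmentFormatError(f"{path} is not coordinate-sorted (SO={so})")
        if not af.has_index():
            raise AlignmentFormatError(f"{path} has no index; sort and index it first")
        if contig not in af.references:
            raise KeyError(f"contig {contig!r} not found in {path}")
        reads = []
        for rec in af.fetch(contig, start, end):
            if rec.is_unmapped or rec.is_duplicate:
                continue
            if (rec.is_secondary or rec.is_supplementary) and not keep_secondary:
                continue
            reads.append(_read_from_pysam(rec))
    return reads


def write_haplotagged(in_path: str | os.PathLike, out_path: str | os.PathLike,
                      tags: Iterable[TaggedAlignmentRecord],
                      program: Optional[dict] = None) -> int:
    """Copy an alignment file, stamping HP/PS tags from ``tags``.

    Records named in ``tags`` with haplotag 1/2 get ``HP``/``PS``; all other
    records (including haplotag 0) are emitted with neither tag. Reads listed
    in ``tags`` but absent from the input are skipped with a warning. Returns
    the number of records actually tagged. ``program`` optionally adds a @PG
    header line (keys ID/PN/VN/CL).
    """
    by_id: dict[str, TaggedAlignmentRecord] = {}
    for tag in tags:
        if tag.read_id in by_id:
            raise ValueError(f"read {tag.read_id!r} appears more than once in tags")
        by_id[tag.read_id] = tag

    out_path = str(out_path)
    mode = "wb" if out_path.endswith(".bam") else "wh"
    n_tagged = 0
    seen: set[str] = set()
    with pysam.AlignmentFile(str(in_path)) as fin:
        header = fin.header.to_dict()
        if program:
            header.setdefault("PG", []).append(program)
        with pysam.AlignmentFile(out_path, mode, header=header) as fout:
            for rec in fin.fetch(until_eof=True):
                tag = by_id.get(rec.query_name)
                primary = not (rec.is_secondary or rec.is_supplementary or rec.is_unmapped)
                if tag is not None and primary:
                    seen.add(rec.query_name)
                for name in (HP_TAG, PS_TAG):
                    if rec.has_tag(name):
                        rec.set_tag(name, None)
                if tag is not None and primary and tag.haplotag in (1, 2):
                    rec.set_tag(HP_TAG, int(tag.haplotag), value_type="i")
                    rec.set_tag(PS_TAG, int(tag.phase_block), value_type="i")
                    n_tagged += 1
                fout.write(rec)
    missing = set(by_id) - seen
    if missing:
        logger.warning("%d tagged read(s) absent from %s (e.g. %s); skipped",
                       len(missing), in_path, sorted(missing)[0])
    if out_path.endswith(".bam"):
        try:
            pysam.index(out_path)
        except pysam.SamtoolsError:  # pragma: no cover - unsorted scratch output
            logger.debug("could not index %s", out_path)
    return n_tagged


RESULT_COLUMNS = ["read_id", "haplotag", "phase_block", "votes1", "votes2"]


def write_result_tsv(path: str | os.PathLike, rows: Iterable[Sequence]) -> None:
    """Write per-read tagging results (read_id, haplotag, phase_block, votes)."""
    df = pd.DataFrame(list(rows), columns=RESULT_COLUMNS)
    df["phase_block"] = df["phase_block"].astype("Int64")  # no float promotion
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_result_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"result TSV {path} lacks columns {sorted(missing)}")
    return df


def write_truth_tsv(path: str | os.PathLike, truth: dict[str, int]) -> None:
    """Write per-read ground-truth haplotypes (read_id, haplotype)."""
    df = pd.DataFrame(sorted(truth.items()), columns=["read_id", "haplotype"])
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"read_id", "haplotype"} <= set(df.columns):
        raise ValueError(f"truth TSV {path} needs read_id and haplotype columns")
    return dict(zip(df["read_id"].astype(str), df["haplotype"].astype(int)))
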