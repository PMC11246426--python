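"""Switch-aware haplotagging accuracy.

Haplotype labels produced by local haplotagging are arbitrary per phase
block, so naive label comparison against truth is meaningless. For each
block, the evaluator considers both label mappings ({1->1, 2->2} and
{1->2, 2->1}), keeps the one matching more reads, and aggregates matches over
blocks. Haplotag-0 reads are never counted as errors — they only lower the
reported tagged fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

IDENTITY = (1, 2)
SWAP = (2, 1)


@dataclass(frozen=True)
class BlockAccuracy:
    block: int
    size: int                      # tagged reads in the block
    permutation: tuple[int, int]   # chosen truth mapping for (tag1, tag2)
    matches: int


@dataclass(frozen=True)
class AccuracyReport:
    total_reads: int
    tagged_reads: int
    tagged_fraction: float
    accuracy: Optional[float]      # None when no read is tagged
    per_block: tuple[BlockAccuracy, ...]

    def summary(self) -> str:
        acc = "undefined" if self.accuracy is None else f"{self.accuracy:.4%}"
        return (f"reads: {self.total_reads}  tagged: {self.tagged_reads} "
                f"({self.tagged_fraction:.2%})  switch-aware accuracy: {acc}  "
                f"blocks: {len(self.per_block)}")


def switch_aware_accuracy(pred_tags: Iterable, truth: Mapping[str, int]) -> AccuracyReport:
    """Compare predicted read tags with truth under per-block best permutation.

    ``pred_tags`` yields objects with ``read_id``, ``haplotag`` and
    ``phase_block`` (e.g. ReadHaplotag or rows of a result table). Every
    tagged read must have a truth haplotype. Accuracy is the match-weighted
    aggregate over blocks; with zero tagged reads it is reported as None, not
    0.
    """
    total = 0
    by_block: dict[int, list[tuple[int, int]]] = {}
    for tag in pred_tags:
        total += 1
        if tag.haplotag not in (1, 2):
            continue
        if tag.read_id not in truth:
            raise KeyError(f"tagged read {tag.read_id!r} has no truth haplotype")
        by_block.setdefault(int(tag.phase_block), []).append(
            (tag.haplotag, truth[tag.read_id]))

    blocks = []
    tagged = matched = 0
    for block in sorted(by_block):
        pairs = by_block[block]
        hits_identity = sum(1 for pred, true in pairs if IDENTITY[pred - 1] == true)
        hits_swap = sum(1 for pred, true in pairs if SWAP[pred - 1] == true)
        permutation, hits = max(((IDENTITY, hits_identity), (SWAP, hits_swap)),
                                key=lambda t: t[1])
        blocks.append(BlockAccuracy(block=block, size=len(pairs),
                                    permutation=permutation, matches=hits))
        tagged += len(pairs)
        matched += hits

    return AccuracyReport(
        total_reads=total,
        tagged_reads=tagged,
        tagged_fraction=tagged / total if total else 0.0,
        accuracy=matched / tagged if tagged else None,
        per_block=tuple(blocks),
    )
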