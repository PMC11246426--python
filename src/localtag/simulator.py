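"""Diploid genome and long-read simulator.

Generates a random reference, plants heterozygous SNPs (on one haplotype,
chosen fairly) and homozygous SNPs (on both), then draws reads from the two
haplotypes with equal probability, injecting i.i.d. substitution errors.
Because all planted variants are substitutions, haplotype coordinates equal
reference coordinates, so reads are emitted pre-aligned (true start, full
match CIGAR) and the pipeline needs no aligner. Base qualities are constant
and calibrated to the configured error rate (phred of the rate), so the
quality floors of candidate filtering behave as they would on real data.

Everything is reproducible from the seed. This emulates the diploid
structure the haplotagger assumes — two locally distinguishable haplotypes
sampled at uniform coverage — and deliberately not platform error profiles
(homopolymer indels, quality waves, chimeras) or coverage biases.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .alignment_io import AlignedRead, ReferenceSequence

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 50_000
    het_snp_rate: float = 0.001
    hom_snp_rate: float = 0.0005
    depth: float = 30.0                  # mean total coverage (both haplotypes)
    read_length_mean: float = 10_000.0
    read_length_sd: float = 1_500.0
    min_read_length: int = 500
    substitution_error_rate: float = 0.01
    mapping_quality: int = 60
    contig: str = "sim1"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("het_snp_rate", "hom_snp_rate", "substitution_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.genome_length <= 0 or self.min_read_length <= 0:
            raise ValueError("lengths must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def base_quality(self) -> int:
        """Phred quality consistent with the substitution error rate."""
        if self.substitution_error_rate <= 0:
            return 40
        return max(2, min(40, round(-10.0 * math.log10(self.substitution_error_rate))))


@dataclass(frozen=True)
class SimulatedVariant:
    position: int            # 0-based
    ref: str
    alt: str
    genotype: str            # "het" or "hom"
    haplotype: Optional[int]  # 1/2 for het (carrier), None for hom


@dataclass
class DiploidSimulation:
    """In-memory simulation output: reference, haplotypes, reads, truth."""

    config: SimulationConfig
    reference: ReferenceSequence
    haplotypes: tuple[str, str]
    variants: list[SimulatedVariant]
    reads: list[AlignedRead]
    truth: dict[str, int] = field(default_factory=dict)  # read_id -> haplotype

    @property
    def het_variants(self) -> list[SimulatedVariant]:
        return [v for v in self.variants if v.genotype == "het"]

    def het_sites_covered(self, read: AlignedRead) -> int:
        return sum(1 for v in self.het_variants if read.start <= v.position < read.end)


def simulate_diploid(config: SimulationConfig | None = None) -> DiploidSimulation:
    """Generate a reproducible diploid dataset from ``config``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    length = config.genome_length

    ref_idx = rng.integers(0, 4, size=length)
    reference = "".join(_BASES[ref_idx])

    draws = rng.random(length)
    het_positions = np.flatnonzero(draws < config.het_snp_rate)
    hom_positions = np.flatnonzero(
        (draws >= config.het_snp_rate)
        & (draws < config.het_snp_rate + config.hom_snp_rate))

    hap = [list(reference), list(reference)]
    variants: list[SimulatedVariant] = []
    for pos in het_positions:
        alt = _other_base(rng, reference[pos])
        carrier = int(rng.integers(1, 3))
        hap[carrier - 1][pos] = alt
        variants.append(SimulatedVariant(int(pos), reference[pos], alt, "het", carrier))
    for pos in hom_positions:
        alt = _other_base(rng, reference[pos])
        hap[0][pos] = alt
        hap[1][pos] = alt
        variants.append(SimulatedVariant(int(pos), reference[pos], alt, "hom", None))
    variants.sort(key=lambda v: v.position)
    if not variants:
        logger.warning("simulation produced zero variants "
                       "(rates %.2g/%.2g over %d bp)",
                       config.het_snp_rate, config.hom_snp_rate, length)
    haplotypes = ("".join(hap[0]), "".join(hap[1]))

    n_reads = max(1, round(config.depth * length / config.read_length_mean))
    lengths = rng.normal(config.read_length_mean, config.read_length_sd, size=n_reads)
    lengths = np.clip(np.rint(lengths), config.min_read_length, length).astype(int)
    starts = rng.integers(0, length - lengths + 1)
    origins = rng.integers(1, 3, size=n_reads)

    qual = config.base_quality
    reads: list[AlignedRead] = []
    truth: dict[str, int] = {}
    order = np.lexsort((np.arange(n_reads), starts))
    for serial, idx in enumerate(order):
        start, rlen, origin = int(starts[idx]), int(lengths[idx]), int(origins[idx])
        seq = np.frombuffer(haplotypes[origin - 1][start:start + rlen].encode(),
                            dtype="S1").astype("U1")
        if config.substitution_error_rate > 0:
            err = rng.random(rlen) < config.substitution_error_rate
            for qpos in np.flatnonzero(err):
                seq[qpos] = _other_base(rng, seq[qpos])
        read_id = f"{config.contig}_r{serial:05d}"
        pairs = tuple((start + k, str(seq[k]), qual) for k in range(rlen))
        reads.append(AlignedRead(read_id=read_id, contig=config.contig,
                                 start=start, aligned_pairs=pairs,
                                 mapping_quality=config.mapping_quality))
        truth[read_id] = origin

    return DiploidSimulation(config=config,
                             reference=ReferenceSequence(config.contig, reference),
                             haplotypes=haplotypes, variants=variants,
                             reads=reads, truth=truth)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def write_simulation(sim: DiploidSimulation, out_dir) -> dict[str, str]:
    """Write FASTA (+.fai), sorted SAM and indexed BAM, variant and truth TSVs.

    Returns the paths keyed by kind. The SAM is plain text for inspection;
    the BAM (+.bai) is what the haplotagger consumes.
    """
    import pysam

    os.makedirs(out_dir, exist_ok=True)
    paths = {kind: os.path.join(out_dir, name) for kind, name in [
        ("fasta", "ref.fa"), ("sam", "reads.sam"), ("bam", "reads.bam"),
        ("variants", "variants.tsv"), ("truth", "truth.tsv")]}

    with open(paths["fasta"], "w") as fh:
        fh.write(f">{sim.reference.name}\n")
        seq = sim.reference.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(paths["fasta"])

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": sim.reference.name, "LN": len(sim.reference.sequence)}],
    }
    for kind, mode in (("sam", "wh"), ("bam", "wb")):
        with pysam.AlignmentFile(paths[kind], mode, header=header) as out:
            for read in sim.reads:
                out.write(_to_segment(read, out.header))
    pysam.index(paths["bam"])

    pd.DataFrame(
        [(sim.reference.name, v.position + 1, v.ref, v.alt, v.genotype,
          v.haplotype if v.haplotype is not None else 0)
         for v in sim.variants],
        columns=["contig", "position", "ref", "alt", "genotype", "haplotype"],
    ).to_csv(paths["variants"], sep="\t", index=False)

    pd.DataFrame(sorted(sim.truth.items()), columns=["read_id", "haplotype"]
                 ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _to_segment(read: AlignedRead, header) -> "pysam.AlignedSegment":
    import pysam

    seg = pysam.AlignedSegment(header)
    seg.query_name = read.read_id
    seg.reference_name = read.contig
    seg.reference_start = read.start
    seg.mapping_quality = read.mapping_quality
    seg.flag = 0
    bases = [b for _, b, _ in read.aligned_pairs if b is not None]
    quals = [q for _, b, q in read.aligned_pairs if b is not None]
    seg.query_sequence = "".join(bases)
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr((q if q is not None else 30) + 33) for q in quals))
    seg.cigartuples = [(0, len(bases))]  # full match; substitutions only
    return seg


def truth_compare_tags(tags, truth: dict[str, int]) -> pd.DataFrame:
    """Join predicted per-read tags with truth haplotypes.

    ``tags`` is an iterable of objects with read_id/haplotag/phase_block/votes
    (e.g. :class:`localtag.read_tagger.ReadHaplotag`). Raises if any predicted
    read is missing from the truth table.
    """
    rows = []
    for t in tags:
        if t.read_id not in truth:
            raise KeyError(f"read {t.read_id!r} absent from truth table")
        rows.append((t.read_id, t.haplotag, t.phase_block,
                     t.votes[0], t.votes[1], truth[t.read_id], t.haplotag != 0))
    return pd.DataFrame(rows, columns=["read_id", "haplotag", "phase_block",
                                       "votes1", "votes2", "true_haplotype",
                                       "tagged"])
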