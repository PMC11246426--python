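"""Candidate generation from pileups and the heterozygous-SNP filter."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from localtag import (AlignedRead, Candidate, CandidateFilterConfig,
                      ReferenceSequence, collect_allele_support,
                      select_het_snp_candidates)

REF = ReferenceSequence("chr1", "A" * 200)
PERMISSIVE = CandidateFilterConfig(min_alt_fraction=0.0)


def _read(read_id, start, bases, qual=30, mapq=60):
    pairs = tuple((start + k, b, None if b is None else qual)
                  for k, b in enumerate(bases))
    return AlignedRead(read_id, "chr1", start, pairs, mapping_quality=mapq)


class TestCollectAlleleSupport:
    def test_all_reference_reads_give_no_candidates(self):
        reads = [_read(f"r{i}", 0, "A" * 50) for i in range(10)]
        assert collect_allele_support(reads, REF, (0, 200)) == []

    def test_balanced_het_column(self):
        reads = [_read(f"ref{i}", 90, "A" * 20) for i in range(5)]
        reads += [_read(f"alt{i}", 90, "A" * 10 + "C" + "A" * 9) for i in range(5)]
        cands = collect_allele_support(reads, REF, (0, 200))
        assert len(cands) == 1
        cand = cands[0]
        assert (cand.position, cand.ref_allele, cand.alt_alleles) == (100, "A", ("C",))
        assert len(cand.support["A"]) == 5 and len(cand.support["C"]) == 5

    def test_deleted_base_supports_no_allele(self):
        # hand-enumerated 3-read pileup: r1 ref, r2 alt C, r3 deletion at 100
        r1 = _read("r1", 98, "AAAAA")
        r2 = _read("r2", 98, "AACAA")
        r3 = AlignedRead("r3", "chr1", 98,
                         ((98, "A", 30), (99, "A", 30), (100, None, None),
                          (101, "A", 30), (102, "A", 30)))
        cands = collect_allele_support([r1, r2, r3], REF, (0, 200),
                                       CandidateFilterConfig(min_alt_support=1,
                                                             min_alt_fraction=0.0))
        (cand,) = [c for c in cands if c.position == 100]
        assert cand.support["C"] == frozenset({"r2"})
        assert cand.support["A"] == frozenset({"r1"})  # r3 supports nothing

    def test_quality_floors_exclude_reads(self):
        good = [_read(f"g{i}", 90, "A" * 10 + "C" + "A" * 9) for i in range(2)]
        low_bq = [_read(f"b{i}", 90, "A" * 10 + "C" + "A" * 9, qual=5)
                  for i in range(3)]
        low_mq = [_read(f"m{i}", 90, "A" * 10 + "C" + "A" * 9, mapq=0)
                  for i in range(3)]
        cands = collect_allele_support(good + low_bq + low_mq, REF, (0, 200),
                                       PERMISSIVE)
        (cand,) = cands
        assert cand.support["C"] == frozenset({"g0", "g1"})

    def test_positions_outside_window_excluded(self):
        reads = [_read(f"r{i}", 90, "A" * 10 + "C" + "A" * 9) for i in range(5)]
        assert collect_allele_support(reads, REF, (0, 100), PERMISSIVE) == []
        assert collect_allele_support(reads, REF, (150, 100), PERMISSIVE) == []

    def test_allele_fraction_floor(self):
        # 2 alt reads out of 20: passes the count floor, fails the 20% floor
        reads = [_read(f"ref{i}", 90, "A" * 20) for i in range(18)]
        reads += [_read(f"alt{i}", 90, "A" * 10 + "C" + "A" * 9) for i in range(2)]
        assert collect_allele_support(reads, REF, (0, 200)) == []
        assert len(collect_allele_support(reads, REF, (0, 200), PERMISSIVE)) == 1


def _candidate(ref_n, alts):
    support = {"A": frozenset(f"ref{i}" for i in range(ref_n))}
    for allele, n in alts.items():
        support[allele] = frozenset(f"{allele}{i}" for i in range(n))
    return Candidate(100, "A", tuple(alts), support)


class TestSelectHetSnpCandidates:
    @pytest.mark.parametrize("ref_support,kept", [(0, False), (2, False),
                                                  (3, True), (10, True)])
    def test_single_alt_needs_reference_support(self, ref_support, kept):
        cands = [_candidate(ref_support, {"C": 5})]
        assert (select_het_snp_candidates(cands) == cands) is kept

    def test_non_snp_alt_eliminated(self):
        assert select_het_snp_candidates([_candidate(5, {"ACT": 4})]) == []

    def test_multi_alt_kept_regardless_of_ref_support(self):
        cands = [_candidate(0, {"C": 5, "G": 4})]
        assert select_het_snp_candidates(cands) == cands

    def test_order_preserved(self):
        a = _candidate(5, {"C": 5})
        b = Candidate(50, "A", ("G",),
                      {"A": frozenset({"x", "y", "z"}), "G": frozenset({"w"})})
        assert select_het_snp_candidates([b, a]) == [b, a]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 6),
                              st.sampled_from(["C", "G", "T", "CT", "ACT"]),
                              st.integers(1, 6))))
    def test_filter_idempotent_and_snv_only(self, spec):
        cands = [_candidate(ref_n, {alt: alt_n}) for ref_n, alt, alt_n in spec]
        once = select_het_snp_candidates(cands)
        assert select_het_snp_candidates(once) == once
        assert all(len(a) == 1 for c in once for a in c.alt_alleles)


def test_every_planted_het_site_recovered_on_clean_simulation(sim_clean):
    """Error-free 30x diploid: every planted het SNP becomes a retained
    candidate (both alleles are carried by ~15 reads each)."""
    config = CandidateFilterConfig()
    retained = set()
    for start in (0, 25_000):
        window = (start, start + 25_000)
        cands = collect_allele_support(sim_clean.reads, sim_clean.reference,
                                       window, config)
        retained |= {c.position for c in select_het_snp_candidates(cands, config)}
    planted = {v.position for v in sim_clean.het_variants}
    covered = set()
    for variant in sim_clean.het_variants:
        per_hap = {
            hap: sum(1 for r in sim_clean.reads
                     if r.start <= variant.position < r.end
                     and sim_clean.truth[r.read_id] == hap)
            for hap in (1, 2)}
        alt_cov = per_hap[variant.haplotype]
        ref_cov = per_hap[3 - variant.haplotype]
        total = alt_cov + ref_cov
        if (ref_cov >= config.min_ref_support
                and alt_cov >= max(config.min_alt_support,
                                   math.ceil(config.min_alt_fraction * total))):
            covered.add(variant.position)
    assert covered <= retained
    assert retained <= planted  # no spurious het candidates without errors
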