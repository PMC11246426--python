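# Methods

## Problem and model

Long reads routinely span several heterozygous SNVs, so the reads themselves
carry enough linkage to split a diploid sample's alignment into its two
parental haplotypes over short ranges. `localtag` performs that split
*locally*: the genome is processed in independent windows (default 25 kb),
and inside each window every read receives a haplotag — 1 or 2 for the two
locally defined haplotypes, 0 when the evidence is absent or contradictory.
Labels are arbitrary per phase block; no attempt is made to stitch blocks
into chromosome-scale haplotypes. This is the regime in which a downstream
genotyper only needs reads *grouped* by haplotype, not globally phased, and
it is what keeps the method a single linear pass with no variant calls as a
prerequisite.

The pipeline per window:

1. **Candidate discovery.** A pileup over the window yields positions where
   reads disagree with the reference. A site enters the graph only if it
   looks like a heterozygous pure SNV (rules below).
2. **Allele graph.** Each retained position contributes one vertex per
   allele: every supported alternate base, plus the reference base when it
   has adequate support (`min_ref_support`, default 3 — the same threshold
   that defines "het-like"). `R(V)` is the set of reads supporting vertex
   `V`. Consecutive positions are joined by an edge wherever
   `R(V_1) ∩ R(V_2) ≠ ∅`.
3. **Pair-score dynamic program.** The DP state at position `n` is an
   ordered vertex pair `(V_{n,i}, V_{n,j})` — `i` labelled haplotype 1, `j`
   haplotype 2, `i = j` allowed. Scores are integer set cardinalities:

       S(V_{1,i}, V_{1,j}) = |R(V_{1,i}) ∪ R(V_{1,j})|

       S(V_{n,i}, V_{n,j}) = max over previous pairs (k, l) with edges
           E(V_{n-1,k}, V_{n,i}) and E(V_{n-1,l}, V_{n,j}) of
           S(V_{n-1,k}, V_{n-1,l})
             + |R(V_{n-1,k}, V_{n,i}) ∪ R(V_{n-1,l}, V_{n,j})
                ∪ R*(V_{n,i}) ∪ R*(V_{n,j})|

   where `R(V_1, V_2)` is the edge read set and `R*(V)` the "new" reads that
   overlap `V` but start after the previous position (they let coverage
   gaps on one haplotype heal). Backtracking from the best final pair labels
   the alleles on the optimal path.
4. **Read voting.** A read votes with every labelled allele it *supports*
   (its base equals the vertex allele; spanning the position is not enough).
   Majority wins; ties — including zero votes — give haplotag 0. A vertex
   that received both labels (an `i = j` step) adds one vote to each side
   and is therefore neutral.
5. **Output.** Tags are written back as the standard `HP`/`PS` SAM auxiliary
   tags; `PS` is the leftmost 1-based reference position of the phase
   segment. Reads spanning a window boundary are tagged by the window
   containing their alignment start.

## Graph repair and segmentation

If some vertex at a position has no incoming edge while a sibling vertex
does, artificial edges connect it to *every* vertex of the previous
position. They carry empty read sets — they exist purely so the chain stays
extendable and contribute no support to any score. If *no* vertex at a
position has an incoming edge, the chain genuinely breaks: the window is
split there, each maximal connected run of positions becomes its own segment
with its own initialization, DP, and phase-block identifier.

## Previous-pair enumeration

Initialization stores each unordered pair once (canonically ordered,
`i ≤ j`; the union is symmetric). The recursion evaluates **all ordered**
current pairs but extends each **stored** previous pair exactly once, in its
stored orientation. Two consequences:

* At the step right after initialization this enumerates exactly the
  canonical pairs, which makes, e.g., the two ordered scores of a 2×2
  instance genuinely asymmetric — that is the arithmetic the built-in worked
  example (`localtag selftest`) reproduces, including its ordered score of
  14 opposite a 19.
* At later steps, whichever orientation of a pair was admissible and scored
  is the one extended. This matters: vertex order within a position (REF
  first, then alternates lexicographically) is arbitrary with respect to
  haplotypes, so the phase-correct pair lands in non-canonical orientation
  about half the time. Extending only canonically ordered states would
  silently drop the phase-correct chain at such positions and collapse the
  DP into uninformative `(i, i)` reference chains — zero reads tagged. (We
  verified exactly that failure mode on an error-free simulation before
  adopting the stored-orientation rule.)

A fully symmetric mode (`--symmetric-pairs`) also extends the mirror of
every stored pair. Both modes provably reach the same segment optimum (the
objective is mirror-symmetric); per-pair intermediate scores can differ.
Ties are always broken by the first pair in canonical enumeration order, so
every result is deterministic.

An independent brute-force oracle (`brute_force_best_score`) enumerates all
admissible pair sequences outright — first pair canonical (lossless by
mirror symmetry), then any ordered pair — and scores them with the same
cumulative-union formula without touching the DP tables. The test suite
checks DP = oracle on hundreds of random instances in both modes.

## Candidate filtering and its parameters

| parameter | default | units | role |
|---|---|---|---|
| `window_size` | 25 000 | bp | independent processing unit and phase-block ceiling |
| `min_ref_support` | 3 | reads | ref vertex creation; single-alt candidates with less ref support are treated as homozygous-alt and dropped |
| `min_alt_support` | 2 | reads | minimum reads on an alt allele |
| `min_alt_fraction` | 0.20 | fraction | minimum share of the eligible coverage an alt allele must reach |
| `min_base_quality` | 10 | phred | pileup entry floor per base |
| `min_mapping_quality` | 5 | phred | pileup entry floor per read |

The het selection rules proper are: drop any candidate with a non-SNV
alternate allele, and drop single-alt candidates whose reference support is
below `min_ref_support`. Multi-alt candidates are kept regardless of
reference support (both haplotypes may be non-reference).

`min_alt_fraction` deserves its own justification. A heterozygous site has
an expected allele fraction of 0.5, so a 0.20 floor tolerates 2.5-fold
allelic imbalance. Without it, a pure count threshold of 2 reads admits
recurrent sequencing errors as "het" sites in droves (at 30× and a 1%
substitution rate, roughly ten per kilobase — an order of magnitude more
than true het sites at human-like density). Each such site is poison for
phasing: its reference vertex dwarfs the error vertex, the DP's best path
takes the `(REF, REF)` state there, and because that state is symmetric the
haplotype orientation downstream of the site degenerates to a tie broken by
arbitrary vertex order. Phasing site selection therefore prefers precision
over recall: a missed borderline het costs little when its neighbours carry
the phase, a false het actively scrambles it.

## The simulator

`simulate_diploid` emulates exactly the structure the algorithm relies on:
a uniform-ACGT reference (default 50 kb), het SNVs at a per-base rate
(default 10⁻³, human-like) planted on a fairly chosen haplotype, hom SNVs
(default 5·10⁻⁴) on both, reads of truncated-normal length (default
10 kb ± 1.5 kb, min 500 bp — a long-read regime) drawn uniformly from the
two haplotypes at a configured total depth (default 30×), with i.i.d.
substitution errors (default 1%). Base qualities are constant and
calibrated to the error rate (phred of the configured rate), so the quality
floors act as they would on calibrated real data. Every read's haplotype of
origin is recorded as truth.

What it deliberately does **not** model: indel errors (the method discards
non-SNV alleles anyway), platform error profiles (homopolymer artifacts,
quality waves, chimeric reads), coverage biases, mapping ambiguity (reads
are emitted at their true coordinates with full-match CIGARs), and
reference N stretches. Passing tests on these simulations therefore
demonstrate the algorithm's correctness under clean diploid structure and
uniform noise — not robustness to alignment artifacts or systematic
basecalling error, which on real data are handled upstream by the aligner
and by candidate filtering margins.

## Evaluation metric

`switch_aware_accuracy` joins predicted tags with truth per phase block,
scores both label mappings ({1→1, 2→2} and {1→2, 2→1}), keeps the better
one, and aggregates matches over blocks; haplotag-0 reads never count as
errors but are visible in the reported tagged fraction. With no tagged
reads the accuracy is reported as undefined rather than 0. Block-local
permutation matching is the correct reading for a method whose labels are
explicitly local; it also makes the metric invariant under global and
per-block label flips, which the tests assert.

## Numerical and degenerate-input choices

* All scores are integers; no floating point exists anywhere in the DP.
* Ties (best previous pair, best final pair, best segment for a
  multi-segment read) resolve to the first candidate in canonical
  enumeration order; multi-segment vote ties and within-segment vote ties
  give haplotag 0.
* Empty windows, windows with no candidates, and candidate-free graphs are
  all legal and tag every read 0; empty vertex groups and empty score
  tables raise immediately (they indicate a caller bug, not data).
* Reads whose base at a candidate position matches no retained allele
  support nothing there; deletions and N bases likewise.
* Internal coordinates are 0-based half-open throughout; 1-based conversion
  happens only at the SAM/`PS`/region-string boundary.

## Verification scale

The shipped checks run at desk scale, chosen so the full suite completes in
well under a minute of DP work: oracle equivalence on 200+ random segments
(≤5 positions, ≤3 vertices/position, ≤30 reads), and simulations of a 50 kb
diploid genome at 30× (≈150 reads, ≈50 het sites, two windows) with 0% and
1% substitution errors. On the error-free simulation the switch-aware
accuracy for reads covering ≥2 het sites is exactly 1.0; with 1% errors the
suite requires ≥0.99 accuracy and ≥0.80 tagged fraction.

## Known limitations and scope

* Phase blocks are at most window-sized; no global phasing, no phasing VCF.
* Only SNVs are used; dense indel regions yield sparse graphs and more
  haplotag-0 reads.
* A surviving false-het site mid-segment (e.g. from systematic errors above
  the fraction floor) still degrades orientation downstream of it — the
  algorithm has no mechanism to recover phase across a site where the best
  state is homozygous; real-data accuracy depends on candidate filtering
  quality.
* The published full-scale results for this family of methods — whole-
  chromosome haplotagging accuracy on GIAB HG002 real reads (≈99% range)
  and all variant-calling F1 benchmarks — require GIAB long-read data,
  trio-phased truth sets and a trained deep-learning genotyper. They are
  **out of scope** here and are not reproduced by this package; the
  simulation and worked-example checks above are the desk-scale substitute
  for validating the haplotagging algorithm itself.
* CRAM input, read realignment and duplex/simplex platform distinctions are
  out of scope.
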