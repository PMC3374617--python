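# Methods

## Model and assumptions

`noveltax` treats novelty discovery as a two-evidence problem. The first
evidence stream is comparative: a long read (200–600 bp amplicon or shotgun
16S sequence) is compared to a reference panel, and reads whose nearest
qualifying neighbor falls below 97% identity are *potentially* novel. The
second stream is physical: an independent short paired-end shotgun library
from the same community must reconstruct the candidate base-for-base. The
core assumption is that a genuine sequence present in the community DNA is
sampled by many short fragments whose perfect (100%-identity) alignments
tile it contiguously, while an artifact — a PCR chimera or a read with a
miscalled, uncalled, inserted or deleted base — contains at least one
position that no perfect short read can cross. Validation therefore never
consults a database; it reads the geometry of perfect alignments only.

Support alignments are exact matches by construction. Because the support
criterion is 100% identity, exact substring matching (seed-and-verify with
a seed of the minimum support length) is both sufficient and correct, and
avoids any aligner heuristics. The general nearest-neighbor aligner is a
local alignment (match +1, mismatch −1, gap open −2, gap extend −1, both
strands, backed by Biopython's `PairwiseAligner`); percent identity is
matching columns over all alignment columns, gap columns included in the
denominator. The screening contract is on identity and length rules, not
on reproducing any particular aligner's bitscores; pre-computed alignments
in 12-column tabular form are accepted as an alternative input, in which
case column 12 serves as the ranking score.

## Parameters

All thresholds live in `ValidationConfig`, serialized as flat `key=value`
text with optional `key@DATASET_TAG=value` per-dataset overrides.

| parameter | default | meaning |
|---|---|---|
| `novelty_identity_max` | 0.97 | novelty ceiling; strict `<` (0.970 is *not* novel) |
| `nn_min_align_len` | 100 bp | minimum qualifying neighbor alignment |
| `nn_max_unaligned_end` | 5 bp | unaligned query bases allowed per end, unless that end overhangs the target |
| `derep_identity` / `derep_coverage` | 1.00 / 0.95 | dereplication: identity over the shorter read's length |
| `support_min_len` | 60 bp | minimum aligned length of a perfect short-read placement |
| `support_breadth_wgs` | 1.00 | shotgun candidates: coverage over 100% of length (inclusive) |
| `support_breadth_amplicon` | 0.95 | amplicon candidates: strictly greater than 95% (their ends were not stringently quality-trimmed) |
| `valley_floor` / `valley_shoulder` | 70 / 90 bp | dip-and-recover thresholds on per-start maximum aligned length |
| `tiling_min_overlap` / `tiling_min_extend` | 20 / 20 bp | chain constraints; the extension is waived for the final step reaching the last covered base |
| `pair_test_min_depth` / `pair_test_min_len` | 500 / 200 | spanning-pair gate, both strict `>` |
| `pair_span_frac` | 0.90 | required mate-pair outer span, inclusive |
| `extended_cluster_identity` | 0.97 | OTU clustering and extended-cohort co-clustering |
| `primer_word_size` | 7 | exact seed for ungapped primer matching |
| `insert_min` / `insert_max` | 100 / 500 bp | fragment-length band of the short-read library |

The unaligned-end rule is evaluated per query end independently: each end
passes if its unaligned bases are ≤5 or project past the corresponding
target end (on the minus strand the query's left end faces the target's
right end). The overhang exemption exists because database entries are
often trimmed — a read cannot be penalized for extending past where its
neighbor simply stops. The primer-context relaxation serves the same
situation when the trimmed content is a primer: for reads with fewer than
100 consecutive non-primer bases, the minimum alignment length is relaxed
to the longest non-primer stretch. A read that is entirely primer relaxes
to 0 and is flagged `degenerate_all_primer` in the report.

## The valley detector

The irregularity signature near a barrier is that the *maximum aligned
length per start position* tapers as starts approach the barrier (only
ever-shorter reads can fit) and snaps back after it. This shape is
operationalized as an automaton over start positions that carry at least
one alignment: a valley exists when some position with value ≤70
(`valley_floor`) lies strictly between two positions with value ≥90
(`valley_shoulder`); the deepest such floor is reported. A terminal window
one maximum-read-length wide is exempt, since aligned lengths are
truncated at the candidate end for the innocent reason that the candidate
stops.

The automaton is exact for length-trimmed short-read libraries (uniform
read length), where per-start maxima are bimodal (full length or absent)
and a sub-shoulder value can only be produced by a genuine barrier. With
heterogeneous read lengths (e.g. 60–100 bp) a lone short read starting at
an interior position also produces a floor value, so the automaton
over-calls valleys on clean candidates; with such libraries the breadth
and tiling-path checks carry the discriminative load, and the valley
thresholds should be tightened or the detector read as descriptive. The
default synthetic library therefore uses a single read length (100 bp);
the generator accepts a length range for studying the valley signature
itself, which the test suite does on chimera junctions under deep,
variable-length coverage.

## Tiling-path search

The chain is sought greedily by farthest reach: start from the alignment
covering the leftmost covered base, repeatedly take the farthest-reaching
alignment that overlaps the current end by ≥20 bp, requiring ≥20 bp of
extension except on a final step that reaches the last covered base.
Greedy farthest-reach can overshoot in rare configurations (taking the
longest first alignment may skip a stepping stone that a shorter start
would have chained through), so when it fails the search falls back to a
complete memoized search over unique alignment intervals — continuation
options depend only on the current chain end, and ends increase strictly
along a chain, so the state space is the interval set and the search is
exact and O(n²). The test suite verifies success/failure equivalence with
an independent exhaustive enumeration on random support sets. Any one
valid chain is accepted; ties prefer farther reach, then leftmost start.

## Classification order and reporting

Checks run in a fixed order — breadth, valley, tiling path, spanning
pair — and the first failure names the verdict; all evidence fields
(breadth, valley position/value, chain, best spanning fragment, median
depth) are populated regardless, so a verdict never hides the remaining
signals. The spanning-pair test applies only above median depth 500 and
length 200; candidates passing all applicable checks are reported
`VALIDATED` whether or not the pair test applied, with the gate decision
preserved in `pair_test_applied` (an explicit
`PAIR_TEST_NOT_APPLICABLE_VALIDATED` status value exists for callers who
want to re-label). Median depth is taken over all candidate positions,
zero-depth positions included (`median_covered_only` switches to covered
positions only). The classifier sorts supports internally, so results are
invariant to input order.

## Synthetic data

The generator emulates the statistical regime the method targets:

* **Reference panel** — independent mutants of a random 1.5-kb root,
  substituted until all pairwise identities are ≤97% (verified by
  alignment). Default five taxa at ≥3% mutual divergence.
* **Novel variants** — substitution-only derivatives of a parent
  reference, tuned until aligned identity sits within ±0.005 of the target
  (default 0.93, inside the 90–96% band of interest). Substitution-only
  divergence keeps the novelty signal separable from platform error.
* **Long reads** — windows drawn by taxon abundance, uniform position and
  uniform length (100–600 bp shotgun-like by default), with independent
  per-base substitution/insertion/deletion/uncalled-base processes and a
  configurable fraction of bimeric chimeras spliced at a uniform
  breakpoint. With `junction_guard_k` set, splices are resampled until no
  guard-length window crossing the junction occurs in any taxon on either
  strand; k = 60 (the minimum support length) guarantees that no perfect
  support alignment can bridge the join, since every aligned segment of
  ≥60 bp crossing the junction contains a crossing 60-mer.
* **Short pairs** — fragments uniform in 100–500 bp, mates taken from the
  fragment ends (minus mate reverse-complemented), fragment counts set so
  the mean per-taxon depth equals `mean_depth` (default 50). Error-free by
  default; an optional per-base substitution rate models miscalls.

Everything derives from a single integer seed; identical specifications
produce byte-identical FASTA output.

What the generator does *not* model: homopolymer-length errors typical of
pyrosequencing, PCR amplification bias, chimeras with more than two
parents, quality-score structure, and non-uniform fragment or read-start
distributions. Passing tests therefore demonstrate the logic of the
screen and validator under idealized sampling, not performance on real
libraries — in particular, real chimeras between closely related parents
whose junction lies in a conserved region (where a crossing read *does*
match a parent) are intrinsically invisible to any coverage-based method,
which is why the junction guard exists in the generator rather than as a
claim about all chimeras.

Two corner cases are handled explicitly in ground-truth construction. A
single-base error is only a testable error if it makes the read
distinguishable from every taxon: deleting a base inside a homopolymer,
for instance, yields a sequence identical to a correct shorter read, which
coverage-based validation rightly accepts; the error injector resamples
positions until the mutated read is not a substring of any taxon on either
strand. Conversely, a read drawn from a novel taxon can itself fail to be
novel — a short window may locally exceed 97% identity to the parent —
so read-level novelty recall on simulated data is expected to sit slightly
below 1 at small read lengths.

## Numerical choices

Boundary semantics follow the stated rules exactly: novelty is strict
(`identity < 0.97`), the amplicon breadth rule is strict (`> 0.95`), the
shotgun breadth rule is inclusive (`= 1.0`, computed as an exact integer
ratio), the pair-test gates are strict (`> 500`, `> 200`) and the span
requirement inclusive (`≥ 0.90`). Nearest-neighbor ties break by higher
identity, then leftmost target start, then lexicographic target id.
Greedy clustering visits reads by decreasing length with id as
tie-breaker, so the partition is order-independent when lengths are
distinct. Degenerate inputs are defined: empty support sets yield breadth
0 and verdict `INSUFFICIENT_BREADTH`; empty cultured sets yield no
cultured neighbor; an empty verdict list writes a header-only report.

## Problem sizes

The default test and acceptance configuration uses five 1.5-kb taxa plus
two novel variants, 50 long reads per condition, mean short-read depth 50
(≈5,000 paired reads), ten cohort samples at depth 40, and 100 random
fixtures per oracle-equivalence family. These sizes put every statistical
property (coverage gaps, junction sampling, depth checks) far from its
noise floor while keeping a full run in tens of seconds.

## Known limitations

* Amplicon-style pre-filtering measures coverage against the query (read)
  length; measuring against the target is a defensible alternative the
  config does not currently expose.
* The spanning-pair test uses the outer span of any one fragment's
  alignments; it does not check mate orientation consistency.
* Extended-cohort co-clustering applies the same shorter-sequence coverage
  rule as dereplication (`extended_cluster_coverage`); protocols that
  co-cluster on identity alone should set that coverage near zero.
* OTU clustering is identity-based (the windows being clustered must
  overlap); reads from one taxon sampled at disjoint windows form separate
  OTUs, as any identity-threshold method would.
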