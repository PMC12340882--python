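# Methods

## Sufficient uniqueness

A reference k-mer sampled at position *i* is kept when (1) it has exactly one
hit within edit distance *d₁* in the reference assembly and (2) it has fewer
than *c·N* hits within edit distance *d₂* over all N assemblies (reference
included), *d₂ > d₁*, *c > 1*. Edit distance is unit-cost Levenshtein. The
threshold comparison `count < c·N` is evaluated in real arithmetic with no
rounding: at N = 100 and c = 1.01, 101 hits against a threshold of exactly
101.0 fail. Failing k-mers mask [i, i+k); the complement of the mask within
the *covered footprint* (the union of sampled k-mer spans), with intervals
shorter than `min_region_len` dropped, is the lenient tier; subtracting
merged low-complexity regions longer than `lcr_max_len` (and re-applying the
length filter) gives the strict tier.

Decisions the model statement leaves open, fixed here:

- **k-mers containing N** cannot be aligned confidently and are masked
  (`fail_ambiguous_base`).
- **The pangenome count includes the reference** — it is one of the N
  genomes — and sums collapsed hits genome-wide with no per-genome cap.
- **Strand handling.** The uniqueness search runs on both strands (an
  inverted duplication causes the same mismapping risk); the Hamming rescue
  is forward-only by default, matching the gapless exact-mappability stage
  it mirrors. Hit counting is per (assembly, sequence, strand).
- **Easy regions are confined to the covered footprint**: sequence tails
  shorter than k, and whole sequences shorter than k, were never tested and
  are not declared easy. The final position `L − k` of each sequence is
  always sampled, even off the w-grid, so at w ≤ k the footprint is the
  whole sequence.
- **The 50 bp filter** is applied at the end of lenient derivation and again
  after the strict subtraction.

## Hit search

The search contract is *completeness*: every end-to-end placement of the
query within the radius, on either strand, in any assembly. A hit is keyed
by its start position; `d_start[s] = min_e edit(query, text[s:e])` is the
cost of the best alignment starting at *s* with a free end.

- `find_hits_exact` computes `d_start` for every position with a vectorised
  Sellers dynamic program over the reversed strings (the horizontal DP
  dependency is removed with the prefix-min identity
  `D[j] = min_{l≤j}(t[l] + j − l)`), then recovers each hit's distance and
  end with a small anchored DP. It is the oracle engine: complete by
  construction, used in tests and available via `--engine exact`.
- `find_hits_seeded` splits the query into `max_d + 1` non-overlapping
  pieces. By the pigeonhole principle an alignment with ≤ `max_d` edits
  contains at least one piece exactly, displaced by at most `max_d`; exact
  piece occurrences come from a hash index (one table per piece length,
  built lazily per collection and reused across all sampled k-mers of a
  masking run), and each candidate start is verified with edlib's infix
  (SHW) alignment bounded at `max_d`. Ties on distance break toward the
  shortest alignment, so the two engines return byte-identical hits; a
  randomized equivalence suite (raw and collapsed) enforces this.

**Hit collapsing.** An alignment with *d* edits can shift its start by at
most *d*, so every true locus appears as a run of jittered raw hits. Hits on
the same (assembly, sequence, strand) are chained while successive starts
differ by ≤ `max_d` and each chain counts once, keeping the minimum distance
(leftmost on ties). The collapse radius equals the query radius: jitter is
merged, tandem copies with period > `max_d` stay distinct. Consequence: a
tandem array with period ≤ 3·`max_d` can chain through its jitter into fewer
counted hits; period-10 arrays used in testing stay distinct for d₁ ≤ 3.

**Mappability rescue.** `hamming_hit_count` counts, exhaustively, length-k
reference windows within a substitution budget (default 3) of the query,
using pigeonhole pieces with *unshifted* offsets (substitutions cannot
displace a piece) and vectorised mismatch verification. A sampled k-mer with
≥ 2 windows is masked. In the published pipeline this exact gapless check
patches heuristic misses of the main aligner; the engines here are already
complete, so with radius ≤ d₁ the stage is provably subsumed by condition 1
(a Hamming hit is an edit hit — asserted on random suites), but it is kept
as an independent stage for fidelity. Unlike edit-distance counting it has
no jitter collapse: two overlapping windows both count, which is what makes
homopolymers of length ≈ k sensitive (see simulator notes).

## Symmetric DUST

The score of a window is `Σ_t c_t(c_t−1)/2 / (n−1)` over its `n = len − 2`
overlapping triplets (64 types); defaults are window 64 and threshold 2.0,
the classical integer threshold 20 in tenths. A *perfect interval* scores
strictly above the threshold, has no proper subinterval scoring strictly
higher, and is not properly contained in another reported interval; merged
(possibly chained beyond the window length) perfect intervals form the LCR
regions, and only merged regions strictly longer than 18 bp are excised from
strict. Both the score threshold and the length cutoff are strict
inequalities, pinned by boundary tests: poly-A of length 6 scores exactly
2.0 and is not reported, length 7 scores 2.5 and is; an 18 bp dinucleotide
run survives in strict, a 19 bp run does not. Triplets containing N are
undefined: N splits the sequence into independently scanned runs. The scan
is O(L·window) with an incremental triplet tally plus an O(L·window)
subinterval-maximum recurrence; a literal brute-force enumeration of the
definition is the test oracle. Note that long arrays of period ≤ 4 (e.g.
ACGT-repeats) concentrate on few triplet types and legitimately exceed the
threshold.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| k | 151 | k-mer length; matches the dominant short-read length |
| w | 10 | sampling stride (one k-mer per w bases) |
| c | 1.01 | copy-number tolerance; masked when pangenome hits ≥ c·N |
| d1 | 3 | reference-uniqueness edit radius |
| d2 | 7 | pangenome edit radius (must exceed d1) |
| hamming_d | 3 | gapless rescue radius, forward strand |
| min_region_len | 50 bp | fragments shorter than this are dropped |
| lcr_max_len | 18 bp | merged LCRs longer than this leave strict |
| sdust_window / sdust_threshold | 64 bp / 2.0 | DUST scan |

Raising *c* can only shrink the masked set (easy bases non-decreasing);
raising *d₂* can only grow hit counts on fixtures without chain-merging
(easy bases non-increasing). Both directions are asserted in the sweep
tests. For toy runs at k = 31 the radii are scaled proportionally
(d1 = 1, d2 = 2, hamming 1): pigeonhole pieces at k = 31 with d2 = 7 would
be 3–4 bp and generate candidates at every position.

## Synthetic pangenomes

`simulate_pangenome` builds a seeded uniform-random reference plus N−1
haploid single-contig samples (mutated copies of the reference) with planted
features: reference duplications (mirror copy elsewhere in the reference,
divergence ≤ d₁), tandem motif arrays, short low-complexity runs, extra
sample-carried copies, and sample deletions. Truth labels are derived from
the construction, never from the pipeline.

What makes the truth *exact* rather than approximate:

- **N spacers around planted copies.** A k-mer partially overlapping a plain
  copy is masked only stochastically (its overhang may or may not align
  cheaply against the copy's random flank). Mirror copies, tandem arrays and
  inserted sample copies are therefore flanked by N runs of width d₂ + 1: N
  matches nothing, so a k-mer with overhang *t* sits at edit distance
  exactly *t* from the guarded copy — hits exist for t ≤ d₂ and never
  beyond — and any k-mer crossing a spacer is masked as ambiguous anyway.
  Every masking boundary falls on a computable coordinate.
- **Divergence placed centrally.** Substitutions distinguishing a duplicated
  copy sit ≥ k from the locus ends, so edge-overlapping k-mers never span
  one, and the overhang arithmetic above stays exact (loci carrying
  divergence must be ≥ 2k + divergence long).
- **Pinned run flanks.** A planted low-complexity run is pinned to exactly
  its configured length with a short rotation-of-ACGT pattern on each side:
  in any window of ≤ 4 consecutive flank bases all bases are pairwise
  distinct and the first differs from the run's edge base, which forces ≥
  hamming_d + 1 mismatches at every nonzero window shift. Without this, a
  run of length k−1 whose neighbour base continues its periodicity becomes a
  multi-mapping k-mer and the mappability stage masks it. Run motifs are
  drawn from a pool with pairwise distinct reverse complements, and
  duplicate motifs are rejected: two identical runs would cross-hit.
- **Noise keeps clear of features.** SNPs are never placed within 2k of a
  planted feature, and losing a hit (deletion, heavily mutated window) can
  never mask a locus, because both conditions are upper-bound tests — which
  is also exactly the deletion-plus-duplication blind spot the model
  inherits.

`expected_regions` converts truth to expected BED sets: masked sampled
positions are those within d₂ of full containment in a duplicated locus
(when the carrier count reaches c·N for sample-carried copies, evaluated
against the analysis parameters) or overlapping a guarded copy extent; their
[i, i+k) spans erode easy sequence by up to k−1 bp beyond each locus. The
strict tier's LCR excision is predicted with the same DUST scan the pipeline
uses — the scan is validated independently against brute force, and reusing
it lets the expectation account for coincidental low-complexity stretches in
the random background. The construction assumes c < 2 (every genome carries
both copies of a reference duplication, so edge k-mers of such loci fail
condition 2 at 2N ≥ c·N).

At snp_rate 0 the pipeline reproduces the expectation base-for-base on the
test configurations (50 kb, N = 20, every feature kind, at both k = 31
scaled and k = 151 defaults); under snp_rate ≤ 0.001 lenient output stays
within the expected envelope, shrinking by at most the predicted erosion.
What the simulator does **not** emulate: real repeat families and segmental
duplication structure, assembly errors, diploidy, structural variation
beyond clean insertion/deletion of whole loci — so passing these tests shows
the masking logic is exact on decidable inputs, not that the coverage
numbers transfer to real genomes.

## Problem sizes and numerics

Toy pipelines use a 50 kb reference with N = 20 (about 5,000 sampled k-mers;
tens of seconds end-to-end), the threshold sweep a 4 kb reference with
N = 100 — large enough that every planted mechanism and both threshold flips
(1 carrier at c = 1.01, 2 at c = 1.02) are exercised, small enough for
interactive runs. The randomized engine-equivalence suite uses 1,000
instances up to 50 kb with k ∈ {11, 31, 151} and radii up to 7; the DUST
oracle suite 500+ sequences up to 300 bp. Integer DP matrices are int32;
DUST scores are float64 ratios of small integers, so equality comparisons
against the brute-force oracle are exact. All randomness flows through
`numpy.random.default_rng` from explicit seeds; identical inputs give
byte-identical BED output (asserted).

## Known limitations

- The deletion-plus-duplication blind spot, inherited from the model.
- Site concordance is exact matching of normalized (seq, pos, ref, alt)
  tuples — haplotype-unaware, so equivalent complex-region representations
  count as errors; adequate for synthetic data, weaker than a
  haplotype-aware comparator on real callsets.
- The Hamming rescue's forward-strand default mirrors the published stage;
  reverse-strand duplications are covered by the edit-distance conditions.
- Desk-scale engines: the hash index holds every piece position in memory;
  collections far beyond a few megabases per assembly call for an FM-index,
  which is out of scope here.
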