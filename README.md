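# panmask

Sample-agnostic **easy regions** for short-read variant calling, derived from
a pangenome of assemblies.

Short-read variant callers look accurate in benchmarks because benchmarks are
restricted to curated per-sample confident regions; genome-wide, error rates
are many times higher. Easy regions are the sample-agnostic counterpart:
intervals where generic callers reach high accuracy without sophisticated
filtering, usable to screen spurious calls in any sample. Reference-only
uniqueness masks (mappability tracks) miss loci that are unique in the
reference but duplicated in other individuals; read-pileup-derived masks are
biased toward the sequencing technology and aligner that produced them.
panmask instead tests reference k-mers directly against a panel of assembled
genomes.

## The model

Let N be the number of genomes, including the reference (assembly 0). A
reference k-mer is **sufficiently unique** if

1. it has exactly **one** hit of edit distance ≤ *d₁* in the reference
   genome, and
2. it has **< c·N** hits of edit distance ≤ *d₂* across all N genomes, with
   *d₂ > d₁* and *c > 1* (tolerance for copy-number gains).

Condition 1 protects against mismapping under sequencing errors and
mutations. Condition 2 catches k-mers that are reference-unique but carry
paralogous copies in non-reference samples: reads from those copies pile up
on the one reference locus and their differences surface as false variants.
(A k-mer deleted in some genomes but duplicated in others evades both
conditions — a documented blind spot.)

One k-mer is sampled every *w* bases (plus the final offset of each
sequence); a failing k-mer at position *i* masks the interval **[i, i+k)**.
Failures include an exhaustive Hamming-distance multi-mapping check on the
reference (radius 3, forward strand, mirroring the exact gapless rescue
stage of the published pipeline) and k-mers containing N. What remains of
the sampled footprint, with fragments shorter than 50 bp dropped, is the
**lenient** tier; additionally excising low-complexity regions longer than
18 bp (symmetric DUST, window 64, threshold 2.0) gives the **strict** tier,
a per-base subset of lenient.

Defaults are the published setting: `k=151, w=10, c=1.01, d1=3, d2=7`,
Hamming radius 3, 50 bp minimum region, 18 bp LCR cutoff.

Two interchangeable hit engines implement the search: an exact
dynamic-programming oracle, and a production engine using pigeonhole seeding
(split the query into `max_d+1` pieces; any placement within `max_d` edits
contains one piece exactly) with edlib infix verification. They return
identical hit sets; tests enforce it.

The package also ships a synthetic pangenome simulator that plants
duplications, tandem repeats, low-complexity runs and deletions with
construction-derived truth labels, so the whole pipeline is testable without
any external data.

## Worked example

Simulate a 50 kb toy pangenome (N = 20) with one planted feature of every
kind, then mask it with proportionally scaled parameters for k = 31:

```sh
$ panmask simulate --config toy.cfg -o sim
[18:25:44] panmask INFO: simulate: N=20, ref 50000 bp, expected lenient 48276 bp / strict 48246 bp

$ panmask mask --ref sim/ref.fa --samples sim/samples \
    -k 31 -w 10 -c 1.01 --d1 1 --d2 2 --hamming 1 -o pm
[18:25:54] panmask INFO: masking chr1: 4998 sampled k-mers, 164 failed
[18:25:56] panmask INFO: easy regions: lenient 48276 bp in 5 intervals, strict 48246 bp in 6 intervals

$ head -5 pm.lenient.bed
chr1	0	3000
chr1	3401	4120
chr1	4581	7970
chr1	8431	16000
chr1	16401	50000
```

The masked gaps are exactly the planted features plus up to k−1 bp of
flanking erosion (any sampled k-mer overlapping a bad locus masks its whole
footprint): the reference duplication at 3000–3400 and its mirror copy near
4200, the tandem array at 8000–8400, and the sample-carried duplication at
16000–16400, which 2 of 19 samples carry — enough to push its pangenome hit
count to 22 ≥ 1.01·20. The planted 30 bp poly-A run at 12000 stays in
lenient but is excised from strict, and the locus deleted in three samples
stays easy (losing hits can never trip an upper-bound threshold). The
outputs are byte-identical to the simulator's `expected.*.bed`.

```sh
$ panmask stats --regions pm.lenient.bed --genome genome.txt --target pm.strict.bed
metric	value
genome_coverage	0.965520
target_coverage	1.000000
subset_fraction_target_in_regions	1.000000
```

96.55% of the toy genome is lenient-easy, and the strict tier is entirely
contained in it.

Other subcommands: `panmask sdust` (FASTA → low-complexity BED),
`panmask mappability` (FASTA → multi-mapping k-mer BED), and
`panmask stats --calls/--truth` for site-level FDR/FNR restricted to a
region set.

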