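"""Sufficient-uniqueness classification and lenient/strict derivation."""

import numpy as np
import pytest

from panmask import (
    GenomeCollection,
    Interval,
    MaskParams,
    SequenceRecord,
    classify_kmer,
    derive_lenient,
    derive_strict,
    mask_reference,
    run_panmask,
    sample_positions,
)

from conftest import random_seq, scaled_params_k31, single_genome


P31 = scaled_params_k31()


class TestMaskParams:
    def test_defaults_are_published_setting(self):
        p = MaskParams()
        assert (p.k, p.w, p.c, p.d1, p.d2) == (151, 10, 1.01, 3, 7)
        assert (p.hamming_d, p.min_region_len, p.lcr_max_len) == (3, 50, 18)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(d1=3, d2=2),
            dict(d1=3, d2=3),
            dict(c=1.0),
            dict(w=0),
            dict(k=5, d2=7),
            dict(hamming_d=-1),
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            MaskParams(**kwargs)


class TestSamplePositions:
    @pytest.mark.parametrize(
        "seq_len,k,w,expected",
        [
            (20, 5, 10, [0, 10, 15]),   # grid plus off-grid tail
            (151, 151, 10, [0]),        # single placement
            (100, 151, 10, []),         # sequence too short
            (21, 5, 8, [0, 8, 16]),     # tail already on grid
        ],
    )
    def test_examples(self, seq_len, k, w, expected):
        assert sample_positions(seq_len, k, w) == expected

    def test_strictly_increasing_and_bounded(self, rng):
        for _ in range(50):
            L = int(rng.integers(1, 500))
            k = int(rng.integers(1, 40))
            w = int(rng.integers(1, 60))
            pos = sample_positions(L, k, w)
            assert pos == sorted(set(pos))
            assert all(0 <= p <= L - k for p in pos)
            if L >= k:
                assert pos[-1] == L - k  # the tail is always testable


class TestClassifyKmer:
    def test_single_genome_unique(self, rng):
        coll = single_genome(random_seq(rng, 800), name="chr1")
        v = classify_kmer(coll, "chr1", 200, P31)
        assert v.status == "unique"
        assert v.ref_hits_d1 == 1          # the self hit
        assert v.pan_hits_d2 == 1          # N = 1: one hit < 1.01

    def test_reference_duplication_fails_condition_one(self, rng):
        core = random_seq(rng, 60)
        seq = random_seq(rng, 300) + core + random_seq(rng, 300) + core + random_seq(rng, 100)
        coll = single_genome(seq, name="chr1")
        v = classify_kmer(coll, "chr1", 310, P31)
        assert v.status == "fail_ref_multi"
        assert v.ref_hits_d1 == 2

    def test_ambiguous_base(self):
        coll = single_genome("ACGT" * 20 + "N" + "ACGT" * 20, name="chr1")
        v = classify_kmer(coll, "chr1", 60, P31)
        assert v.status == "fail_ambiguous_base"

    def test_threshold_comparison_is_real_valued(self, rng):
        """With N = 100 genomes and c = 1.01, one extra copy in one sample
        gives 101 hits against a threshold of exactly 101.0 — and fails,
        because the comparison count < c*N is strict."""
        ref = random_seq(rng, 400)
        locus = ref[150:190]
        samples = [[SequenceRecord("chr1", ref)] for _ in range(99)]
        coll = GenomeCollection([[SequenceRecord("chr1", ref)]] + samples)
        p = MaskParams(k=31, w=10, c=1.01, d1=1, d2=2, hamming_d=1)
        v0 = classify_kmer(coll, "chr1", 150, p)
        assert (v0.pan_hits_d2, v0.status) == (100, "unique")
        # insert one extra copy of the locus into the last sample, far away
        carrier = samples[-1][0].seq[:30] + "NNN" + locus + "NNN" + samples[-1][0].seq[30:]
        coll.assemblies[-1][0] = SequenceRecord("chr1", carrier)
        v1 = classify_kmer(coll, "chr1", 150, p)
        assert (v1.pan_hits_d2, v1.status) == (101, "fail_pan_excess")

    def test_engines_agree_on_verdicts(self, rng):
        seq = random_seq(rng, 600)
        seq = seq + seq[100:180]  # planted tail duplication
        coll = single_genome(seq, name="chr1")
        for i in (0, 100, 340, 600):
            a = classify_kmer(coll, "chr1", i, P31, engine="exact")
            b = classify_kmer(coll, "chr1", i, P31, engine="seeded")
            assert a == b


class TestMaskAndDerive:
    def test_failing_kmer_masks_its_footprint(self, rng):
        # one N at position 45 poisons exactly the sampled k-mers overlapping it
        seq = random_seq(rng, 400)
        seq = seq[:45] + "N" + seq[46:]
        coll = single_genome(seq, name="chr1")
        masked, verdicts = mask_reference(coll, P31)
        k = P31.k
        bad = [v.position for v in verdicts if v.status != "unique"]
        assert bad == [i for i in sample_positions(400, k, 10) if i <= 45 < i + k]
        assert masked.pairs("chr1") == [(min(bad), max(bad) + k)]

    def test_repeat_free_single_genome_is_fully_easy(self, rng):
        seq = random_seq(rng, 1000)
        coll = single_genome(seq, name="chr1")
        lenient = derive_lenient(coll, P31)
        assert lenient.pairs("chr1") == [(0, 1000)]

    def test_reference_shorter_than_k_yields_nothing(self):
        coll = single_genome("ACGTACGT" * 3, name="chr1")  # 24 bp < k = 31
        assert derive_lenient(coll, P31).is_empty()

    def test_planted_duplication_removed_from_lenient(self, rng):
        flank = random_seq(rng, 2000)
        core = random_seq(rng, 300)
        seq = flank + core + random_seq(rng, 2000) + core + random_seq(rng, 1000)
        coll = single_genome(seq, name="chr1")
        lenient = derive_lenient(coll, P31)
        for start in (2000, 4300):
            # every base of both copy interiors is outside the easy regions
            for pos in range(start + P31.k, start + 300 - P31.k, 29):
                assert not lenient.contains("chr1", pos)

    def test_strict_excises_long_lcr_only(self, rng):
        left = random_seq(rng, 500).rstrip("A")
        right = random_seq(rng, 500)
        right = right[1:] if right.startswith("A") else right
        seq = left + "A" * 30 + right
        run = (len(left), len(left) + 30)
        coll = single_genome(seq, name="chr1")
        res = run_panmask(coll, P31)
        assert res.lenient.pairs("chr1") == [(0, len(seq))]
        assert res.strict.pairs("chr1") == [(0, run[0]), (run[1], len(seq))]

    def test_strict_equals_lenient_without_long_lcrs(self, rng):
        seq = random_seq(np.random.default_rng(1), 1000)
        coll = single_genome(seq, name="chr1")
        res = run_panmask(coll, P31)
        assert res.strict == res.lenient

    def test_lcr_length_boundary(self):
        # an 18 bp dinucleotide run survives in strict, a 19 bp run does not
        pad_l, pad_r = "TGACGTCCATGCAATTGT", "GATCGTTACGCAGTCATG"
        rng = np.random.default_rng(5)
        base_l = random_seq(rng, 300) + pad_l
        base_r = pad_r + random_seq(rng, 300)
        for extra, excised in ((0, False), (1, True)):
            seq = base_l + "AC" * 9 + "A" * extra + base_r
            coll = single_genome(seq, name="chr1")
            res = run_panmask(coll, P31)
            run_mid = len(base_l) + 9
            assert res.lenient.contains("chr1", run_mid)
            assert res.strict.contains("chr1", run_mid) != excised
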