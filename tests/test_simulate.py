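"""Simulator: determinism, truth labels, threshold flips, pipeline agreement."""

import numpy as np
import pytest

from panmask import (
    GenomeCollection,
    Interval,
    MaskParams,
    PlantedFeature,
    SimConfig,
    classify_kmer,
    derive_lenient,
    expected_regions,
    run_panmask,
    simulate_pangenome,
)
from panmask.simulate import parse_config

from conftest import scaled_params_k31


P31 = scaled_params_k31()


def small_cfg(seed=3, planted=(), n_samples=4, ref_len=6000, snp_rate=0.0):
    return SimConfig(
        seed=seed, ref_len=ref_len, n_samples=n_samples, snp_rate=snp_rate,
        planted=list(planted), params=P31,
    )


class TestConstruction:
    def test_no_features_no_noise_gives_identical_assemblies(self):
        coll, truth = simulate_pangenome(small_cfg())
        ref = coll.reference[0].seq
        assert all(a[0].seq == ref for a in coll.assemblies)
        assert truth.entries == []
        exp = expected_regions(small_cfg(), truth)
        assert exp.lenient.pairs("chr1") == [(0, 6000)]

    def test_seed_determinism(self):
        planted = [PlantedFeature("ref_duplication", Interval("chr1", 2000, 2100))]
        a, ta = simulate_pangenome(small_cfg(planted=planted))
        b, tb = simulate_pangenome(small_cfg(planted=planted))
        assert [r[0].seq for r in a.assemblies] == [r[0].seq for r in b.assemblies]
        assert ta == tb
        c, _ = simulate_pangenome(small_cfg(seed=4, planted=planted))
        assert c.reference[0].seq != a.reference[0].seq

    def test_ref_duplication_truth_class(self):
        planted = [PlantedFeature("ref_duplication", Interval("chr1", 2000, 2100), divergence=1)]
        coll, truth = simulate_pangenome(small_cfg(planted=planted))
        entry = truth.entries[0]
        assert entry.verdict_class == "masked_by_cond1"
        assert len(entry.guarded) == 1
        # k-mers wholly inside either copy are classified as expected
        v = classify_kmer(coll, "chr1", 2030, P31)
        assert v.status == "fail_ref_multi"
        gs = entry.guarded[0]
        v2 = classify_kmer(coll, "chr1", gs.start + P31.d2 + 1 + 10, P31)
        assert v2.status == "fail_ref_multi"

    def test_sample_deletion_stays_easy(self):
        planted = [PlantedFeature("sample_deletion", Interval("chr1", 2000, 2100), n_carriers=3)]
        coll, truth = simulate_pangenome(small_cfg(planted=planted))
        assert truth.entries[0].verdict_class == "easy"
        v = classify_kmer(coll, "chr1", 2030, P31)
        assert v.status == "unique"
        assert v.pan_hits_d2 < coll.n_genomes  # hits lost, never gained

    def test_infeasible_spacing_rejected(self):
        planted = [
            PlantedFeature("ref_duplication", Interval("chr1", 2000, 2100)),
            PlantedFeature("lcr_run", Interval("chr1", 2110, 2130)),
        ]
        with pytest.raises(ValueError, match="too close"):
            simulate_pangenome(small_cfg(planted=planted))

    @pytest.mark.parametrize(
        "feature,match",
        [
            (PlantedFeature("ref_duplication", Interval("chr1", 2000, 2020)), "too short"),
            (PlantedFeature("ref_duplication", Interval("chr1", 2000, 2100), divergence=2), "divergence"),
            (PlantedFeature("lcr_run", Interval("chr1", 2000, 2100)), "shorter than k"),
            (PlantedFeature("sample_duplication", Interval("chr1", 2000, 2100), n_carriers=9), "carriers"),
        ],
    )
    def test_feature_validation(self, feature, match):
        with pytest.raises(ValueError, match=match):
            simulate_pangenome(small_cfg(planted=[feature]))


class TestThresholdArithmetic:
    def sweep_cfg(self, m, c):
        params = MaskParams(k=31, w=10, c=c, d1=1, d2=2, hamming_d=1)
        return SimConfig(
            seed=11, ref_len=4000, n_samples=99, snp_rate=0.0,
            planted=[PlantedFeature("sample_duplication", Interval("chr1", 2000, 2100),
                                    n_carriers=m)],
            params=params,
        )

    @pytest.mark.parametrize("c,flip_at", [(1.01, 1), (1.02, 2)])
    def test_locus_flips_at_exact_carrier_count(self, c, flip_at):
        """At N = 100 the planted locus goes from easy to masked exactly when
        N + carriers first reaches c * N."""
        for m in range(0, flip_at + 2):
            cfg = self.sweep_cfg(m, c)
            coll, truth = simulate_pangenome(cfg)
            v = classify_kmer(coll, "chr1", 2030, cfg.params)
            expect_masked = m >= flip_at
            assert (v.status == "fail_pan_excess") == expect_masked, (c, m)
            assert v.pan_hits_d2 == 100 + m
            assert truth.entries[0].verdict_class == (
                "masked_by_cond2" if expect_masked else "easy"
            )


class TestExpectedVsPipeline:
    def test_base_for_base_agreement_small(self):
        planted = [
            PlantedFeature("ref_duplication", Interval("chr1", 1000, 1100), divergence=1),
            PlantedFeature("sample_duplication", Interval("chr1", 3000, 3100), n_carriers=2),
            PlantedFeature("lcr_run", Interval("chr1", 4500, 4525)),
        ]
        cfg = small_cfg(planted=planted, n_samples=9, ref_len=8000)
        coll, truth = simulate_pangenome(cfg)
        exp = expected_regions(cfg, truth)
        res = run_panmask(coll, cfg.params)
        assert res.lenient == exp.lenient
        assert res.strict == exp.strict
        # the LCR run is excised from strict only
        assert res.lenient.contains("chr1", 4510)
        assert not res.strict.contains("chr1", 4510)

    def test_agreement_within_margin_under_snp_noise(self):
        planted = [PlantedFeature("ref_duplication", Interval("chr1", 1000, 1100))]
        cfg = small_cfg(planted=planted, n_samples=5, ref_len=8000, snp_rate=0.001)
        coll, truth = simulate_pangenome(cfg)
        exp = expected_regions(cfg, truth)
        res = run_panmask(coll, cfg.params)
        # noise may only remove easy bases (a mutated sample hit drops out,
        # which cannot mask); lenient stays within the expected envelope
        assert res.lenient.subtract(exp.lenient).is_empty()
        missing = exp.lenient.subtract(res.lenient)
        assert missing.total_length <= 2 * (cfg.params.k - 1)


class TestConfigParsing:
    CFG = """
# toy fixture
seed = 5
ref_len = 6000
n_samples = 3
k = 31
w = 10
c = 1.01
d1 = 1
d2 = 2
hamming_d = 1
feature = ref_duplication:2000-2100:div=1
feature = sample_duplication:4000-4100:carriers=2
"""

    def test_round_trip(self, tmp_path):
        p = tmp_path / "toy.cfg"
        p.write_text(self.CFG)
        cfg = parse_config(str(p))
        assert cfg.seed == 5 and cfg.n_samples == 3
        assert cfg.params.k == 31 and cfg.params.d2 == 2
        assert [f.kind for f in cfg.planted] == ["ref_duplication", "sample_duplication"]
        assert cfg.planted[0].divergence == 1
        assert cfg.planted[1].n_carriers == 2
        coll, _ = simulate_pangenome(cfg)
        assert coll.n_genomes == 4

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("ref_len = 6000\nn_samples = 1\nbogus = 3\n")
        with pytest.raises(ValueError, match="bogus"):
            parse_config(str(p))
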