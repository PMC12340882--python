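"""Shared fixtures: random sequences, toy pangenome configs, bitmap oracle."""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pytest

from panmask import (
    GenomeCollection,
    Interval,
    MaskParams,
    PlantedFeature,
    RegionSet,
    SequenceRecord,
    SimConfig,
)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def single_genome(seq: str, name: str = "s") -> GenomeCollection:
    return GenomeCollection([[SequenceRecord(name, seq)]])


def region_bitmap(r: RegionSet, lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Per-base membership arrays — the oracle representation for set algebra."""
    bm = {name: np.zeros(L, dtype=bool) for name, L in lengths.items()}
    for iv in r.intervals():
        bm[iv.seq_name][iv.start : iv.end] = True
    return bm


def bitmap_to_regions(bm: Dict[str, np.ndarray]) -> List[Interval]:
    """Brute-force conversion of membership arrays back to merged intervals."""
    out: List[Interval] = []
    for name in sorted(bm):
        arr = bm[name]
        start = None
        for p, v in enumerate(arr):
            if v and start is None:
                start = p
            elif not v and start is not None:
                out.append(Interval(name, start, p))
                start = None
        if start is not None:
            out.append(Interval(name, start, len(arr)))
    return out


def scaled_params_k31() -> MaskParams:
    """k=31 with proportionally scaled edit radii for fast toy pangenomes."""
    return MaskParams(k=31, w=10, c=1.01, d1=1, d2=2, hamming_d=1)


def toy_planted() -> List[PlantedFeature]:
    """One feature of every kind, spaced for decidable truth at k up to 151."""
    I = Interval
    return [
        PlantedFeature("ref_duplication", I("chr1", 3000, 3400), divergence=1),
        PlantedFeature("tandem_repeat", I("chr1", 8000, 8400)),
        PlantedFeature("lcr_run", I("chr1", 12000, 12030)),
        PlantedFeature("sample_duplication", I("chr1", 16000, 16400), n_carriers=2),
        PlantedFeature("sample_duplication", I("chr1", 20000, 20400), n_carriers=0),
        PlantedFeature("sample_deletion", I("chr1", 24000, 24400), n_carriers=3),
    ]


def toy_config(params: MaskParams, seed: int = 7, n_samples: int = 19) -> SimConfig:
    return SimConfig(
        seed=seed,
        ref_len=50_000,
        n_samples=n_samples,
        snp_rate=0.0,
        planted=toy_planted(),
        params=params,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test sees the same deterministic stream
    return np.random.default_rng(20_240_815)
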