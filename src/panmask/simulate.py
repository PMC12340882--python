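"""Synthetic pangenome generator with planted features and decidable truth.

Stands in for a panel of real haploid assemblies so that every pipeline stage
is testable without downloads: a seeded random reference plus N-1 sample
assemblies (mutated copies of the reference), with planted features whose
expected masking outcome is derivable from the construction alone:

``ref_duplication``
    A second, optionally diverged copy of the locus placed elsewhere in the
    reference.  K-mers inside either copy fail reference uniqueness
    (condition 1).
``sample_duplication``
    An extra copy of the locus inserted into ``n_carriers`` sample
    assemblies.  The locus stays unique in the reference; its pangenome hit
    count rises from N to N + carriers and trips condition 2 exactly when
    ``N + carriers >= c * N``.
``tandem_repeat``
    A tandem motif array; k-mers inside see shifted self-copies and fail
    condition 1.
``lcr_run``
    A short low-complexity run (shorter than k, so uniqueness is unharmed);
    excised from the strict tier only.
``sample_deletion``
    The locus is deleted in carriers.  Losing hits can never push a count
    over the threshold, so the locus stays easy — the method's documented
    blind spot (a k-mer deleted in some genomes but duplicated in others
    goes unnoticed).

Decidable boundaries
--------------------
A k-mer that only partially overlaps a plain planted copy would be masked
only stochastically: the alignment of its overhang against the other copy's
random flank may or may not fit the edit budget.  Planted copies are
therefore flanked with N spacers of width d2 + 1.  N matches nothing and a
k-mer crossing a spacer is masked as ambiguous anyway, so the edit distance
of a k-mer with overhang t to the guarded copy is exactly t: hits exist for
t <= d2 and never beyond.  Every masking boundary then falls on a known
coordinate and the expected region sets can be computed base-for-base.

SNP noise never falls within 2k of a planted feature, so divergences stay
exactly as configured.  All randomness flows from one seed; identical
configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Set, Tuple

import numpy as np

from .core import MaskParams, covered_footprint, sample_positions
from .formats import GenomeCollection, SequenceRecord
from .intervals import Interval, RegionSet
from . import sdust as _sdust

__all__ = [
    "PlantedFeature",
    "SimConfig",
    "FeatureTruth",
    "SimTruth",
    "ExpectedRegions",
    "simulate_pangenome",
    "expected_regions",
    "parse_config",
    "write_truth",
]

_IDX2BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

FEATURE_KINDS = (
    "ref_duplication",
    "sample_duplication",
    "tandem_repeat",
    "lcr_run",
    "sample_deletion",
)

# low-complexity motifs with pairwise distinct reverse complements, so runs
# planted from different pool entries cannot cross-hit on the minus strand
_LCR_MOTIFS = ("A", "AC", "AG", "AAC", "AAG", "ACC")


@dataclass(frozen=True)
class PlantedFeature:
    """One planted feature on the reference."""

    kind: str
    locus: Interval
    divergence: int = 0
    n_carriers: int = 0
    motif: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.divergence < 0 or self.n_carriers < 0:
            raise ValueError("divergence and n_carriers must be >= 0")


@dataclass
class SimConfig:
    """Simulation settings; ``params`` sizes guards and validates spacing."""

    seed: int
    ref_len: int
    n_samples: int
    snp_rate: float = 0.0
    planted: List[PlantedFeature] = field(default_factory=list)
    params: MaskParams = field(default_factory=MaskParams)
    seq_name: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 <= self.snp_rate < 0.02:
            raise ValueError("snp_rate must be in [0, 0.02)")
        if self.ref_len < 10 * self.params.k:
            raise ValueError("ref_len must be >= 10 * k")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


@dataclass(frozen=True)
class FeatureTruth:
    """Construction-derived expectation for one feature.

    ``source`` is the planted locus; ``guarded`` lists N-guarded copy extents
    (mirror or tandem array, spacers included) installed on the reference.
    """

    feature: PlantedFeature
    verdict_class: str  # masked_by_cond1 | masked_by_cond2 | masked_by_lcr | easy
    source: Interval
    guarded: Tuple[Interval, ...] = ()


@dataclass
class SimTruth:
    seq_name: str
    ref_len: int
    entries: List[FeatureTruth]


class ExpectedRegions(NamedTuple):
    lenient: RegionSet
    strict: RegionSet


def _validate_features(cfg: SimConfig) -> None:
    p = cfg.params
    k, d1, d2 = p.k, p.d1, p.d2
    margin = 2 * k
    g = d2 + 1
    zones: List[Tuple[int, int]] = []
    lcr_motifs: List[Optional[str]] = []
    for f in cfg.planted:
        s, e = f.locus.start, f.locus.end
        L = e - s
        if f.locus.seq_name != cfg.seq_name:
            raise ValueError(f"feature locus on unknown sequence {f.locus.seq_name!r}")
        if s < margin + g or e > cfg.ref_len - margin - g:
            raise ValueError(f"feature at [{s},{e}) too close to a sequence end")
        if f.kind in ("ref_duplication", "sample_duplication"):
            need = 2 * k + f.divergence if f.divergence else k
            if L < need:
                raise ValueError(
                    f"{f.kind} locus of {L} bp too short (need >= {need} for k={k}, "
                    f"divergence={f.divergence})"
                )
            dmax = d1 if f.kind == "ref_duplication" else d2
            if f.divergence > dmax:
                raise ValueError(f"{f.kind} divergence must be <= {dmax}")
        if f.kind == "tandem_repeat" and f.motif is not None:
            if L < k + len(f.motif):
                raise ValueError("tandem array must be >= k + motif length")
        if f.kind == "lcr_run" and L >= k:
            raise ValueError("lcr_run must be shorter than k to leave uniqueness intact")
        if f.kind == "lcr_run":
            lcr_motifs.append(f.motif)
        if f.kind in ("sample_duplication", "sample_deletion"):
            if f.n_carriers > cfg.n_samples:
                raise ValueError("n_carriers exceeds the number of sample assemblies")
        zones.append((s - margin, e + margin))
    explicit = [m for m in lcr_motifs if m is not None]
    if len(explicit) != len(set(explicit)) or len(lcr_motifs) - len(explicit) > len(
        _LCR_MOTIFS
    ):
        raise ValueError(
            "lcr_run motifs must be distinct (identical runs would cross-hit)"
        )
    zones.sort()
    for (s1, e1), (s2, e2) in zip(zones, zones[1:]):
        if s2 < e1:
            raise ValueError(
                "planted loci too close: guarded extents must be >= 2k apart"
            )


def _pick_slot(
    rng: np.random.Generator,
    length: int,
    ref_len: int,
    margin: int,
    zones: List[Tuple[int, int]],
) -> int:
    """Uniform placement of a ``length``-bp block clear of existing zones."""
    for _ in range(10_000):
        pos = int(rng.integers(margin, ref_len - margin - length + 1))
        if all(pos + length + margin <= zs or pos - margin >= ze for zs, ze in zones):
            return pos
    raise ValueError("infeasible placement: no free slot for a planted copy")


def _divergent_copy(
    rng: np.random.Generator, src: np.ndarray, divergence: int, k: int
) -> np.ndarray:
    """Copy with ``divergence`` substitutions placed >= k from either end,
    so k-mers overlapping a copy edge never span a divergent base."""
    out = src.copy()
    if divergence:
        lo, hi = k, len(src) - k  # exclusive hi
        pos = rng.choice(np.arange(lo, hi), size=divergence, replace=False)
        for q in np.sort(pos):
            out[q] = (out[q] + int(rng.integers(1, 4))) % 4
    return out


def _random_tandem_motif(rng: np.random.Generator, length: int = 10) -> str:
    """A motif with no smaller period and distinct from its reverse complement."""
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    while True:
        idx = rng.integers(0, 4, size=length)
        motif = "".join("ACGT"[int(i)] for i in idx)
        if any(motif[: length - q] == motif[q:] for q in range(1, length)):
            continue
        rc = "".join("ACGT"["TGCA".index(c)] for c in reversed(motif))
        if motif != rc:
            return motif


def simulate_pangenome(cfg: SimConfig) -> Tuple[GenomeCollection, SimTruth]:
    """Build the genome collection and its construction-derived truth."""
    _validate_features(cfg)
    p = cfg.params
    k, d2 = p.k, p.d2
    g = d2 + 1
    margin = 2 * k
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_samples + 1

    ref = rng.integers(0, 4, size=cfg.ref_len).astype(np.int8)  # 0..3, 4 = N
    zones: List[Tuple[int, int]] = [
        (f.locus.start - margin, f.locus.end + margin) for f in cfg.planted
    ]
    entries: List[FeatureTruth] = []
    # per-feature sample payloads, applied after SNP noise
    insertions: List[Tuple[PlantedFeature, np.ndarray]] = []
    deletions: List[PlantedFeature] = []
    lcr_cycle = 0

    for f in cfg.planted:
        s, e = f.locus.start, f.locus.end
        if f.kind == "ref_duplication":
            copy = _divergent_copy(rng, ref[s:e], f.divergence, k)
            block = np.concatenate(
                [np.full(g, 4, np.int8), copy, np.full(g, 4, np.int8)]
            )
            pos = _pick_slot(rng, len(block), cfg.ref_len, margin, zones)
            ref[pos : pos + len(block)] = block
            zones.append((pos - margin, pos + len(block) + margin))
            entries.append(
                FeatureTruth(
                    f, "masked_by_cond1", f.locus,
                    (Interval(cfg.seq_name, pos, pos + len(block)),),
                )
            )
        elif f.kind == "tandem_repeat":
            motif = f.motif or _random_tandem_motif(rng)
            midx = np.array(["ACGT".index(c) for c in motif], dtype=np.int8)
            reps = int(np.ceil((e - s) / len(motif)))
            ref[s:e] = np.tile(midx, reps)[: e - s]
            ref[s - g : s] = 4
            ref[e : e + g] = 4
            entries.append(
                FeatureTruth(
                    f, "masked_by_cond1", f.locus,
                    (Interval(cfg.seq_name, s - g, e + g),),
                )
            )
        elif f.kind == "lcr_run":
            motif = f.motif or _LCR_MOTIFS[lcr_cycle % len(_LCR_MOTIFS)]
            lcr_cycle += 1
            midx = np.array(["ACGT".index(c) for c in motif], dtype=np.int8)
            reps = int(np.ceil((e - s) / len(motif)))
            run = np.tile(midx, reps)[: e - s]
            ref[s:e] = run
            # Pin short flank patterns so the run's masking outcome is exactly
            # as configured.  A run of length k-1 leaves a single flank base
            # in each covering k-mer; if the flank continues the run's
            # periodicity, a shift-by-delta window sits within hamming_d
            # mismatches and the mappability stage masks the run.  A rotation
            # of ACGT starting off the run's edge base has all bases in any
            # <=4 window pairwise distinct, which forces >= hamming_d + 1
            # mismatches at every nonzero shift.
            pin = p.hamming_d + 2
            for j in range(pin):
                ref[e + j] = (run[-1] + 1 + j) % 4
                ref[s - 1 - j] = (run[0] + 1 + j) % 4
            entries.append(FeatureTruth(f, "masked_by_lcr", f.locus))
        elif f.kind == "sample_duplication":
            copy = _divergent_copy(rng, ref[s:e], f.divergence, k)
            block = np.concatenate(
                [np.full(g, 4, np.int8), copy, np.full(g, 4, np.int8)]
            )
            insertions.append((f, block))
            masked = N + f.n_carriers >= p.c * N
            entries.append(
                FeatureTruth(f, "masked_by_cond2" if masked else "easy", f.locus)
            )
        elif f.kind == "sample_deletion":
            deletions.append(f)
            entries.append(FeatureTruth(f, "easy", f.locus))

    # carriers per sample feature (drawn after reference construction so the
    # reference bytes do not depend on carrier counts)
    carriers: Dict[int, Set[int]] = {}
    for fi, f in enumerate(cfg.planted):
        if f.kind in ("sample_duplication", "sample_deletion") and f.n_carriers:
            chosen = rng.choice(cfg.n_samples, size=f.n_carriers, replace=False)
            carriers[fi] = set(int(x) for x in chosen)

    eligible = np.ones(cfg.ref_len, dtype=bool)
    for zs, ze in zones:
        eligible[max(zs, 0) : min(ze, cfg.ref_len)] = False

    def to_str(arr: np.ndarray) -> str:
        return _IDX2BASE[arr.astype(np.intp)].tobytes().decode("ascii")

    assemblies: List[List[SequenceRecord]] = [
        [SequenceRecord(cfg.seq_name, to_str(ref))]
    ]
    for j in range(cfg.n_samples):
        arr = ref.copy()
        if cfg.snp_rate > 0:
            hit = np.nonzero((rng.random(cfg.ref_len) < cfg.snp_rate) & eligible)[0]
            for q in hit:
                if arr[q] < 4:
                    arr[q] = (arr[q] + int(rng.integers(1, 4))) % 4
        edits: List[Tuple[int, str, object]] = []
        ip_zones = list(zones)
        for fi, f in enumerate(cfg.planted):
            if fi not in carriers or j not in carriers[fi]:
                continue
            if f.kind == "sample_deletion":
                edits.append((f.locus.start, "del", f.locus.end))
            else:
                block = next(b for ff, b in insertions if ff is f)
                ip = _pick_slot(rng, 0, cfg.ref_len, margin, ip_zones)
                ip_zones.append((ip - margin, ip + margin))
                edits.append((ip, "ins", block))
        parts: List[np.ndarray] = []
        prev = 0
        for pos, kind, payload in sorted(edits):
            if kind == "del":
                parts.append(arr[prev:pos])
                prev = int(payload)
            else:
                parts.append(arr[prev:pos])
                parts.append(payload)  # type: ignore[arg-type]
                prev = pos
        parts.append(arr[prev:])
        sample = np.concatenate(parts) if len(parts) > 1 else arr
        assemblies.append([SequenceRecord(cfg.seq_name, to_str(sample))])

    truth = SimTruth(cfg.seq_name, cfg.ref_len, entries)
    return GenomeCollection(assemblies), truth


def expected_regions(
    cfg: SimConfig, truth: SimTruth, params: Optional[MaskParams] = None
) -> ExpectedRegions:
    """Expected lenient/strict region sets implied by the construction.

    A sampled k-mer is expected masked when it lies within d2 of full
    containment in a duplicated locus, or overlaps a guarded copy extent at
    all (overlap means either an N spacer in the window or full containment
    in the copy).  The masked footprint is the union of those k-mers'
    ``[i, i+k)`` spans, which erodes easy sequence by up to k-1 bp beyond
    each planted locus.  Low-complexity excision for the strict tier is
    predicted with the same DUST scan the pipeline uses, so coincidental
    low-complexity stretches of the random background are accounted for.
    """
    params = params or cfg.params
    if params.c >= 2:
        raise ValueError("expected_regions assumes c < 2 (every genome carries "
                         "both copies of a reference duplication)")
    coll, _ = simulate_pangenome(cfg)
    k, d2 = params.k, params.d2
    N = coll.n_genomes
    name = truth.seq_name
    L = truth.ref_len
    grid = np.array(sample_positions(L, k, params.w), dtype=np.int64)

    ranges: List[Tuple[int, int]] = []
    for entry in truth.entries:
        s, e = entry.source.start, entry.source.end
        if entry.feature.kind in ("ref_duplication", "sample_duplication"):
            masked = entry.feature.kind == "ref_duplication" or (
                N + entry.feature.n_carriers >= params.c * N
            )
            if masked:
                ranges.append((s - d2, e - k + d2))
        for giv in entry.guarded:
            ranges.append((giv.start - k + 1, giv.end - 1))

    masked_ivals: List[Interval] = []
    for lo, hi in ranges:
        sel = grid[(grid >= max(lo, 0)) & (grid <= min(hi, L - k))]
        for i in sel:
            masked_ivals.append(Interval(name, int(i), int(i) + k))
    masked = RegionSet(masked_ivals, sequence_lengths={name: L})

    covered = covered_footprint(coll, params)
    lenient = covered.subtract(masked).filter_min_length(params.min_region_len)
    lcrs = _sdust.lcr_regions_assembly(
        coll.reference, params.sdust_window, params.sdust_threshold,
        min_len=params.lcr_max_len,
    )
    strict = lenient.subtract(lcrs).filter_min_length(params.min_region_len)
    return ExpectedRegions(lenient, strict)


# -- config file and truth table I/O ---------------------------------------


def parse_config(path: str) -> SimConfig:
    """Plain key=value simulation config.

    Recognised keys: ``seed``, ``ref_len``, ``n_samples``, ``snp_rate``,
    ``seq_name``, any :class:`MaskParams` field (``k``, ``w``, ``c``, ``d1``,
    ``d2``, ``hamming_d``, ``min_region_len``, ``lcr_max_len``,
    ``sdust_window``, ``sdust_threshold``), and one line per feature::

        feature = kind:start-end[:div=INT][:carriers=INT][:motif=SEQ]
    """
    ints = {"seed", "ref_len", "n_samples", "k", "w", "d1", "d2", "hamming_d",
            "min_region_len", "lcr_max_len", "sdust_window"}
    floats = {"snp_rate", "c", "sdust_threshold"}
    values: Dict[str, object] = {}
    features: List[Tuple[str, int, int, Dict[str, str]]] = []
    seq_name = "chr1"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, val = (t.strip() for t in line.split("=", 1))
            if key == "feature":
                parts = val.split(":")
                kind = parts[0]
                span = parts[1].split("-")
                opts = dict(t.split("=", 1) for t in parts[2:])
                features.append((kind, int(span[0]), int(span[1]), opts))
            elif key == "seq_name":
                seq_name = val
            elif key in ints:
                values[key] = int(val)
            elif key in floats:
                values[key] = float(val)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    pkeys = {k: v for k, v in values.items()
             if k in MaskParams.__dataclass_fields__}
    params = MaskParams(**pkeys)  # type: ignore[arg-type]
    planted = [
        PlantedFeature(
            kind,
            Interval(seq_name, s, e),
            divergence=int(opts.get("div", 0)),
            n_carriers=int(opts.get("carriers", 0)),
            motif=opts.get("motif"),
        )
        for kind, s, e, opts in features
    ]
    return SimConfig(
        seed=int(values.get("seed", 0)),
        ref_len=int(values["ref_len"]),
        n_samples=int(values["n_samples"]),
        snp_rate=float(values.get("snp_rate", 0.0)),
        planted=planted,
        params=params,
        seq_name=seq_name,
    )


def write_truth(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tseq\tstart\tend\tclass\tcarriers\tdivergence\tguarded\n")
        for t in truth.entries:
            guarded = ",".join(f"{g.start}-{g.end}" for g in t.guarded) or "."
            fh.write(
                f"{t.feature.kind}\t{t.source.seq_name}\t{t.source.start}\t"
                f"{t.source.end}\t{t.verdict_class}\t{t.feature.n_carriers}\t"
                f"{t.feature.divergence}\t{guarded}\n"
            )
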