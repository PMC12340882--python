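"""Sufficient-uniqueness classification and easy-region derivation.

Given a pangenome of N assemblies (index 0 = reference), a reference k-mer is
*sufficiently unique* when

1. it has exactly one hit of edit distance <= d1 in the reference genome, and
2. it has fewer than c * N hits of edit distance <= d2 across all N genomes,
   with d2 > d1 and c > 1 (tolerance for copy-number gains).

Condition 1 guards against mismapping under sequencing errors or mutations;
condition 2 catches k-mers unique in the reference but carrying extra
paralogous copies in non-reference samples, whose reads would pile up on the
single reference locus and produce false variants.  (A k-mer deleted in some
genomes but duplicated in others slips through both conditions — a known
blind spot, documented but not solved.)

One k-mer is sampled every w bases (plus the final position so sequence tails
are testable).  Every sampled k-mer that fails — including the exhaustive
Hamming mappability rescue and k-mers containing N — masks its footprint
[i, i+k).  The remaining covered bases, with fragments shorter than 50 bp
dropped, form the *lenient* regions; subtracting low-complexity regions
longer than 18 bp yields the *strict* regions, a subset of lenient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .formats import GenomeCollection, SequenceRecord
from .hitsearch import (
    PangenomeIndex,
    collapse_hits,
    find_hits_exact,
    find_hits_seeded,
)
from .intervals import Interval, RegionSet
from .mappability import hamming_hit_count, _AssemblyView
from . import sdust as _sdust

__all__ = [
    "MaskParams",
    "KmerVerdict",
    "PanmaskResult",
    "sample_positions",
    "classify_kmer",
    "mask_reference",
    "derive_lenient",
    "derive_strict",
    "run_panmask",
]

logger = logging.getLogger("panmask")


@dataclass(frozen=True)
class MaskParams:
    """Tunable parameters of the masking pipeline (published defaults).

    k=151 matches the dominant short-read length; w=10 samples one k-mer per
    ten bases; c=1.01 tolerates a 1% excess of pangenome copies; d1/d2 are
    the reference and pangenome edit radii; hamming_d is the gapless rescue
    radius; regions shorter than min_region_len are dropped to reduce
    fragmentation; low-complexity regions longer than lcr_max_len are
    excluded from the strict tier, detected with a DUST window/threshold of
    64 bp / 2.0.
    """

    k: int = 151
    w: int = 10
    c: float = 1.01
    d1: int = 3
    d2: int = 7
    hamming_d: int = 3
    min_region_len: int = 50
    lcr_max_len: int = 18
    sdust_window: int = _sdust.DEFAULT_WINDOW
    sdust_threshold: float = _sdust.DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 <= self.d1:
            raise ValueError(f"need d2 > d1 >= 0 (got d1={self.d1}, d2={self.d2})")
        if self.c <= 1:
            raise ValueError(f"need c > 1 (got c={self.c})")
        if self.w < 1:
            raise ValueError("need w >= 1")
        if self.k <= self.d2:
            raise ValueError(f"need k > d2 (got k={self.k}, d2={self.d2})")
        if self.hamming_d < 0 or self.hamming_d >= self.k:
            raise ValueError("need 0 <= hamming_d < k")
        for name in ("k", "min_region_len", "lcr_max_len", "sdust_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class KmerVerdict:
    """Audit record for one sampled k-mer."""

    seq_name: str
    position: int
    ref_hits_d1: int
    pan_hits_d2: int
    mappability_multi: bool
    status: str  # unique | fail_ref_multi | fail_pan_excess | fail_mappability | fail_ambiguous_base


_ENGINES = {"exact": find_hits_exact, "seeded": find_hits_seeded}


def sample_positions(seq_len: int, k: int, w: int) -> List[int]:
    """Sampled k-mer offsets: the w-grid plus the final placement.

    ``0, w, 2w, ...`` up to ``seq_len - k``, with ``seq_len - k`` appended when
    it is off-grid so terminal bases stay testable.  A sequence shorter than k
    has no testable k-mer and yields an empty list.
    """
    if seq_len < k:
        return []
    last = seq_len - k
    positions = list(range(0, last + 1, w))
    if positions[-1] != last:
        positions.append(last)
    return positions


def _find_hits(engine: str, *args, **kwargs):
    try:
        fn = _ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown engine {engine!r}") from None
    return fn(*args, **kwargs)


def classify_kmer(
    coll: GenomeCollection,
    seq_name: str,
    position: int,
    params: MaskParams,
    engine: str = "seeded",
    index: Optional[PangenomeIndex] = None,
    strand_mode: str = "both",
) -> KmerVerdict:
    """Apply the two sufficiency conditions to one sampled reference k-mer.

    The pangenome count of condition 2 includes the reference (it is one of
    the N genomes) and sums collapsed hits over all assemblies and strands;
    the threshold comparison ``count < c * N`` is evaluated in real
    arithmetic with no rounding.  The mappability rescue is applied
    separately by :func:`mask_reference`.
    """
    rec = coll.reference_record(seq_name)
    kmer = rec.seq[position : position + params.k]
    if len(kmer) < params.k:
        raise ValueError(f"position {position} leaves no full k-mer on {seq_name!r}")
    if "N" in kmer:
        return KmerVerdict(seq_name, position, 0, 0, False, "fail_ambiguous_base")
    kw = dict(strand_mode=strand_mode)
    if engine == "seeded":
        kw["index"] = index
    ref_hits = collapse_hits(
        _find_hits(engine, kmer, coll, params.d1, assemblies=[0], **kw), params.d1
    )
    pan_hits = collapse_hits(
        _find_hits(engine, kmer, coll, params.d2, **kw), params.d2
    )
    n_ref, n_pan = len(ref_hits), len(pan_hits)
    if n_ref != 1:
        status = "fail_ref_multi"
    elif n_pan >= params.c * coll.n_genomes:
        status = "fail_pan_excess"
    else:
        status = "unique"
    return KmerVerdict(seq_name, position, n_ref, n_pan, False, status)


def mask_reference(
    coll: GenomeCollection,
    params: MaskParams,
    engine: str = "seeded",
    strand_mode: str = "both",
    hamming_strand_mode: str = "forward",
) -> Tuple[RegionSet, List[KmerVerdict]]:
    """Classify every sampled reference k-mer and mask the failures.

    Returns the merged union of ``[i, i+k)`` over every sampled k-mer whose
    status is not ``unique`` (the exhaustive Hamming rescue is applied to
    every sampled k-mer as an additional filter), plus the verdict audit
    trail.
    """
    index = PangenomeIndex(coll) if engine == "seeded" else None
    ham_index = PangenomeIndex(_AssemblyView(coll.reference))  # type: ignore[arg-type]
    ham_encoded: Dict[int, object] = {}
    lengths = coll.reference_lengths()
    masked: List[Interval] = []
    verdicts: List[KmerVerdict] = []
    for rec in coll.reference:
        positions = sample_positions(len(rec.seq), params.k, params.w)
        for i in positions:
            v = classify_kmer(
                coll, rec.name, i, params, engine=engine, index=index,
                strand_mode=strand_mode,
            )
            if v.status != "fail_ambiguous_base":
                kmer = rec.seq[i : i + params.k]
                multi = (
                    hamming_hit_count(
                        kmer, coll.reference, params.hamming_d,
                        strand_mode=hamming_strand_mode,
                        index=ham_index, encoded=ham_encoded,  # type: ignore[arg-type]
                    )
                    >= 2
                )
                if multi:
                    status = "fail_mappability" if v.status == "unique" else v.status
                    v = KmerVerdict(
                        v.seq_name, v.position, v.ref_hits_d1, v.pan_hits_d2,
                        True, status,
                    )
            if v.status != "unique":
                masked.append(Interval(rec.name, i, i + params.k))
            verdicts.append(v)
        logger.info(
            "masking %s: %d sampled k-mers, %d failed",
            rec.name, len(positions),
            sum(1 for v in verdicts if v.seq_name == rec.name and v.status != "unique"),
        )
    return RegionSet(masked, sequence_lengths=lengths), verdicts


def covered_footprint(coll: GenomeCollection, params: MaskParams) -> RegionSet:
    """Union of sampled k-mer footprints — the testable part of the reference.

    Bases never spanned by a sampled k-mer (tails of sequences shorter than
    k, or gaps when w > k) are outside any easy region by construction."""
    ivals = [
        Interval(rec.name, i, i + params.k)
        for rec in coll.reference
        for i in sample_positions(len(rec.seq), params.k, params.w)
    ]
    return RegionSet(ivals, sequence_lengths=coll.reference_lengths())


@dataclass
class PanmaskResult:
    """Everything one masking run produces."""

    lenient: RegionSet
    strict: RegionSet
    masked: RegionSet
    covered: RegionSet
    verdicts: List[KmerVerdict] = field(default_factory=list)


def derive_lenient(
    coll: GenomeCollection,
    params: MaskParams,
    engine: str = "seeded",
    _masked: Optional[RegionSet] = None,
) -> RegionSet:
    """Easy regions after uniqueness, mappability and the 50 bp filter."""
    masked = _masked
    if masked is None:
        masked, _ = mask_reference(coll, params, engine=engine)
    covered = covered_footprint(coll, params)
    return covered.subtract(masked).filter_min_length(params.min_region_len)


def derive_strict(
    lenient: RegionSet,
    reference: Sequence[SequenceRecord],
    params: MaskParams,
) -> RegionSet:
    """Lenient minus low-complexity regions longer than ``lcr_max_len``.

    The length cutoff applies to merged (chained) LCR regions; the minimum
    region length filter is re-applied after the subtraction, so the result
    is a per-base subset of the lenient input.
    """
    lcrs = _sdust.lcr_regions_assembly(
        reference, params.sdust_window, params.sdust_threshold,
        min_len=params.lcr_max_len,
    )
    return lenient.subtract(lcrs).filter_min_length(params.min_region_len)


def run_panmask(
    coll: GenomeCollection,
    params: MaskParams,
    engine: str = "seeded",
) -> PanmaskResult:
    """Full pipeline: mask, lenient tier, strict tier, audit trail."""
    masked, verdicts = mask_reference(coll, params, engine=engine)
    covered = covered_footprint(coll, params)
    lenient = covered.subtract(masked).filter_min_length(params.min_region_len)
    strict = derive_strict(lenient, coll.reference, params)
    logger.info(
        "easy regions: lenient %d bp in %d intervals, strict %d bp in %d intervals",
        lenient.total_length, lenient.num_intervals(),
        strict.total_length, strict.num_intervals(),
    )
    return PanmaskResult(lenient, strict, masked, covered, verdicts)


def write_verdicts(verdicts: Sequence[KmerVerdict], path: str) -> None:
    """Verdict audit trail as TSV (sequence, position, counts, flags, status)."""
    with open(path, "w") as fh:
        fh.write("seq_name\tposition\tref_hits_d1\tpan_hits_d2\tmappability_multi\tstatus\n")
        for v in verdicts:
            fh.write(
                f"{v.seq_name}\t{v.position}\t{v.ref_hits_d1}\t{v.pan_hits_d2}\t"
                f"{int(v.mappability_multi)}\t{v.status}\n"
            )
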