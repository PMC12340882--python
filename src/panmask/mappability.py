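"""Exact Hamming-distance multi-mapping rescue on the reference.

A gapless, exhaustive check that a sampled k-mer occurs only once among all
length-k reference windows within a small substitution budget (default 3).
In the published pipeline this stage patches heuristic misses of the main
aligner; the edit-distance engines here are already complete, but the stage
is kept as an independent filter for fidelity, and it is strictly subsumed by
the uniqueness condition whenever its radius does not exceed d1 (a Hamming
hit is an edit hit).

Counting is forward-strand by default; windows containing N can never match
a query (N mismatches every base).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from .formats import SequenceRecord
from .intervals import Interval, RegionSet
from .hitsearch import PangenomeIndex, _pieces, encode, revcomp

__all__ = ["hamming_hit_count", "multi_mapping_mask"]


class _AssemblyView:
    """Minimal collection-like wrapper so PangenomeIndex can serve one assembly."""

    def __init__(self, records: Sequence[SequenceRecord]) -> None:
        self.assemblies = [list(records)]
        self.n_genomes = 1


def hamming_hit_count(
    query: str,
    assembly: Sequence[SequenceRecord],
    max_mm: int,
    strand_mode: str = "forward",
    index: Optional[PangenomeIndex] = None,
    encoded: Optional[Dict[int, np.ndarray]] = None,
) -> int:
    """Number of length-k windows within Hamming distance ``max_mm`` of the query.

    Exhaustive: the query is split into ``max_mm + 1`` pieces; a window with
    at most ``max_mm`` substitutions contains one piece exactly and, unlike
    gapped matching, at its unshifted offset.  Candidate windows are then
    verified with a vectorised mismatch count.
    """
    k = len(query)
    if max_mm < 0 or max_mm >= k:
        raise ValueError(f"need 0 <= max_mm < k (got {max_mm}, k={k})")
    if not set(query) <= set("ACGT"):
        raise ValueError("query must be over {A,C,G,T}")
    if index is None:
        index = PangenomeIndex(_AssemblyView(assembly))  # type: ignore[arg-type]
    if encoded is None:
        encoded = {}
    queries = [query] if strand_mode == "forward" else [query, revcomp(query)]
    total = 0
    for q in queries:
        qenc = encode(q)
        starts: Dict[int, Set[int]] = {}
        for off, piece in _pieces(q, max_mm):
            for _ai, ri, p in index.lookup(piece):
                s = p - off
                if 0 <= s <= len(assembly[ri].seq) - k:
                    starts.setdefault(ri, set()).add(s)
        for ri, ss in starts.items():
            tenc = encoded.get(ri)
            if tenc is None:
                tenc = encoded[ri] = encode(assembly[ri].seq)
            for s in ss:
                if int(np.count_nonzero(tenc[s : s + k] != qenc)) <= max_mm:
                    total += 1
    return total


def multi_mapping_mask(
    assembly: Sequence[SequenceRecord],
    sampled_positions: Dict[str, Sequence[int]],
    k: int,
    max_mm: int,
    strand_mode: str = "forward",
) -> RegionSet:
    """Union of ``[i, i+k)`` over sampled k-mers with two or more Hamming hits.

    ``sampled_positions`` maps sequence name to sampled offsets; k-mers
    containing N are skipped here (they are masked as ambiguous upstream).
    """
    index = PangenomeIndex(_AssemblyView(assembly))  # type: ignore[arg-type]
    encoded: Dict[int, np.ndarray] = {}
    lengths = {r.name: len(r.seq) for r in assembly}
    masked: List[Interval] = []
    for rec in assembly:
        for i in sampled_positions.get(rec.name, []):
            kmer = rec.seq[i : i + k]
            if "N" in kmer:
                continue
            n_hits = hamming_hit_count(
                kmer, assembly, max_mm, strand_mode, index=index, encoded=encoded
            )
            if n_hits >= 2:
                masked.append(Interval(rec.name, i, i + k))
    return RegionSet(masked, sequence_lengths=lengths)
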