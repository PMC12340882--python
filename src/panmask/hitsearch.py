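"""All-hits approximate k-mer matching within a bounded edit distance.

Sufficient-uniqueness classification needs, for a reference k-mer, *every*
end-to-end placement in every assembly with unit-cost Levenshtein distance at
most ``max_d``.  Two engines share this contract:

``find_hits_exact``
    An oracle: a vectorised Sellers dynamic program computes, for every start
    position ``s`` of every sequence, ``d_start[s] = min_e edit(query,
    text[s:e])`` — the best end-to-end alignment cost of the query against any
    substring starting at ``s``.  Complete by construction, used for
    verification and small inputs.

``find_hits_seeded``
    The production engine.  The query is split into ``max_d + 1``
    non-overlapping pieces; by the pigeonhole principle any placement with at
    most ``max_d`` edits contains at least one piece exactly, shifted by at
    most ``max_d`` from its query offset.  Exact piece occurrences are looked
    up in a hash index, candidate starts are screened with edlib's infix
    (SHW) aligner, and surviving hits get their distance and end recomputed
    with the same small DP the exact engine uses, so both engines report
    byte-identical hits.

A "hit" is keyed by its start position; neighbouring starts within ``max_d``
are alignment jitter of the same locus (an alignment with ``d`` edits can
shift its start by at most ``d``) and are merged by :func:`collapse_hits`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import edlib
import numpy as np

from .formats import GenomeCollection, SequenceRecord

__all__ = [
    "Hit",
    "PangenomeIndex",
    "find_hits_exact",
    "find_hits_seeded",
    "collapse_hits",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A=0 C=1 G=2 T=3, N=4).

    N never equals a query base, so it behaves as a guaranteed mismatch."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True, order=True)
class Hit:
    """One end-to-end placement of a query k-mer.

    ``start``/``end`` delimit the aligned interval on the forward strand of
    the named sequence; for a reverse-strand hit the reverse complement of
    the query was aligned to the forward text.
    """

    assembly_index: int
    seq_name: str
    strand: str
    start: int
    end: int
    edit_distance: int


def _check_query(query: str, max_d: int) -> None:
    if not query:
        raise ValueError("empty query")
    if max_d < 0 or max_d >= len(query):
        raise ValueError(f"need 0 <= max_d < k (got max_d={max_d}, k={len(query)})")
    if not set(query) <= set("ACGT"):
        raise ValueError("query must be over {A,C,G,T}; pre-filter k-mers containing N")


def per_start_distances(query: str, text: str) -> np.ndarray:
    """``d_start[s] = min_e edit(query, text[s:e])`` for every start s.

    Computed as a Sellers ends-free DP over the reversed strings: a free end
    in the reversed text is a free alignment end to the right of ``s`` in the
    forward text.  Runs in O(k * n) with vectorised rows; the horizontal
    (insertion-in-text) dependency is resolved with the prefix-min trick
    ``D[j] = min_{l<=j} (t[l] + j - l)``.
    """
    n = len(text)
    m = len(query)
    q = encode(query)[::-1]
    t = encode(text)[::-1]
    idx = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i in range(m):
        mism = (t != q[i]).astype(np.int32)
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i + 1
        np.minimum(prev[:-1] + mism, prev[1:] + 1, out=cur[1:])
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    # reversed end j corresponds to forward start n - j
    return prev[::-1][:n].copy()


def best_end(query: str, text: str, start: int, max_d: int) -> Tuple[int, int]:
    """Best (distance, end) for an end-to-end alignment anchored at ``start``.

    Full DP of the query against ``text[start : start + k + max_d]`` with a
    free end in the text.  Ties on distance break toward the shortest
    alignment (smallest end) so both engines agree byte-for-byte.
    Returns ``(distance, end)``; distance may exceed ``max_d``.
    """
    window = text[start : start + len(query) + max_d]
    w = encode(window)
    q = encode(query)
    n = len(w)
    idx = np.arange(n + 1, dtype=np.int32)
    prev = idx.copy()  # global in the query, so deletions at row 0 cost
    for i in range(len(q)):
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i + 1
        np.minimum(prev[:-1] + (w != q[i]).astype(np.int32), prev[1:] + 1, out=cur[1:])
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    e_off = int(np.argmin(prev))
    return int(prev[e_off]), start + e_off


def _iter_targets(
    coll: GenomeCollection, assemblies: Optional[Iterable[int]]
) -> List[Tuple[int, SequenceRecord]]:
    picked = range(coll.n_genomes) if assemblies is None else sorted(set(assemblies))
    out = []
    for ai in picked:
        for rec in coll.assemblies[ai]:
            out.append((ai, rec))
    return out


def _strands(query: str, strand_mode: str) -> List[Tuple[str, str]]:
    if strand_mode == "forward":
        return [("+", query)]
    if strand_mode == "both":
        return [("+", query), ("-", revcomp(query))]
    raise ValueError(f"unknown strand_mode {strand_mode!r}")


def find_hits_exact(
    query: str,
    coll: GenomeCollection,
    max_d: int,
    strand_mode: str = "both",
    assemblies: Optional[Iterable[int]] = None,
) -> List[Hit]:
    """Complete raw hit list via the full dynamic program (oracle engine)."""
    _check_query(query, max_d)
    hits: List[Hit] = []
    for ai, rec in _iter_targets(coll, assemblies):
        if len(rec.seq) < len(query) - max_d:
            continue
        for strand, q in _strands(query, strand_mode):
            d = per_start_distances(q, rec.seq)
            for s in np.nonzero(d <= max_d)[0]:
                dist, end = best_end(q, rec.seq, int(s), max_d)
                hits.append(Hit(ai, rec.name, strand, int(s), end, dist))
    hits.sort()
    return hits


# -- seeded engine ---------------------------------------------------------


def _pieces(query: str, max_d: int) -> List[Tuple[int, str]]:
    """Split the query into max_d+1 non-overlapping pieces covering it."""
    k = len(query)
    nseed = max_d + 1
    bounds = [round(j * k / nseed) for j in range(nseed + 1)]
    return [(bounds[j], query[bounds[j] : bounds[j + 1]]) for j in range(nseed)]


class PangenomeIndex:
    """Exact-match position index over a genome collection.

    One hash table per piece length, built lazily and kept for the lifetime
    of the index, so a masking run over thousands of sampled k-mers pays the
    scan once.  Entries are ``piece -> [(assembly_index, record_index,
    position), ...]``.
    """

    def __init__(self, coll: GenomeCollection) -> None:
        self.coll = coll
        self._tables: Dict[int, Dict[str, List[Tuple[int, int, int]]]] = {}
        self._records: List[Tuple[int, int, SequenceRecord]] = []
        for ai, recs in enumerate(coll.assemblies):
            for ri, rec in enumerate(recs):
                self._records.append((ai, ri, rec))

    def table(self, L: int) -> Dict[str, List[Tuple[int, int, int]]]:
        tab = self._tables.get(L)
        if tab is None:
            tab = {}
            for ai, ri, rec in self._records:
                s = rec.seq
                for p in range(len(s) - L + 1):
                    piece = s[p : p + L]
                    if "N" in piece:
                        continue
                    tab.setdefault(piece, []).append((ai, ri, p))
            self._tables[L] = tab
        return tab

    def lookup(self, piece: str) -> List[Tuple[int, int, int]]:
        return self.table(len(piece)).get(piece, [])


def find_hits_seeded(
    query: str,
    coll: GenomeCollection,
    max_d: int,
    strand_mode: str = "both",
    assemblies: Optional[Iterable[int]] = None,
    index: Optional[PangenomeIndex] = None,
) -> List[Hit]:
    """Same hit set as :func:`find_hits_exact`, via pigeonhole seeding."""
    _check_query(query, max_d)
    if index is None:
        index = PangenomeIndex(coll)
    allowed = None if assemblies is None else set(assemblies)
    k = len(query)
    hits: List[Hit] = []
    for strand, q in _strands(query, strand_mode):
        cand: Dict[Tuple[int, int], Set[int]] = {}
        for off, piece in _pieces(q, max_d):
            for ai, ri, p in index.lookup(piece):
                if allowed is not None and ai not in allowed:
                    continue
                base = p - off
                cand.setdefault((ai, ri), set()).update(
                    range(base - max_d, base + max_d + 1)
                )
        for (ai, ri), starts in sorted(cand.items()):
            rec = coll.assemblies[ai][ri]
            n = len(rec.seq)
            for s in sorted(starts):
                if s < 0 or s > n - (k - max_d):
                    continue
                window = rec.seq[s : s + k + max_d]
                res = edlib.align(q, window, mode="SHW", task="locations", k=max_d)
                dist = res["editDistance"]
                if dist == -1:
                    continue
                # inclusive end of the shortest optimal alignment
                end = s + min(e for _, e in res["locations"]) + 1
                hits.append(Hit(ai, rec.name, strand, s, end, dist))
    hits.sort()
    return hits


def collapse_hits(hits: Sequence[Hit], max_d: int) -> List[Hit]:
    """Deduplicate alignment jitter: chain hits on the same (assembly,
    sequence, strand) whose successive starts differ by at most ``max_d``
    into one hit, keeping the minimum edit distance (leftmost on ties)."""
    groups: Dict[Tuple[int, str, str], List[Hit]] = {}
    for h in hits:
        groups.setdefault((h.assembly_index, h.seq_name, h.strand), []).append(h)
    out: List[Hit] = []
    for key in sorted(groups):
        chain: List[Hit] = []
        for h in sorted(groups[key], key=lambda h: (h.start, h.edit_distance)):
            if chain and h.start - chain[-1].start <= max_d:
                chain.append(h)
            else:
                if chain:
                    out.append(min(chain, key=lambda h: (h.edit_distance, h.start)))
                chain = [h]
        if chain:
            out.append(min(chain, key=lambda h: (h.edit_distance, h.start)))
    out.sort()
    return out
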