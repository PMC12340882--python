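"""Genomic interval algebra on 0-based half-open coordinates.

Every region operation in the package (masking, easy-region derivation,
coverage statistics) is built on two types: :class:`Interval`, a single
``[start, end)`` span on a named sequence, and :class:`RegionSet`, a merged,
sorted, per-sequence collection of such spans.  Coordinates follow the BED
convention throughout; conversion to 1-based happens only at I/O edges.

Abutting intervals merge: a region set is a per-base mask, so ``[0,10)`` plus
``[10,20)`` is indistinguishable from ``[0,20)``.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

__all__ = [
    "Interval",
    "RegionSet",
    "merge",
    "complement",
    "subtract",
    "intersect",
    "filter_min_length",
]


class Interval(Tuple[str, int, int]):
    """A 0-based half-open genomic interval ``(seq_name, start, end)``."""

    __slots__ = ()

    def __new__(cls, seq_name: str, start: int, end: int) -> "Interval":
        if not isinstance(start, (int,)) or not isinstance(end, (int,)):
            raise ValueError(f"non-integer coordinates in ({seq_name}, {start}, {end})")
        if start < 0 or start >= end:
            raise ValueError(
                f"invalid interval ({seq_name}, {start}, {end}): need 0 <= start < end"
            )
        return tuple.__new__(cls, (seq_name, int(start), int(end)))

    @property
    def seq_name(self) -> str:
        return self[0]

    @property
    def start(self) -> int:
        return self[1]

    @property
    def end(self) -> int:
        return self[2]

    @property
    def length(self) -> int:
        return self[2] - self[1]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Interval({self[0]!r}, {self[1]}, {self[2]})"


def _merge_pairs(pairs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge (start, end) pairs into canonical form; abutting pairs fuse."""
    out: List[Tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


class RegionSet:
    """A merged set of non-overlapping intervals, grouped per sequence.

    Parameters
    ----------
    intervals:
        Any iterable of :class:`Interval` (or raw ``(name, start, end)``
        triples).  Overlapping and abutting inputs are merged.
    sequence_lengths:
        Optional map ``seq_name -> length``; required for :meth:`complement`
        and whole-genome statistics.  When given, intervals are checked
        against the declared lengths.
    """

    def __init__(
        self,
        intervals: Iterable[Tuple[str, int, int]] = (),
        sequence_lengths: Optional[Dict[str, int]] = None,
    ) -> None:
        per_seq: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            iv = iv if isinstance(iv, Interval) else Interval(*iv)
            per_seq.setdefault(iv.seq_name, []).append((iv.start, iv.end))
        self._ivals: Dict[str, List[Tuple[int, int]]] = {
            name: _merge_pairs(pairs) for name, pairs in sorted(per_seq.items())
        }
        self.sequence_lengths: Optional[Dict[str, int]] = (
            dict(sequence_lengths) if sequence_lengths is not None else None
        )
        if self.sequence_lengths is not None:
            for name, pairs in self._ivals.items():
                if name not in self.sequence_lengths:
                    raise ValueError(f"no declared length for sequence {name!r}")
                L = self.sequence_lengths[name]
                if pairs and pairs[-1][1] > L:
                    raise ValueError(
                        f"interval ({name}, {pairs[-1][0]}, {pairs[-1][1]}) exceeds "
                        f"sequence length {L}"
                    )

    # -- basic accessors ---------------------------------------------------

    def intervals(self) -> Iterator[Interval]:
        """Iterate intervals sorted by (seq_name, start)."""
        for name in self._ivals:
            for s, e in self._ivals[name]:
                yield Interval(name, s, e)

    def pairs(self, seq_name: str) -> List[Tuple[int, int]]:
        return list(self._ivals.get(seq_name, []))

    @property
    def seq_names(self) -> List[str]:
        return list(self._ivals)

    @property
    def total_length(self) -> int:
        """Total number of bases covered."""
        return sum(e - s for pairs in self._ivals.values() for s, e in pairs)

    def num_intervals(self) -> int:
        return sum(len(p) for p in self._ivals.values())

    def is_empty(self) -> bool:
        return not any(self._ivals.values())

    def contains(self, seq_name: str, pos: int) -> bool:
        """Per-base membership test."""
        pairs = self._ivals.get(seq_name)
        if not pairs:
            return False
        i = bisect_right(pairs, (pos, float("inf"))) - 1
        return i >= 0 and pairs[i][0] <= pos < pairs[i][1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = {n: p for n, p in self._ivals.items() if p}
        b = {n: p for n, p in other._ivals.items() if p}
        return a == b

    def __hash__(self) -> int:  # region sets are mutated nowhere
        return hash(tuple((n, tuple(p)) for n, p in self._ivals.items() if p))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"RegionSet({self.num_intervals()} intervals, {self.total_length} bp)"

    # -- algebra -----------------------------------------------------------

    def _lengths_or_fail(self) -> Dict[str, int]:
        if self.sequence_lengths is None:
            raise ValueError("sequence_lengths required for this operation")
        return self.sequence_lengths

    def complement(self) -> "RegionSet":
        """Per-base complement within ``[0, length)`` of every declared sequence."""
        lengths = self._lengths_or_fail()
        out: List[Interval] = []
        for name, L in sorted(lengths.items()):
            prev = 0
            for s, e in self._ivals.get(name, []):
                if s > prev:
                    out.append(Interval(name, prev, s))
                prev = e
            if prev < L:
                out.append(Interval(name, prev, L))
        return RegionSet(out, sequence_lengths=lengths)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Bases present in both sets; sequences unknown to *other* drop out."""
        out: List[Interval] = []
        for name, a in self._ivals.items():
            b = other._ivals.get(name)
            if not b:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    out.append(Interval(name, s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out, sequence_lengths=self.sequence_lengths)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Bases in this set and not in *other*; unknown sequences in *other*
        are ignored."""
        out: List[Interval] = []
        for name, a in self._ivals.items():
            b = other._ivals.get(name, [])
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j][1] <= cur:
                    j += 1
                jj = j
                while jj < len(b) and b[jj][0] < e:
                    bs, be = b[jj]
                    if bs > cur:
                        out.append(Interval(name, cur, bs))
                    cur = max(cur, be)
                    jj += 1
                if cur < e:
                    out.append(Interval(name, cur, e))
        return RegionSet(out, sequence_lengths=self.sequence_lengths)

    def filter_min_length(self, min_len: int) -> "RegionSet":
        """Keep intervals of length >= *min_len* ("shorter than" is dropped)."""
        if min_len < 1:
            raise ValueError("min_len must be >= 1")
        return RegionSet(
            (iv for iv in self.intervals() if iv.length >= min_len),
            sequence_lengths=self.sequence_lengths,
        )


# -- functional surface ----------------------------------------------------


def merge(
    intervals: Iterable[Tuple[str, int, int]],
    sequence_lengths: Optional[Dict[str, int]] = None,
) -> RegionSet:
    """Union of intervals in canonical merged form."""
    return RegionSet(intervals, sequence_lengths=sequence_lengths)


def complement(r: RegionSet) -> RegionSet:
    return r.complement()


def subtract(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.subtract(b)


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.intersect(b)


def filter_min_length(r: RegionSet, min_len: int) -> RegionSet:
    return r.filter_min_length(min_len)
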