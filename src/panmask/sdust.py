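"""Symmetric DUST low-complexity detection.

SNP and indel calling errors concentrate in low-complexity regions
(homopolymers, short tandem repeats), so the strict output tier excises them.
The score of a window is its excess of repeated overlapping triplets:

    score = sum_t c_t * (c_t - 1) / 2  /  (n - 1)

where ``c_t`` counts each of the 64 triplet types among the ``n = len - 2``
overlapping triplets.  A window of all-distinct triplets scores 0; a
homopolymer of length L scores (L - 2) / 2.  The classical defaults are a
64 bp window and a threshold of 2.0 (the original integer threshold 20, in
tenths).

A *perfect interval* is a window-bounded interval whose score exceeds the
threshold, no proper subinterval of which scores strictly higher, and which
is not properly contained in another reported interval.  Overlapping and
abutting perfect intervals chain into merged low-complexity regions, which
may exceed the window length.  The construction is symmetric: the regions of
a sequence and of its reverse complement mirror each other.

Triplets containing N are undefined: N splits a sequence into independently
scanned runs.
"""

from __future__ import annotations

from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .formats import SequenceRecord
from .intervals import Interval, RegionSet

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_THRESHOLD",
    "LcrInterval",
    "dust_score",
    "perfect_intervals",
    "lcr_regions",
    "lcr_regions_assembly",
]

DEFAULT_WINDOW = 64
DEFAULT_THRESHOLD = 2.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class LcrInterval(NamedTuple):
    """A perfect low-complexity interval with its DUST score."""

    start: int
    end: int
    score: float


def dust_score(window: str) -> float:
    """DUST score of one window; windows containing N score 0."""
    if len(window) < 3:
        raise ValueError("dust_score needs a window of length >= 3")
    if "N" in window:
        return 0.0
    counts = [0] * 64
    pairs = 0
    code = _CODE
    t = code[window[0]] * 4 + code[window[1]]
    for ch in window[2:]:
        t = (t * 4 + code[ch]) & 63
        pairs += counts[t]
        counts[t] += 1
    n = len(window) - 2
    return pairs / (n - 1) if n > 1 else 0.0


def _scan_run(seq: str, window: int, threshold: float) -> List[LcrInterval]:
    """Perfect intervals of one N-free run (coordinates local to the run)."""
    L = len(seq)
    if L < 3:
        return []
    max_len = min(window, L)
    n_lens = max_len - 2  # lengths 3 .. max_len
    codes = np.array([_CODE[c] for c in seq], dtype=np.int64)
    trip = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]  # triplet code per offset

    # scores[s, li] = score of interval starting at s with length li + 3
    scores = np.full((L, n_lens), -1.0)
    counts = np.zeros(64, dtype=np.int64)
    for s in range(L - 2):
        counts[:] = 0
        pairs = 0
        top = min(max_len, L - s)
        for length in range(3, top + 1):
            t = trip[s + length - 3]
            pairs += counts[t]
            counts[t] += 1
            n = length - 2
            scores[s, length - 3] = pairs / (n - 1) if n > 1 else 0.0

    # best[s, li] = max score over all subintervals (incl. itself) of (s, s+li+3)
    best = scores.copy()
    for li in range(1, n_lens):
        np.maximum(best[:, li], best[:, li - 1], out=best[:, li])
        np.maximum(best[: L - 1, li], best[1:, li - 1], out=best[: L - 1, li])

    out: List[Tuple[int, int, float]] = []
    for s in range(L - 2):
        for li in range(n_lens):
            sc = scores[s, li]
            if sc <= threshold:
                continue
            # proper subintervals are subintervals of (s+1, e) or (s, e-1)
            sub = -1.0
            if li > 0:
                sub = max(best[s, li - 1], best[s + 1, li - 1])
            if sc >= sub:
                out.append((s, s + li + 3, sc))

    # drop intervals properly contained in another reported interval
    out.sort(key=lambda t: (t[0], -t[1]))
    kept: List[LcrInterval] = []
    max_end = -1
    for s, e, sc in out:
        if e <= max_end:
            continue
        kept.append(LcrInterval(s, e, sc))
        max_end = e
    kept.sort(key=lambda t: (t.start, t.end))
    return kept


def perfect_intervals(
    seq: str, window: int = DEFAULT_WINDOW, threshold: float = DEFAULT_THRESHOLD
) -> List[LcrInterval]:
    """All perfect intervals of a sequence, ordered by start.

    N bases split the sequence; each N-free run is scanned independently and
    run-local coordinates are shifted back to the full sequence.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    seq = seq.upper()
    out: List[LcrInterval] = []
    pos = 0
    for run in seq.split("N"):
        if len(run) >= 3:
            out.extend(
                LcrInterval(iv.start + pos, iv.end + pos, iv.score)
                for iv in _scan_run(run, window, threshold)
            )
        pos += len(run) + 1
    return out


def lcr_regions(
    record: SequenceRecord,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
) -> RegionSet:
    """Merged union of perfect intervals of one sequence record."""
    ivs = perfect_intervals(record.seq, window, threshold)
    return RegionSet(
        (Interval(record.name, iv.start, iv.end) for iv in ivs),
        sequence_lengths={record.name: len(record.seq)},
    )


def lcr_regions_assembly(
    records: Sequence[SequenceRecord],
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: Optional[int] = None,
) -> RegionSet:
    """Merged LCR regions over an assembly, optionally length-filtered.

    With ``min_len`` only merged regions *longer than* ``min_len`` are kept
    (strict inequality, matching the 18 bp exclusion rule of the strict tier).
    """
    ivals: List[Interval] = []
    lengths: Dict[str, int] = {}
    for rec in records:
        lengths[rec.name] = len(rec.seq)
        ivals.extend(
            Interval(rec.name, iv.start, iv.end)
            for iv in perfect_intervals(rec.seq, window, threshold)
        )
    merged = RegionSet(ivals, sequence_lengths=lengths)
    if min_len is None:
        return merged
    return RegionSet(
        (iv for iv in merged.intervals() if iv.length > min_len),
        sequence_lengths=lengths,
    )
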