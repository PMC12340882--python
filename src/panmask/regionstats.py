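"""Evaluation statistics on region sets and variant-site lists.

Coverage and subset fractions are per-base; variant membership uses the
0-based start position of the site (the common convention when intersecting
VCF records with BED intervals).  Site concordance is exact matching of
normalized ``(seq, pos, ref, alt)`` tuples restricted to a region set — a
simplified, haplotype-unaware surrogate for benchmark comparators, so
equivalent complex-region representations count as errors.
"""

from __future__ import annotations

from collections import Counter
from typing import List, Optional, Sequence, Tuple

from .formats import VariantSite
from .intervals import RegionSet

__all__ = [
    "coverage_fraction",
    "subset_fraction",
    "variant_density",
    "site_concordance",
]


def coverage_fraction(r: RegionSet, target: Optional[RegionSet] = None) -> float:
    """Fraction of the target (default: whole genome) covered by ``r``."""
    if target is None:
        if r.sequence_lengths is None:
            raise ValueError("whole-genome coverage needs sequence_lengths on r")
        denom = sum(r.sequence_lengths.values())
        num = r.total_length
    else:
        denom = target.total_length
        num = r.intersect(target).total_length
    if denom == 0:
        raise ValueError("coverage target has zero length")
    return num / denom


def subset_fraction(a: RegionSet, b: RegionSet) -> float:
    """Fraction of ``a``'s bases included in ``b`` (asymmetric)."""
    denom = a.total_length
    if denom == 0:
        raise ValueError("subset_fraction needs a non-empty first set")
    return a.intersect(b).total_length / denom


def _sites_in(sites: Sequence[VariantSite], r: RegionSet) -> List[VariantSite]:
    return [s for s in sites if r.contains(s.seq_name, s.pos)]


def variant_density(
    sites: Sequence[VariantSite],
    r: RegionSet,
    confident: Optional[RegionSet] = None,
) -> Tuple[float, Optional[float]]:
    """Sites per base of ``r``; optionally relative to a confident set.

    The relative density is ``density(r) / density(confident)`` computed on
    the same site list.
    """
    if r.total_length == 0:
        raise ValueError("variant_density needs a non-empty region set")
    density = len(_sites_in(sites, r)) / r.total_length
    relative: Optional[float] = None
    if confident is not None:
        if confident.total_length == 0:
            raise ValueError("confident set is empty")
        conf_density = len(_sites_in(sites, confident)) / confident.total_length
        if conf_density == 0:
            raise ValueError("confident-set density is zero")
        relative = density / conf_density
    return density, relative


def site_concordance(
    truth: Sequence[VariantSite],
    calls: Sequence[VariantSite],
    r: RegionSet,
) -> Tuple[float, float]:
    """(FDR, FNR) of calls against truth, restricted to a region set.

    Both lists are filtered to sites whose position lies in ``r``; a call
    matches a truth site on exact ``(seq, pos, ref, alt)`` identity
    (genotypes ignored).  Either rate is 0 when its denominator is 0.
    """
    t_in = Counter(_sites_in(truth, r))
    c_in = Counter(_sites_in(calls, r))
    matched = sum((t_in & c_in).values())
    n_calls = sum(c_in.values())
    n_truth = sum(t_in.values())
    fdr = (n_calls - matched) / n_calls if n_calls else 0.0
    fnr = (n_truth - matched) / n_truth if n_truth else 0.0
    return fdr, fnr
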