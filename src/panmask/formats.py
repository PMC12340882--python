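"""Readers and writers for FASTA, BED3 and a minimal VCF-site dialect.

Sequences are uppercased on read and any character outside {A,C,G,T,N} is
mapped to N.  BED is 3+ column, tab-delimited, 0-based half-open.  VCF reading
extracts one normalized site per ALT allele of each PASS record; genotypes,
INFO and FORMAT are ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence

from Bio import SeqIO

from .intervals import Interval, RegionSet

__all__ = [
    "SequenceRecord",
    "GenomeCollection",
    "VariantSite",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_vcf_sites",
    "normalize_site",
]

_ALLOWED = set("ACGTN")


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _ALLOWED:
        return seq
    return "".join(c if c in _ALLOWED else "N" for c in seq)


class SequenceRecord(NamedTuple):
    """A named nucleotide sequence over {A,C,G,T,N}."""

    name: str
    seq: str


@dataclass
class GenomeCollection:
    """An ordered pangenome: assembly 0 is the reference, the rest are samples.

    Sequence names must be unique within each assembly but may repeat across
    assemblies (samples are conventionally named like the reference).
    """

    assemblies: List[List[SequenceRecord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assemblies:
            raise ValueError("a genome collection needs at least one assembly")
        for ai, recs in enumerate(self.assemblies):
            names = [r.name for r in recs]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate sequence names in assembly {ai}")

    @property
    def n_genomes(self) -> int:
        return len(self.assemblies)

    @property
    def reference(self) -> List[SequenceRecord]:
        return self.assemblies[0]

    def reference_lengths(self) -> Dict[str, int]:
        return {r.name: len(r.seq) for r in self.reference}

    def reference_record(self, seq_name: str) -> SequenceRecord:
        for r in self.reference:
            if r.name == seq_name:
                return r
        raise KeyError(f"no reference sequence named {seq_name!r}")


class VariantSite(NamedTuple):
    """A normalized bi-allelic site on the reference (0-based position)."""

    seq_name: str
    pos: int
    ref_allele: str
    alt_allele: str


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str) -> List[SequenceRecord]:
    """Read a (possibly wrapped, possibly lowercase) FASTA file.

    The record name is the first whitespace-delimited token of the header.
    Raises ``ValueError`` for an empty file, an empty sequence, or duplicate
    names.
    """
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        name = rec.id
        seq = _sanitize(str(rec.seq))
        if not seq:
            raise ValueError(f"record {name!r} in {path} has an empty sequence")
        if name in seen:
            raise ValueError(f"duplicate sequence name {name!r} in {path}")
        seen.add(name)
        records.append(SequenceRecord(name, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# -- BED -------------------------------------------------------------------


def write_bed(r: RegionSet, path: str) -> None:
    """Write a RegionSet as sorted, headerless BED3."""
    with open(path, "w") as fh:
        for iv in r.intervals():
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str, sequence_lengths: Optional[Dict[str, int]] = None) -> RegionSet:
    """Read a 3+ column BED file; extra columns are ignored.

    Malformed lines (fewer than 3 columns, non-integer coordinates,
    start >= end) are rejected with their line number.
    """
    ivals: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                ivals.append(Interval(cols[0], start, end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return RegionSet(ivals, sequence_lengths=sequence_lengths)


# -- VCF sites -------------------------------------------------------------


def normalize_site(
    seq_name: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Optional[Dict[str, str]] = None,
) -> VariantSite:
    """Canonicalize an allele pair: trim shared context and left-align.

    ``pos`` is 0-based.  With a reference, indels are shifted left as far as
    the sequence allows (vt-style normalization); without one the alleles are
    only trimmed.
    """
    ref, alt = ref.upper(), alt.upper()
    refseq = reference.get(seq_name) if reference else None
    while True:
        # trim identical trailing bases
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        # left-shift: both alleles end in the same base but one is length 1
        if (
            refseq is not None
            and ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
            and pos > 0
        ):
            prev = refseq[pos - 1]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantSite(seq_name, pos, ref, alt)


def read_vcf_sites(
    path: str, reference: Optional[Sequence[SequenceRecord]] = None
) -> List[VariantSite]:
    """Extract normalized sites from a VCF 4.x text file.

    One site per ALT allele.  Records with symbolic alleles, breakends or a
    FILTER other than PASS/"." are skipped.  A file without a ``#CHROM``
    header line is rejected.
    """
    import pysam

    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty VCF")
    with open(path) as fh:
        if not any(line.startswith("#CHROM") for line in fh):
            raise ValueError(f"{path}: missing #CHROM header line")
    refmap = {r.name: r.seq for r in reference} if reference else None
    sites: List[VariantSite] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or any(ch in alt for ch in "<>[].*"):
                    continue
                if not set(alt.upper()) <= set("ACGT"):
                    continue
                if not set(rec.ref.upper()) <= set("ACGT"):
                    continue
                if alt.upper() == rec.ref.upper():
                    continue
                sites.append(
                    normalize_site(rec.chrom, rec.pos - 1, rec.ref, alt, refmap)
                )
    return sites
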