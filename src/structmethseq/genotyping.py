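"""Allele-diagnostic k-mer genotyping of embryo RNA-seq read sets.

The Mettl16 knockout allele carries a triple-stop cassette whose junction
sequences are absent from the wild-type allele, so a read set can be
genotyped by exact substring search for allele-diagnostic 22-mers.  Each
allele is represented by a pair of reverse-complementary 22-mers because
the embryo libraries are non-strand-specific; consequently searching the
reads or their reverse complements yields identical counts.

A read counts toward an allele when it contains any of that allele's
k-mers; reads matching both alleles are flagged as ambiguous and
excluded.  The call requires ``min_reads`` supporting reads per allele
(default 2, guarding against index hopping; ``min_reads=1`` reproduces a
literal presence/absence rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .fixtures import emit_fixture_sequences
from .reads import revcomp

__all__ = [
    "AlleleKmers",
    "DiagnosticCounts",
    "GenotypeCall",
    "count_diagnostic_reads",
    "call_genotype",
    "genotype_reads",
]

_FIX = emit_fixture_sequences()


@dataclass(frozen=True)
class AlleleKmers:
    """Diagnostic k-mer sets for the wild-type and knockout alleles."""

    wt: frozenset[str] = frozenset(_FIX.wt_kmers)
    ko: frozenset[str] = frozenset(_FIX.ko_kmers)
    min_reads: int = 2

    def __post_init__(self) -> None:
        if self.wt & self.ko:
            raise ValueError("WT and KO k-mer sets must be disjoint")
        for name, kmers in (("wt", self.wt), ("ko", self.ko)):
            if {revcomp(k) for k in kmers} != set(kmers):
                raise ValueError(f"{name} k-mer set is not closed under reverse complement")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass(frozen=True)
class DiagnosticCounts:
    wt: int
    ko: int
    ambiguous: int = 0


@dataclass(frozen=True)
class GenotypeCall:
    call: str  # WT | HET | KO | indeterminate
    wt_read_count: int
    ko_read_count: int


def count_diagnostic_reads(
    reads: Iterable[str], kmers: AlleleKmers | None = None
) -> DiagnosticCounts:
    """Count reads containing a WT or KO diagnostic k-mer (exact match).

    A read matching k-mers of both alleles is counted as ambiguous and
    excluded from both allele counts.
    """
    kmers = kmers or AlleleKmers()
    wt = ko = ambiguous = 0
    for read in reads:
        seq = read.upper()
        hit_wt = any(k in seq for k in kmers.wt)
        hit_ko = any(k in seq for k in kmers.ko)
        if hit_wt and hit_ko:
            ambiguous += 1
        elif hit_wt:
            wt += 1
        elif hit_ko:
            ko += 1
    return DiagnosticCounts(wt=wt, ko=ko, ambiguous=ambiguous)


def call_genotype(
    counts: DiagnosticCounts | tuple[int, int], kmers: AlleleKmers | None = None
) -> GenotypeCall:
    """Call WT/HET/KO from diagnostic read counts.

    WT: wt >= min and ko < min; KO: ko >= min and wt < min;
    HET: both >= min; indeterminate otherwise.
    """
    kmers = kmers or AlleleKmers()
    if isinstance(counts, tuple):
        counts = DiagnosticCounts(*counts)
    wt_ok = counts.wt >= kmers.min_reads
    ko_ok = counts.ko >= kmers.min_reads
    if wt_ok and ko_ok:
        call = "HET"
    elif wt_ok:
        call = "WT"
    elif ko_ok:
        call = "KO"
    else:
        call = "indeterminate"
    return GenotypeCall(call=call, wt_read_count=counts.wt, ko_read_count=counts.ko)


def genotype_reads(
    reads: Iterable[str], kmers: AlleleKmers | None = None
) -> GenotypeCall:
    """Convenience: count diagnostic reads and call the genotype."""
    kmers = kmers or AlleleKmers()
    return call_genotype(count_diagnostic_reads(reads, kmers), kmers)
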