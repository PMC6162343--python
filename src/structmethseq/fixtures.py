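"""Reference sequences for the Mettl16 knockout allele and the METTL16 motif.

These are the published sequences used throughout the package: the
single-stranded DNA repair template that introduced a triple-stop cassette
into Mettl16 exon 3, the cassette itself, the allele-diagnostic 22-mers
used to genotype embryo RNA-seq libraries, and the METTL16 consensus
nonamer whose fourth adenosine is the methyl acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FixtureSequences", "emit_fixture_sequences", "NONAMER_RNA", "NONAMER_DNA"]

#: METTL16 consensus nonamer (RNA alphabet); the methyl-acceptor A is base 4.
NONAMER_RNA = "UACAGAGAA"
NONAMER_DNA = "TACAGAGAA"

#: 170-nt single-stranded repair template (negative-strand sequence) carrying
#: the reverse complement of the stop cassette between an 81-nt and a 75-nt
#: homology arm.
_REPAIR_TEMPLATE = (
    "AGTTGAGAATGCAAAACCTATGGAAGTAAGAACCACCTACCTATGTCAATTCCTCTTCGGAGAGT"
    "AGTTTTGTCCGAATCCTCATCTATTTACATTGGTGACCAATCAAATCTTCTACCCAGTGAATATA"
    "GTTAAGTCTCAAGGGGACTGTGGGAATTAGTCTCTCCAAA"
)

#: Triple-stop codon cassette inserted into Mettl16 exon 3 (sense strand).
_STOP_CASSETTE = "ATGTAAATAGATGA"

#: Allele-diagnostic 22-mers (each set is closed under reverse complement
#: because the embryo libraries are non-strand-specific).
_WT_KMERS = ("CACCAGGATTCGGACAAAACTA", "TAGTTTTGTCCGAATCCTGGTG")
_KO_KMERS = ("TCACCAATGTAAATAGATGAGG", "CCTCATCTATTTACATTGGTGA")


@dataclass(frozen=True)
class FixtureSequences:
    """Named reference sequences (all DNA alphabet except ``nonamer``)."""

    repair_template: str = _REPAIR_TEMPLATE
    stop_cassette: str = _STOP_CASSETTE
    wt_kmers: tuple[str, str] = _WT_KMERS
    ko_kmers: tuple[str, str] = _KO_KMERS
    nonamer: str = NONAMER_RNA
    #: 1-based position of the methyl-acceptor adenosine within the nonamer.
    nonamer_target_offset: int = 4


def emit_fixture_sequences() -> FixtureSequences:
    """Return the published reference sequences, verbatim."""
    return FixtureSequences()
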