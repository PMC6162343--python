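"""Motif + structural-context scanning for candidate METTL16 substrates.

METTL16 methylates the fourth adenosine of the nonamer UACAGAGAA only
when that adenosine is unpaired and flanked by double-stranded regions
(a single-nucleotide bulge or a junction between two stems).  The
scanner finds exact nonamer occurrences in a transcript, folds a local
window around each hit and evaluates that structural rule at the methyl
acceptor.  This encodes a qualitative conclusion as a binary screening
rule — it is a screening aid, not a validated predictor of methylation
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .features import PositionContext, classify_positions, helix_lengths
from .fixtures import NONAMER_RNA
from .fold import FoldParams, mfe_fold
from .reads import to_rna

__all__ = ["SubstrateCall", "scan_motif", "classify_substrate", "scan_transcripts"]

#: 1-based offset of the methyl-acceptor A within the nonamer.
TARGET_OFFSET = 4


@dataclass(frozen=True)
class SubstrateCall:
    """Structural evaluation of one motif hit."""

    seq_id: str
    motif_start: int  # 1-based in the full sequence
    motif_end: int
    target_pos: int  # 1-based position of the methyl-acceptor A
    window_start: int  # 1-based bounds of the folded window
    window_end: int
    context: PositionContext
    candidate: bool


def scan_motif(seq: str, motif: str = NONAMER_RNA) -> list[int]:
    """All exact motif occurrences, as 1-based start positions.

    DNA and RNA alphabets are equivalent (T == U); overlapping hits are
    all reported.
    """
    hay = to_rna(seq)
    needle = to_rna(motif)
    hits = []
    start = 0
    while True:
        idx = hay.find(needle, start)
        if idx < 0:
            return hits
        hits.append(idx + 1)
        start = idx + 1


def classify_substrate(
    seq: str,
    motif_start: int,
    motif: str = NONAMER_RNA,
    window_flank: int = 30,
    params: FoldParams | None = None,
    min_stem: int = 1,
    seq_id: str = "",
) -> SubstrateCall:
    """Fold a window around a motif hit and evaluate the substrate rule.

    The window spans ``window_flank`` bases on each side of the motif,
    clipped to the sequence.  The hit is a candidate substrate when the
    methyl-acceptor A is unpaired with both immediate neighbours paired
    in the window fold; with ``min_stem`` > 1 both flanking helices must
    additionally contain at least ``min_stem`` stacked pairs.
    """
    rna = to_rna(seq)
    motif = to_rna(motif)
    if rna[motif_start - 1 : motif_start - 1 + len(motif)] != motif:
        raise ValueError(f"no motif occurrence at position {motif_start}")
    w_start = max(1, motif_start - window_flank)
    w_end = min(len(rna), motif_start + len(motif) - 1 + window_flank)
    window = rna[w_start - 1 : w_end]
    if len(window) < len(motif):
        raise ValueError("window shorter than the motif")
    structure = mfe_fold(window, params)
    annotation = classify_positions(structure)
    target_pos = motif_start + TARGET_OFFSET - 1
    pos_in_window = target_pos - w_start + 1
    context = annotation.context(pos_in_window)
    candidate = context.between_two_stems
    if candidate and min_stem > 1:
        helices = helix_lengths(structure.dot_bracket)
        candidate = (
            helices.get(pos_in_window - 1, 0) >= min_stem
            and helices.get(pos_in_window + 1, 0) >= min_stem
        )
    return SubstrateCall(
        seq_id=seq_id,
        motif_start=motif_start,
        motif_end=motif_start + len(motif) - 1,
        target_pos=target_pos,
        window_start=w_start,
        window_end=w_end,
        context=context,
        candidate=candidate,
    )


def scan_transcripts(
    records: Sequence[tuple[str, str]],
    motif: str = NONAMER_RNA,
    window_flank: int = 30,
    params: FoldParams | None = None,
    min_stem: int = 1,
) -> pd.DataFrame:
    """Scan (id, sequence) records; one row per motif hit (BED-like)."""
    rows = []
    for seq_id, seq in records:
        for start in scan_motif(seq, motif):
            call = classify_substrate(
                seq,
                start,
                motif=motif,
                window_flank=window_flank,
                params=params,
                min_stem=min_stem,
                seq_id=seq_id,
            )
            rows.append(
                {
                    "seq_id": call.seq_id,
                    "motif_start": call.motif_start,
                    "motif_end": call.motif_end,
                    "target_pos": call.target_pos,
                    "candidate": call.candidate,
                    "category": call.context.category,
                    "single_nt_bulge": call.context.single_nt_bulge,
                    "between_two_stems": call.context.between_two_stems,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "motif_start",
            "motif_end",
            "target_pos",
            "candidate",
            "category",
            "single_nt_bulge",
            "between_two_stems",
        ],
    )
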