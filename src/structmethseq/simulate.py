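"""Synthetic randomized-oligo libraries and a simulated m6A-IP experiment.

The generator emulates the chemically synthesized 30-nt library
N11-UACAGAGAA-N10: eleven random 5' bases, the constant METTL16 nonamer
(methyl acceptor at oligo position 15), ten random 3' bases.  Flank
bases are drawn i.i.d. uniform over {A, C, G, T}.

The simulated immunoprecipitation captures the folding-dependent
selection that the experiment measures: each oligo is folded with the
same folder the analysis pipeline uses, and oligos whose target
adenosine is unpaired with both neighbours paired ("structured") are
captured with probability ``p_ip_structured``, all others with
``p_ip_background``.  Input replicates sample oligos uniformly with
replacement; IP replicates sample proportionally to capture probability.
Sequencing artifacts (N substitutions, length changes, motif errors) are
injected per read at configurable rates; reads are emitted
post-adapter-trimming.  All randomness flows through a single seeded
generator per operation, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .features import classify_positions
from .fixtures import NONAMER_RNA
from .fold import FoldParams, SecondaryStructure, fold_many
from .genotyping import AlleleKmers
from .reads import revcomp, to_dna, to_rna, write_fasta, write_fastq

__all__ = [
    "LibraryDesign",
    "ErrorRates",
    "SelectionModel",
    "Oligo",
    "generate_oligo_library",
    "SimulatedExperiment",
    "simulate_ip_experiment",
    "simulate_genotyping_reads",
]

_BASES = np.array(list("ACGT"))


class Oligo(NamedTuple):
    id: str
    sequence: str  # DNA alphabet


@dataclass(frozen=True)
class LibraryDesign:
    """Layout of the randomized oligo: left flank + constant motif + right
    flank, with the methyl-acceptor A at ``target_offset_in_motif`` of the
    motif (all 1-based)."""

    left_flank_len: int = 11
    motif: str = NONAMER_RNA
    right_flank_len: int = 10
    target_offset_in_motif: int = 4

    def __post_init__(self) -> None:
        if self.left_flank_len < 0 or self.right_flank_len < 0:
            raise ValueError("flank lengths must be non-negative")
        if not 1 <= self.target_offset_in_motif <= len(self.motif):
            raise ValueError("target offset outside the motif")
        if to_rna(self.motif)[self.target_offset_in_motif - 1] != "A":
            raise ValueError("motif must carry A at the target offset")

    @property
    def length(self) -> int:
        return self.left_flank_len + len(self.motif) + self.right_flank_len

    @property
    def target_pos(self) -> int:
        """1-based oligo position of the methyl-acceptor A (default 15)."""
        return self.left_flank_len + self.target_offset_in_motif

    @property
    def motif_start(self) -> int:
        """1-based start of the motif window (default 12)."""
        return self.left_flank_len + 1

    @property
    def motif_dna(self) -> str:
        return to_dna(self.motif)


@dataclass(frozen=True)
class ErrorRates:
    """Per-read probabilities of sequencing artifacts."""

    n_substitution: float = 0.005
    length_change: float = 0.005
    motif_mismatch: float = 0.005

    def __post_init__(self) -> None:
        for r in (self.n_substitution, self.length_change, self.motif_mismatch):
            if not 0 <= r <= 1:
                raise ValueError("error rates must be probabilities")


@dataclass(frozen=True)
class SelectionModel:
    """Capture probabilities and depths for the simulated IP experiment."""

    p_ip_structured: float = 0.9
    p_ip_background: float = 0.05
    input_depth: int = 100_000
    ip_depth: int = 100_000
    n_replicates: int = 2
    error_rates: ErrorRates = ErrorRates()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_ip_background <= self.p_ip_structured <= 1:
            raise ValueError("require 0 <= p_ip_background <= p_ip_structured <= 1")
        if self.input_depth <= 0 or self.ip_depth <= 0:
            raise ValueError("depths must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def generate_oligo_library(
    design: LibraryDesign | None = None, n: int = 1000, seed: int = 0
) -> list[Oligo]:
    """Draw ``n`` oligos from the design (DNA alphabet), deterministically.

    Every oligo has the designed length with the exact motif at the
    designed window and i.i.d. uniform random flanks.
    """
    design = design or LibraryDesign()
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    motif = design.motif_dna
    flanks = rng.integers(0, 4, size=(n, design.left_flank_len + design.right_flank_len))
    oligos = []
    for i in range(n):
        row = _BASES[flanks[i]]
        left = "".join(row[: design.left_flank_len])
        right = "".join(row[design.left_flank_len :])
        oligos.append(Oligo(id=f"oligo_{i:06d}", sequence=left + motif + right))
    return oligos


@dataclass
class SimulatedExperiment:
    """Read sets per library plus the per-oligo ground truth."""

    reads: dict[str, list[tuple[str, str]]]  # library -> [(read_id, seq)]
    truth: pd.DataFrame  # oligo_id, sequence, dot_bracket, structured, p_capture
    design: LibraryDesign
    model: SelectionModel

    @property
    def input_libraries(self) -> list[str]:
        return [lib for lib in self.reads if lib.startswith("input")]

    @property
    def ip_libraries(self) -> list[str]:
        return [lib for lib in self.reads if lib.startswith("ip")]

    def write(self, out_dir: str | Path, fmt: str = "fasta") -> dict[str, Path]:
        """Write one FASTA/FASTQ per library plus the ground-truth TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        writer = write_fastq if fmt == "fastq" else write_fasta
        ext = "fastq" if fmt == "fastq" else "fasta"
        paths = {}
        for lib, recs in self.reads.items():
            path = out_dir / f"{lib}.{ext}"
            writer(path, recs)
            paths[lib] = path
        truth_path = out_dir / "ground_truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["ground_truth"] = truth_path
        return paths


def _inject_errors(
    seq: str,
    rng: np.random.Generator,
    design: LibraryDesign,
    do_n: bool,
    do_len: bool,
    do_motif: bool,
) -> str:
    """Apply the flagged per-read artifacts (N, length change, motif error)."""
    if do_n:
        pos = int(rng.integers(0, len(seq)))
        seq = seq[:pos] + "N" + seq[pos + 1 :]
    if do_len:
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5 and len(seq) > 1:
            seq = seq[:pos] + seq[pos + 1 :]  # single-base deletion
        else:
            seq = seq[: pos + 1] + seq[pos] + seq[pos + 1 :]  # duplication
    if do_motif:
        start = design.motif_start - 1
        off = int(rng.integers(0, len(design.motif)))
        pos = min(start + off, len(seq) - 1)
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        seq = seq[:pos] + choices[int(rng.integers(0, 3))] + seq[pos + 1 :]
    return seq


def simulate_ip_experiment(
    oligos: Sequence[Oligo],
    folder: FoldParams | Callable[[str], SecondaryStructure] | None = None,
    model: SelectionModel | None = None,
    design: LibraryDesign | None = None,
) -> SimulatedExperiment:
    """Simulate input and IP sequencing libraries from an oligo pool.

    ``folder`` is the folding engine used to decide each oligo's
    ground-truth structure class — by default the same native folder
    (and parameters) the analysis pipeline uses, so ground truth and
    pipeline are self-consistent.

    Returns read sets named ``input_rep1..k`` / ``ip_rep1..k`` and a
    ground-truth table with one row per oligo.
    """
    model = model or SelectionModel()
    design = design or LibraryDesign()
    if not oligos:
        raise ValueError("empty oligo list")
    seqs = [o.sequence for o in oligos]
    if callable(folder):
        structures = {to_rna(s): folder(to_rna(s)) for s in set(seqs)}
    else:
        structures = fold_many(seqs, folder)
    target = design.target_pos
    dot_brackets = []
    structured = np.zeros(len(seqs), dtype=bool)
    for i, s in enumerate(seqs):
        st = structures[to_rna(s)]
        dot_brackets.append(st.dot_bracket)
        ann = classify_positions(st)
        structured[i] = ann.between_two_stems[target - 1]
    p_capture = np.where(structured, model.p_ip_structured, model.p_ip_background)

    truth = pd.DataFrame(
        {
            "oligo_id": [o.id for o in oligos],
            "sequence": seqs,
            "dot_bracket": dot_brackets,
            "structured": structured,
            "p_capture": p_capture,
        }
    )

    rng = np.random.default_rng(model.seed)
    weights = p_capture / p_capture.sum() if p_capture.sum() > 0 else None
    if weights is None:
        raise ValueError("all capture probabilities are zero")
    reads: dict[str, list[tuple[str, str]]] = {}
    n = len(seqs)
    for rep in range(1, model.n_replicates + 1):
        for lib, depth, w in (
            (f"input_rep{rep}", model.input_depth, None),
            (f"ip_rep{rep}", model.ip_depth, weights),
        ):
            idx = rng.choice(n, size=depth, replace=True, p=w)
            rates = model.error_rates
            u = rng.random((depth, 3))
            err_n = u[:, 0] < rates.n_substitution
            err_len = u[:, 1] < rates.length_change
            err_motif = u[:, 2] < rates.motif_mismatch
            any_err = err_n | err_len | err_motif
            recs = []
            for r in range(depth):
                seq = seqs[idx[r]]
                if any_err[r]:
                    seq = _inject_errors(
                        seq, rng, design, err_n[r], err_len[r], err_motif[r]
                    )
                recs.append((f"{lib}_read{r:07d}", seq))
            reads[lib] = recs
    return SimulatedExperiment(reads=reads, truth=truth, design=design, model=model)


def simulate_genotyping_reads(
    n_diagnostic: int,
    ko_fraction: float,
    n_background: int = 0,
    read_length: int = 80,
    kmers: AlleleKmers | None = None,
    seed: int = 0,
) -> list[str]:
    """Simulate a non-strand-specific embryo read set with a known allele mix.

    ``n_diagnostic`` reads each embed one allele-diagnostic 22-mer (KO
    allele with probability ``ko_fraction``, otherwise WT) at a random
    offset and random orientation; ``n_background`` reads are random
    sequence.  Used to validate genotype recovery at known 0/50/100% KO
    fractions.
    """
    if not 0 <= ko_fraction <= 1:
        raise ValueError("ko_fraction must be in [0, 1]")
    kmers = kmers or AlleleKmers()
    rng = np.random.default_rng(seed)
    wt_list = sorted(kmers.wt)
    ko_list = sorted(kmers.ko)
    reads = []
    for _ in range(n_diagnostic):
        allele = ko_list if rng.random() < ko_fraction else wt_list
        kmer = allele[int(rng.integers(0, len(allele)))]
        pad = read_length - len(kmer)
        left = int(rng.integers(0, pad + 1))
        flanks = "".join(_BASES[rng.integers(0, 4, size=pad)])
        read = flanks[:left] + kmer + flanks[left:]
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append(read)
    for _ in range(n_background):
        reads.append("".join(_BASES[rng.integers(0, 4, size=read_length)]))
    return reads
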