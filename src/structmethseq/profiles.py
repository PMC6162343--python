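"""Positional frequency profiles and floored log2 ratios.

For a class of structures (e.g. IP-enriched), the frequency of a
structural feature at position p is the (optionally read-count-weighted)
fraction of class members whose position p shows that feature.  Profiles
for two classes are compared as per-position log2 ratios after flooring
both frequencies at 0.5% (so ratios are bounded by +-log2(1/floor) and a
frequency of zero never produces an infinite ratio).

Two weightings are exposed: ``per-structure`` counts each unique
structure once (matching comparisons framed in terms of proportions of
structures), ``per-read`` weights each structure by its read count
(matching direct comparisons of sequenced oligos between libraries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import CATEGORIES, FeatureAnnotation

__all__ = [
    "FloorRule",
    "FEATURES",
    "feature_frequency_profile",
    "log2_frequency_ratio",
    "target_feature_proportions",
    "nucleotide_frequency_comparison",
]

#: Primary categories plus the derived flags, all usable as profile features.
FEATURES = CATEGORIES + ("single_nt_bulge", "between_two_stems", "unpaired")


@dataclass(frozen=True)
class FloorRule:
    """Frequencies below ``floor`` are raised to ``floor`` before ratios
    (default 0.5%)."""

    floor: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.floor < 1:
            raise ValueError("floor must be in (0, 1)")

    def apply(self, freq: np.ndarray) -> np.ndarray:
        return np.maximum(np.asarray(freq, dtype=float), self.floor)


def _feature_indicator(ann: FeatureAnnotation, feature: str) -> np.ndarray:
    if feature in CATEGORIES:
        return np.array([c == feature for c in ann.categories], dtype=float)
    if feature == "single_nt_bulge":
        return np.array(ann.single_nt_bulge, dtype=float)
    if feature == "between_two_stems":
        return np.array(ann.between_two_stems, dtype=float)
    if feature == "unpaired":
        return np.array([c != "stem" for c in ann.categories], dtype=float)
    raise ValueError(f"unknown feature {feature!r}; choose from {FEATURES}")


def feature_frequency_profile(
    annotations: Sequence[FeatureAnnotation],
    feature: str,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-position frequency of a feature over a class of structures.

    ``weights=None`` gives per-structure weighting (every structure
    counts once); passing read counts gives per-read weighting.  All
    structures must have equal length.  Frequencies of the mutually
    exclusive primary categories sum to one at every position.
    """
    if len(annotations) == 0:
        raise ValueError("empty structure class")
    lengths = {len(a) for a in annotations}
    if len(lengths) != 1:
        raise ValueError(f"structures of unequal lengths {sorted(lengths)}")
    if weights is None:
        w = np.ones(len(annotations))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(annotations):
            raise ValueError("weights length does not match annotations")
        if w.sum() <= 0:
            raise ValueError("weights must have positive sum")
    mat = np.stack([_feature_indicator(a, feature) for a in annotations])
    return (w[:, None] * mat).sum(axis=0) / w.sum()


def log2_frequency_ratio(
    prof_a: np.ndarray,
    prof_b: np.ndarray,
    rule: FloorRule | None = None,
) -> np.ndarray:
    """Per-position log2(freq_a / freq_b) with both sides floored."""
    rule = rule or FloorRule()
    a = np.asarray(prof_a, dtype=float)
    b = np.asarray(prof_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile shapes differ: {a.shape} vs {b.shape}")
    return np.log2(rule.apply(a) / rule.apply(b))


def target_feature_proportions(
    annotations: Sequence[FeatureAnnotation],
    pos: int,
    weights: Sequence[float] | None = None,
) -> dict[str, float]:
    """Proportions of structural contexts of the target position.

    Returns proportions over the exclusive primary-category partition
    (summing to one) plus, separately, the overlapping flags
    ``single_nt_bulge`` and ``between_two_stems``.
    """
    if len(annotations) == 0:
        raise ValueError("empty structure class")
    if not all(1 <= pos <= len(a) for a in annotations):
        raise IndexError(f"position {pos} outside some structure")
    if weights is None:
        w = np.ones(len(annotations))
    else:
        w = np.asarray(weights, dtype=float)
    total = w.sum()
    out: dict[str, float] = {}
    for cat in CATEGORIES:
        mask = np.array([a.categories[pos - 1] == cat for a in annotations])
        out[cat] = float((w * mask).sum() / total)
    for flag in ("single_nt_bulge", "between_two_stems"):
        mask = np.array([getattr(a, flag)[pos - 1] for a in annotations])
        out[flag] = float((w * mask).sum() / total)
    return out


def nucleotide_frequency_comparison(
    reads_ip: Sequence[str],
    reads_input: Sequence[str],
    motif_start: int = 12,
    motif_end: int = 20,
    rule: FloorRule | None = None,
) -> pd.DataFrame:
    """Per-position, per-base log2 ratio of nucleotide frequencies
    between IP and input reads.

    Reads must be filtered (equal length, DNA alphabet).  Positions
    inside the motif window are reported but flagged ``in_motif`` — the
    filter guarantees them constant, so their ratios are zero.
    """
    rule = rule or FloorRule()
    if not reads_ip or not reads_input:
        raise ValueError("empty read set")
    length = len(reads_ip[0])
    if any(len(r) != length for r in reads_ip) or any(
        len(r) != length for r in reads_input
    ):
        raise ValueError("reads of unequal length; run the filter first")

    def base_freqs(reads: Sequence[str]) -> np.ndarray:
        arr = np.frombuffer("".join(reads).encode(), dtype="S1").reshape(len(reads), length)
        freqs = np.zeros((length, 4))
        for bi, base in enumerate((b"A", b"C", b"G", b"T")):
            freqs[:, bi] = (arr == base).mean(axis=0)
        return freqs

    f_ip = base_freqs(reads_ip)
    f_in = base_freqs(reads_input)
    rows = []
    for p in range(length):
        for bi, base in enumerate("ACGT"):
            rows.append(
                {
                    "position": p + 1,
                    "base": base,
                    "freq_ip": f_ip[p, bi],
                    "freq_input": f_in[p, bi],
                    "log2_ratio": float(
                        np.log2(rule.apply(f_ip[p, bi]) / rule.apply(f_in[p, bi]))
                    ),
                    "in_motif": motif_start <= p + 1 <= motif_end,
                }
            )
    return pd.DataFrame(rows)
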