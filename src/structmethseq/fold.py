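"""Secondary-structure prediction for short RNAs.

The native folder is a Nussinov-style dynamic program maximizing a pair
score (GC=3, AU=2, GU=1 by default) plus a stacking bonus (+1 for every
pair stacked directly on another).  It predicts a single optimal
non-pseudoknotted structure with a minimum hairpin of three unpaired
bases and a deterministic traceback, which is sufficient to express the
qualitative structure classes (stems, loops, bulges) that the downstream
analysis works with.  For exact replication with a full thermodynamic
nearest-neighbour model, structures computed externally (e.g. by RNAfold)
can be ingested through :func:`read_vienna`.

Tie-breaking in the traceback is fixed: a position is left unpaired when
that is score-equivalent to pairing it, and among score-equivalent
partners the smallest (5'-most) partner is chosen, so outputs are
byte-reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .reads import to_rna

__all__ = [
    "FoldParams",
    "SecondaryStructure",
    "mfe_fold",
    "fold_many",
    "brute_force_fold",
    "score_structure",
    "read_vienna",
    "write_vienna",
    "validate_structure",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_NEG_INF = float("-inf")


@dataclass(frozen=True)
class FoldParams:
    """Scoring model for the native folder.

    ``pair_weights`` maps unordered base pairs (given as two-letter RNA
    strings) to positive scores; pairs not listed are disallowed.
    ``stack_bonus`` is added once for every pair (i, j) whose inner
    neighbour (i+1, j-1) is also paired.  ``min_hairpin`` is the minimum
    number of unpaired bases closed by any pair (steric constraint).
    """

    pair_weights: tuple[tuple[str, float], ...] = (("GC", 3.0), ("AU", 2.0), ("GU", 1.0))
    stack_bonus: float = 1.0
    min_hairpin: int = 3
    max_len: int = 200

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if any(w <= 0 for _, w in self.pair_weights):
            raise ValueError("pair weights must be positive")

    def weight_matrix(self) -> np.ndarray:
        """Symmetric 4x4 matrix of pair scores (0 = pair disallowed)."""
        mat = np.zeros((4, 4), dtype=np.float64)
        for pair, w in self.pair_weights:
            a, b = _BASE_INDEX[pair[0]], _BASE_INDEX[pair[1]]
            mat[a, b] = w
            mat[b, a] = w
        return mat


DEFAULT_PARAMS = FoldParams()


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with one predicted structure in dot-bracket notation.

    ``score`` is the native folding score, or the free energy in
    kcal/mol when the structure was read from an external folder.
    """

    sequence: str
    dot_bracket: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dot_bracket):
            raise ValueError(
                f"sequence length {len(self.sequence)} != structure "
                f"length {len(self.dot_bracket)}"
            )

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 1-based (i, j) tuples with i < j."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for pos, ch in enumerate(self.dot_bracket, 1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced dot-bracket {self.dot_bracket!r}")
                out.append((stack.pop(), pos))
            elif ch != ".":
                raise ValueError(f"invalid character {ch!r} in dot-bracket")
        if stack:
            raise ValueError(f"unbalanced dot-bracket {self.dot_bracket!r}")
        return sorted(out)


def _encode(seq: str) -> np.ndarray:
    rna = to_rna(seq)
    try:
        return np.array([_BASE_INDEX[b] for b in rna], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence {seq!r}") from None


def _fill_dp(code, wmat, min_hairpin, stack_bonus, best, best_paired):
    """Interval DP. best[i,j]: optimal score on [i..j]; best_paired[i,j]:
    optimal score on [i..j] given that (i,j) is paired (-inf if it cannot
    pair). Stacking is credited through the best_paired channel."""
    n = code.shape[0]
    neg_inf = -np.inf
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            w = wmat[code[i], code[j]]
            if w > 0.0 and j - i - 1 >= min_hairpin:
                interior = best[i + 1, j - 1]
                stacked = best_paired[i + 1, j - 1]
                if stacked > neg_inf and stacked + stack_bonus > interior:
                    interior = stacked + stack_bonus
                best_paired[i, j] = w + interior
            else:
                best_paired[i, j] = neg_inf
            # position i unpaired, or paired with some k
            b = best[i + 1, j]
            for k in range(i + min_hairpin + 1, j + 1):
                bp = best_paired[i, k]
                if bp > neg_inf:
                    rest = best[k + 1, j] if k + 1 <= j else 0.0
                    if bp + rest > b:
                        b = bp + rest
            best[i, j] = b


try:  # JIT-compile the DP fill when numba is importable
    from numba import njit

    _fill_dp = njit(_fill_dp)
except ImportError:  # pragma: no cover - numba is a declared dependency
    pass


def _traceback(code, wmat, min_hairpin, stack_bonus, best, best_paired):
    n = code.shape[0]
    db = ["."] * n
    work = [(0, n - 1, False)]
    while work:
        i, j, paired = work.pop()
        if i > j:
            continue
        if paired:
            db[i] = "("
            db[j] = ")"
            w = wmat[code[i], code[j]]
            # prefer the generic interior (lets inner bases stay unpaired
            # on ties); the stacked channel only wins when strictly better
            if best_paired[i, j] == w + best[i + 1, j - 1]:
                work.append((i + 1, j - 1, False))
            else:
                work.append((i + 1, j - 1, True))
            continue
        if i == j or best[i, j] == best[i + 1, j]:
            work.append((i + 1, j, False))
            continue
        for k in range(i + min_hairpin + 1, j + 1):
            bp = best_paired[i, k]
            if bp == _NEG_INF:
                continue
            rest = best[k + 1, j] if k + 1 <= j else 0.0
            if bp + rest == best[i, j]:
                work.append((i, k, True))
                work.append((k + 1, j, False))
                break
        else:  # pragma: no cover - DP and traceback use identical arithmetic
            raise AssertionError("traceback failed to reproduce DP score")
    return "".join(db)


def mfe_fold(seq: str, params: FoldParams | None = None) -> SecondaryStructure:
    """Predict the maximum-score secondary structure of an RNA.

    Accepts DNA or RNA alphabet (T is treated as U).  Deterministic: the
    same sequence and parameters always give the same structure.

    Raises
    ------
    ValueError
        On an empty sequence, invalid characters, or a sequence longer
        than ``params.max_len``.
    """
    params = params or DEFAULT_PARAMS
    rna = to_rna(seq)
    if not rna:
        raise ValueError("cannot fold an empty sequence")
    if len(rna) > params.max_len:
        raise ValueError(f"sequence length {len(rna)} exceeds max_len {params.max_len}")
    code = _encode(rna)
    n = len(code)
    wmat = params.weight_matrix()
    best = np.zeros((n + 1, n + 1), dtype=np.float64)
    best_paired = np.full((n + 1, n + 1), _NEG_INF, dtype=np.float64)
    _fill_dp(code, wmat, params.min_hairpin, params.stack_bonus, best, best_paired)
    db = _traceback(code, wmat, params.min_hairpin, params.stack_bonus, best, best_paired)
    return SecondaryStructure(sequence=rna, dot_bracket=db, score=float(best[0, n - 1]))


def fold_many(
    seqs: Iterable[str], params: FoldParams | None = None
) -> dict[str, SecondaryStructure]:
    """Fold each distinct sequence once; keys are RNA-alphabet sequences."""
    params = params or DEFAULT_PARAMS
    out: dict[str, SecondaryStructure] = {}
    for seq in seqs:
        rna = to_rna(seq)
        if rna not in out:
            out[rna] = mfe_fold(rna, params)
    return out


def score_structure(
    seq: str, dot_bracket: str, params: FoldParams | None = None
) -> float:
    """Score an explicit structure under the native model (pair weights
    plus stacking bonus); used by the brute-force oracle."""
    params = params or DEFAULT_PARAMS
    wmat = params.weight_matrix()
    code = _encode(seq)
    pairs = SecondaryStructure(to_rna(seq), dot_bracket).pairs()
    pair_set = set(pairs)
    score = 0.0
    for i, j in pairs:
        w = wmat[code[i - 1], code[j - 1]]
        if w <= 0:
            raise ValueError(f"disallowed pair at ({i},{j})")
        score += w
        if (i + 1, j - 1) in pair_set:
            score += params.stack_bonus
    return score


_BRUTE_FORCE_CAP = 18


def brute_force_fold(
    seq: str, params: FoldParams | None = None
) -> tuple[float, SecondaryStructure]:
    """Exhaustive-enumeration folding oracle for short sequences.

    Enumerates every valid non-pseudoknotted structure (allowed pairs,
    minimum hairpin) and returns the maximum score together with the
    first optimal structure in a fixed enumeration order (position
    unpaired before paired, smaller partner first) — the same order the
    DP traceback prefers.

    Raises
    ------
    ValueError
        For sequences longer than 18 nt (enumeration is exponential).
    """
    params = params or DEFAULT_PARAMS
    rna = to_rna(seq)
    if len(rna) > _BRUTE_FORCE_CAP:
        raise ValueError(f"brute force capped at {_BRUTE_FORCE_CAP} nt, got {len(rna)}")
    code = _encode(rna)
    wmat = params.weight_matrix()
    h = params.min_hairpin
    n = len(code)

    def enumerate_pairs(i: int, j: int):
        """Yield lists of 0-based pairs for the interval [i..j]."""
        if i >= j:
            yield []
            return
        yield from enumerate_pairs(i + 1, j)
        for k in range(i + h + 1, j + 1):
            if wmat[code[i], code[k]] > 0.0:
                for inner in enumerate_pairs(i + 1, k - 1):
                    for rest in enumerate_pairs(k + 1, j):
                        yield [(i, k)] + inner + rest

    best_score = _NEG_INF
    best_pairs: list[tuple[int, int]] = []
    for pairs in enumerate_pairs(0, n - 1):
        pair_set = set(pairs)
        score = 0.0
        for i, j in pairs:
            score += wmat[code[i], code[j]]
            if (i + 1, j - 1) in pair_set:
                score += params.stack_bonus
        if score > best_score:
            best_score = score
            best_pairs = pairs
    db = ["."] * n
    for i, j in best_pairs:
        db[i] = "("
        db[j] = ")"
    return best_score, SecondaryStructure(rna, "".join(db), best_score)


# ---------------------------------------------------------------------------
# Validation and Vienna-style text I/O
# ---------------------------------------------------------------------------

def validate_structure(
    structure: SecondaryStructure,
    params: FoldParams | None = None,
    check_model: bool = True,
) -> None:
    """Raise ValueError if a structure violates its invariants.

    Always checks balance and length agreement.  With ``check_model``,
    additionally checks that every pair is allowed by ``params`` and that
    every hairpin loop has at least ``min_hairpin`` unpaired bases —
    appropriate for natively folded structures, not necessarily for
    structures imported from external folders.
    """
    params = params or DEFAULT_PARAMS
    pairs = structure.pairs()  # raises on unbalanced/invalid characters
    if not check_model:
        return
    wmat = params.weight_matrix()
    code = _encode(structure.sequence)
    pair_set = set(pairs)
    for i, j in pairs:
        if wmat[code[i - 1], code[j - 1]] <= 0:
            raise ValueError(f"pair ({i},{j}) not in the allowed pair set")
        if j - i - 1 < params.min_hairpin and not any(
            i < k < l < j for k, l in pair_set
        ):
            raise ValueError(f"hairpin closed by ({i},{j}) shorter than min_hairpin")


_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_vienna(path: str | Path) -> list[SecondaryStructure]:
    """Parse Vienna-style structure text.

    Records are either name/sequence/structure line triples (name lines
    start with ``>``) or sequence/structure pairs; structure lines may
    carry a trailing ``(energy)`` token as written by RNAfold.  Balance
    and length agreement are validated; errors name the offending record.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    out: list[SecondaryStructure] = []
    idx = 0
    rec = 0
    while idx < len(lines):
        name = None
        if lines[idx].startswith(">"):
            name = lines[idx][1:].strip()
            idx += 1
        if idx >= len(lines):
            raise ValueError(f"record {name or rec}: missing sequence line")
        if idx + 1 >= len(lines):
            raise ValueError(f"record {name or rec}: missing structure line")
        seq = to_rna(lines[idx])
        struct_line = lines[idx + 1]
        idx += 2
        rec += 1
        label = name or f"#{rec}"
        score = 0.0
        match = _ENERGY_RE.search(struct_line)
        if match:
            score = float(match.group(1))
            struct_line = struct_line[: match.start()].strip()
        if len(struct_line) != len(seq):
            raise ValueError(
                f"record {label}: structure length {len(struct_line)} != "
                f"sequence length {len(seq)}"
            )
        structure = SecondaryStructure(seq, struct_line, score)
        try:
            structure.pairs()
        except ValueError as exc:
            raise ValueError(f"record {label}: {exc}") from None
        out.append(structure)
    return out


def write_vienna(
    path: str | Path,
    structures: Iterable[tuple[str, SecondaryStructure]],
) -> None:
    """Write (name, structure) pairs as name/sequence/structure triples."""
    with open(path, "w") as handle:
        for name, st in structures:
            handle.write(f">{name}\n{st.sequence}\n{st.dot_bracket} ({st.score:.2f})\n")
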