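"""Per-position structural feature classification of dot-bracket structures.

Every position of a structure is assigned exactly one primary category:

* ``stem`` — the position is base-paired;
* ``hairpin_loop`` — unpaired, inside a loop closed by one pair with no
  inner pairs;
* ``bulge`` — unpaired, in a helix interruption where the opposite
  strand contributes zero unpaired bases;
* ``internal_loop`` — unpaired, in a helix interruption with unpaired
  bases on both strands;
* ``multiloop`` — unpaired, inside a loop from which three or more
  helices emanate;
* ``exterior`` — unpaired and not enclosed by any pair.

Two derived flags capture the local context of the METTL16 methyl
acceptor: ``single_nt_bulge`` (a bulge run of length one) and
``between_two_stems`` (an unpaired position whose immediate 5' and 3'
neighbours are both paired, regardless of loop type — this deliberately
covers single-nucleotide bulges as well as junction nucleotides in
multiloops and the exterior).  Terminal positions can never be between
two stems because they lack a neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

from .fold import SecondaryStructure

__all__ = [
    "CATEGORIES",
    "PositionContext",
    "FeatureAnnotation",
    "pair_table",
    "classify_positions",
    "target_context",
    "helix_lengths",
    "annotations_to_frame",
]

CATEGORIES = (
    "stem",
    "hairpin_loop",
    "bulge",
    "internal_loop",
    "multiloop",
    "exterior",
)


def pair_table(dot_bracket: str) -> list[int]:
    """1-based partner table: ``pt[i]`` is the partner of position i, or 0.

    ``pt[0]`` is unused.  Raises ValueError on unbalanced input or
    characters outside ``(.)``.  Parsing only — model constraints such as
    the minimum hairpin size are the folder's responsibility.
    """
    n = len(dot_bracket)
    pt = [0] * (n + 1)
    stack: list[int] = []
    for i, ch in enumerate(dot_bracket, 1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unclosed '(' at position {stack[-1]}")
    return pt


@dataclass(frozen=True)
class PositionContext:
    """Structural context of one position."""

    category: str
    single_nt_bulge: bool
    between_two_stems: bool
    paired: bool


@dataclass(frozen=True)
class FeatureAnnotation:
    """Per-position structural categories and flags for one structure."""

    dot_bracket: str
    categories: tuple[str, ...]
    single_nt_bulge: tuple[bool, ...]
    between_two_stems: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.dot_bracket)

    def context(self, pos: int) -> PositionContext:
        """Context at a 1-based position."""
        if not 1 <= pos <= len(self):
            raise IndexError(f"position {pos} out of range 1..{len(self)}")
        i = pos - 1
        return PositionContext(
            category=self.categories[i],
            single_nt_bulge=self.single_nt_bulge[i],
            between_two_stems=self.between_two_stems[i],
            paired=self.categories[i] == "stem",
        )


def _unpaired_runs(pt: Sequence[int], start: int, stop: int) -> list[int]:
    """Positions start..stop (1-based inclusive) that are unpaired."""
    return [p for p in range(start, stop + 1) if stop >= start and pt[p] == 0]


def classify_positions(structure: Union[SecondaryStructure, str]) -> FeatureAnnotation:
    """Assign a primary category and the derived flags to every position.

    Accepts a :class:`SecondaryStructure` or a bare dot-bracket string.
    Pure function of the dot-bracket: re-annotating the same string gives
    identical output.
    """
    db = structure.dot_bracket if isinstance(structure, SecondaryStructure) else structure
    pt = pair_table(db)
    n = len(db)
    cats: list[str | None] = [None] * (n + 1)
    run_len = [0] * (n + 1)  # length of the unpaired run containing position

    for i in range(1, n + 1):
        if pt[i]:
            cats[i] = "stem"

    def mark_run(positions: list[int], category: str) -> None:
        for p in positions:
            cats[p] = category
            run_len[p] = len(positions)

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], list[int]]:
        """Directly enclosed helices and unpaired positions of loop (i, j)."""
        kids: list[tuple[int, int]] = []
        unpaired: list[int] = []
        k = i + 1
        while k < j:
            if pt[k]:
                kids.append((k, pt[k]))
                k = pt[k] + 1
            else:
                unpaired.append(k)
                k += 1
        return kids, unpaired

    # loops closed by each pair
    for i in range(1, n + 1):
        j = pt[i]
        if not j or j < i:
            continue
        kids, unpaired = children_of(i, j)
        if not kids:
            mark_run(unpaired, "hairpin_loop")
        elif len(kids) == 1:
            (k, l) = kids[0]
            left = [p for p in unpaired if p < k]
            right = [p for p in unpaired if p > l]
            if left and right:
                mark_run(left, "internal_loop")
                mark_run(right, "internal_loop")
            elif left:
                mark_run(left, "bulge")
            elif right:
                mark_run(right, "bulge")
            # no unpaired bases: stacked pairs, nothing to mark
        else:
            for p in unpaired:
                cats[p] = "multiloop"
                run_len[p] = 0

    # exterior: unpaired positions at the top level
    k = 1
    while k <= n:
        if pt[k]:
            k = pt[k] + 1
        else:
            cats[k] = "exterior"
            k += 1

    categories = tuple(cats[1:])
    assert all(c is not None for c in categories)
    single = tuple(
        categories[i] == "bulge" and run_len[i + 1] == 1 for i in range(n)
    )
    between = tuple(
        categories[i] != "stem"
        and 0 < i < n - 1
        and pt[i] != 0  # pt is 1-based: pt[i] is the partner of position i (= index i-1)
        and pt[i + 2] != 0
        for i in range(n)
    )
    return FeatureAnnotation(
        dot_bracket=db,
        categories=categories,
        single_nt_bulge=single,
        between_two_stems=between,
    )


def target_context(annotation: FeatureAnnotation, pos: int) -> PositionContext:
    """Look up the stored context at a 1-based position (no recomputation)."""
    return annotation.context(pos)


def helix_lengths(dot_bracket: str) -> dict[int, int]:
    """Map each paired 1-based position to the length (in pairs) of its
    helix, where a helix is a maximal run of stacked pairs."""
    pt = pair_table(dot_bracket)
    n = len(dot_bracket)
    out: dict[int, int] = {}
    seen: set[int] = set()
    for i in range(1, n + 1):
        j = pt[i]
        if not j or j < i or i in seen:
            continue
        # i is the outermost 5' base of a helix iff (i-1, j+1) is not a pair
        if i > 1 and pt[i - 1] == j + 1:
            continue
        length = 1
        a, b = i, j
        while a + 1 <= n and pt[a + 1] == b - 1 and b - 1 > a + 1:
            length += 1
            a, b = a + 1, b - 1
        for off in range(length):
            seen.add(i + off)
            out[i + off] = length
            out[j - off] = length
    return out


def annotations_to_frame(
    annotations: dict[str, FeatureAnnotation]
) -> pd.DataFrame:
    """Long-format table: one row per (structure_id, position)."""
    rows = []
    for sid, ann in annotations.items():
        for pos in range(1, len(ann) + 1):
            ctx = ann.context(pos)
            rows.append(
                {
                    "structure_id": sid,
                    "position": pos,
                    "category": ctx.category,
                    "single_nt_bulge": ctx.single_nt_bulge,
                    "between_two_stems": ctx.between_two_stems,
                }
            )
    return pd.DataFrame(rows)
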