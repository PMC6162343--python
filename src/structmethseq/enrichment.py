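"""IP-vs-input differential representation of unique structures.

Filtered reads are aggregated by the dot-bracket string of their
predicted structure (sequences that differ but fold identically are
pooled), then each structure is tested for differential representation
between the pooled immunoprecipitation (IP) libraries and the pooled
input libraries with a library-size-conditioned exact binomial test:
given the structure's total count, the IP share is binomial with success
probability ip_size / (ip_size + input_size) under the null of equal
representation.  P values are Benjamini-Hochberg adjusted across all
tested structures and each structure is classified as ``enriched``
(adjusted p <= alpha and log2FC > 0), ``depleted`` (adjusted p <= alpha
and log2FC < 0) or ``nondiff``.

The log2 fold change is computed on library-size-normalized pooled
counts with a pseudocount applied inside the ratio only::

    log2FC = log2( ((ip + c) / ip_size) / ((input + c) / input_size) )

Replicate dispersion is not modelled; per-structure discordance between
replicates (max |log2 ratio| of normalized replicate counts) is reported
as a diagnostic column instead.  Structures with fewer than ``min_total``
reads overall are excluded from testing.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .reads import to_rna

__all__ = ["aggregate_structures", "differential_representation"]


def aggregate_structures(
    reads_per_library: Mapping[str, Sequence[str]],
    structures: Mapping[str, str],
) -> pd.DataFrame:
    """Count reads per unique dot-bracket per library.

    Parameters
    ----------
    reads_per_library
        Library name -> list of read sequences (DNA or RNA alphabet).
    structures
        Sequence -> dot-bracket string.  Every read sequence must be
        present (keys are matched on the RNA alphabet).

    Returns
    -------
    DataFrame indexed by dot-bracket with one integer column per
    library; column sums equal the library read counts.
    """
    lookup = {to_rna(seq): db for seq, db in structures.items()}
    columns: dict[str, Counter] = {}
    for lib, reads in reads_per_library.items():
        counts: Counter = Counter()
        for idx, read in enumerate(reads):
            db = lookup.get(to_rna(read))
            if db is None:
                raise ValueError(f"library {lib!r}, read {idx}: no structure for read")
            counts[db] += 1
        columns[lib] = counts
    table = pd.DataFrame(columns).fillna(0).astype(int)
    table.index.name = "structure"
    return table.sort_index()


def _infer_columns(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    input_cols = [c for c in table.columns if c.lower().startswith("input")]
    ip_cols = [c for c in table.columns if c.lower().startswith("ip")]
    return input_cols, ip_cols


def differential_representation(
    table: pd.DataFrame,
    input_cols: Sequence[str] | None = None,
    ip_cols: Sequence[str] | None = None,
    alpha: float = 0.1,
    pseudocount: float = 0.5,
    min_total: int = 10,
) -> pd.DataFrame:
    """Classify each structure as enriched, depleted or non-differential.

    ``input_cols``/``ip_cols`` default to columns whose names start with
    ``input``/``ip``.  Library sizes are the column sums.  Returns a
    DataFrame with columns ``structure, input_count, ip_count, log2fc,
    pvalue, padj, tested, class`` (plus ``replicate_discordance`` when a
    condition has >= 2 replicates), sorted by adjusted p value.
    """
    if input_cols is None and ip_cols is None:
        input_cols, ip_cols = _infer_columns(table)
    input_cols = list(input_cols or [])
    ip_cols = list(ip_cols or [])
    if not input_cols or not ip_cols:
        raise ValueError(
            f"need at least one input and one IP column, got input={input_cols} ip={ip_cols}"
        )
    in_sizes = table[input_cols].sum(axis=0)
    ip_sizes = table[ip_cols].sum(axis=0)
    in_size = int(in_sizes.sum())
    ip_size = int(ip_sizes.sum())
    if in_size == 0 or ip_size == 0:
        raise ValueError("all-zero counts in one condition")

    in_counts = table[input_cols].sum(axis=1).to_numpy()
    ip_counts = table[ip_cols].sum(axis=1).to_numpy()
    c = pseudocount
    log2fc = np.log2(((ip_counts + c) / ip_size) / ((in_counts + c) / in_size))

    total = in_counts + ip_counts
    tested = total >= min_total
    p_null = ip_size / (ip_size + in_size)
    pvals = np.full(len(table), np.nan)
    for i in np.flatnonzero(tested):
        pvals[i] = binomtest(int(ip_counts[i]), int(total[i]), p_null).pvalue

    padj = np.full(len(table), np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    klass = np.where(
        tested & (padj <= alpha) & (log2fc > 0),
        "enriched",
        np.where(tested & (padj <= alpha) & (log2fc < 0), "depleted", "nondiff"),
    )

    out = pd.DataFrame(
        {
            "structure": table.index,
            "input_count": in_counts,
            "ip_count": ip_counts,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "tested": tested,
            "class": klass,
        }
    )

    # replicate concordance diagnostic: worst pairwise |log2 ratio| of
    # normalized counts between replicates of the same condition
    discord = np.zeros(len(table))
    any_pairs = False
    for cols in (input_cols, ip_cols):
        if len(cols) < 2:
            continue
        any_pairs = True
        norm = [
            (table[col].to_numpy() + c) / max(int(table[col].sum()), 1) for col in cols
        ]
        for a in range(len(norm)):
            for b in range(a + 1, len(norm)):
                discord = np.maximum(discord, np.abs(np.log2(norm[a] / norm[b])))
    if any_pairs:
        out["replicate_discordance"] = discord

    return out.sort_values(["padj", "pvalue", "structure"], na_position="last").reset_index(
        drop=True
    )
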