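"""Structure aggregation and the IP-vs-input differential test."""

import numpy as np
import pandas as pd
import pytest

from structmethseq import aggregate_structures, differential_representation


def test_aggregation_pools_identical_folds():
    structures = {"AAAA": "....", "CCCC": "....", "GGCC": "(())"}
    reads = {"input_rep1": ["AAAA", "CCCC", "AAAA"], "ip_rep1": ["GGCC"]}
    table = aggregate_structures(reads, structures)
    assert table.loc["....", "input_rep1"] == 3  # different sequences, same fold
    assert table.loc["(())", "ip_rep1"] == 1
    assert table.loc["....", "ip_rep1"] == 0
    # conservation: column sums equal library read counts
    assert table["input_rep1"].sum() == 3
    assert table["ip_rep1"].sum() == 1


def test_aggregation_requires_structures():
    with pytest.raises(ValueError, match="read 0"):
        aggregate_structures({"ip_rep1": ["AAAA"]}, {})


def _table(rows, libs=("input_rep1", "ip_rep1")):
    return pd.DataFrame(rows, columns=list(libs)).set_index(
        pd.Index([f"s{i}" for i in range(len(rows))], name="structure")
    )


def test_identical_proportions_are_nondiff():
    table = _table([[500, 500], [300, 300], [200, 200]])
    res = differential_representation(table, alpha=0.1, min_total=10)
    assert (res.log2fc == 0).all()
    assert (res["class"] == "nondiff").all()


def test_strong_enrichment_example():
    # background structures bring both library sizes to exactly 10,000
    rows = [[0, 100]] + [[100, 99]] * 100
    table = _table(rows)
    res = differential_representation(table, min_total=10).set_index("structure")
    rec = res.loc["s0"]
    assert rec.log2fc == pytest.approx(np.log2(100.5 / 0.5), abs=1e-9)  # 7.6511
    assert rec["class"] == "enriched"
    assert rec.padj < 1e-10


def test_swapping_conditions_negates_log2fc():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 200, size=(50, 2))
    table = _table(counts.tolist())
    res = differential_representation(table).set_index("structure")
    flipped = table.rename(
        columns={"input_rep1": "ip_rep1", "ip_rep1": "input_rep1"}
    )
    res_f = differential_representation(flipped).set_index("structure")
    assert np.allclose(res.log2fc, -res_f.loc[res.index].log2fc)


def test_min_total_excludes_sparse_structures():
    table = _table([[2, 3], [50, 50]])
    res = differential_representation(table, min_total=10).set_index("structure")
    assert not res.loc["s0", "tested"]
    assert np.isnan(res.loc["s0", "pvalue"])
    assert res.loc["s0", "class"] == "nondiff"
    assert res.loc["s1", "tested"]


def test_bh_adjustment_is_monotone_in_p_rank():
    rng = np.random.default_rng(1)
    table = _table(rng.integers(5, 300, size=(200, 2)).tolist())
    res = differential_representation(table)
    tested = res[res.tested].sort_values("pvalue")
    assert (tested.padj.diff().dropna() >= -1e-12).all()
    assert (tested.padj >= tested.pvalue - 1e-12).all()


def test_error_conditions():
    table = _table([[10, 10]])
    with pytest.raises(ValueError, match="input"):
        differential_representation(table[["ip_rep1"]])
    zero = _table([[0, 5]])
    zero["input_rep1"] = 0
    with pytest.raises(ValueError, match="all-zero"):
        differential_representation(zero)


def test_replicate_discordance_reported_with_replicates():
    table = pd.DataFrame(
        {"input_rep1": [100, 50], "input_rep2": [100, 50],
         "ip_rep1": [100, 50], "ip_rep2": [100, 50]},
        index=pd.Index(["a", "b"], name="structure"),
    )
    res = differential_representation(table, min_total=1)
    assert "replicate_discordance" in res.columns
    assert np.allclose(res.replicate_discordance, 0)


def test_planted_preference_recovers_direction(planted_sim, planted_pipeline):
    """Structures whose target A sits between two stems are IP-enriched;
    background structures are depleted (median log2FC signs)."""
    results = planted_pipeline["results"]
    truth = planted_sim.truth.drop_duplicates("dot_bracket")
    merged = results.merge(
        truth[["dot_bracket", "structured"]],
        left_on="structure",
        right_on="dot_bracket",
    )
    tested = merged[merged.tested]
    assert tested[tested.structured].log2fc.median() > 0
    assert tested[~tested.structured].log2fc.median() < 0
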