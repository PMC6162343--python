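"""Positional frequency profiles, the 0.5% floor rule, and target-position
feature proportions."""

import numpy as np
import pytest

from structmethseq import (
    FloorRule,
    classify_positions,
    feature_frequency_profile,
    log2_frequency_ratio,
    nucleotide_frequency_comparison,
    target_feature_proportions,
)
from structmethseq.features import CATEGORIES

ANN_STEM = classify_positions("((...))")  # position 1 paired
ANN_FLAT = classify_positions(".......")  # position 1 unpaired


def test_unweighted_frequency_is_structure_fraction():
    prof = feature_frequency_profile([ANN_STEM, ANN_FLAT], "stem")
    assert prof[0] == 0.5


def test_read_count_weighting():
    prof = feature_frequency_profile([ANN_STEM, ANN_FLAT], "stem", weights=[3, 1])
    assert prof[0] == 0.75


def test_primary_categories_partition_each_position():
    anns = [ANN_STEM, ANN_FLAT]
    total = sum(
        feature_frequency_profile(anns, cat) for cat in CATEGORIES
    )
    assert np.allclose(total, 1.0)


def test_equal_weights_coincide_with_unweighted():
    anns = [ANN_STEM, ANN_FLAT, ANN_STEM]
    for feature in ("stem", "between_two_stems", "unpaired"):
        unweighted = feature_frequency_profile(anns, feature)
        weighted = feature_frequency_profile(anns, feature, weights=[7, 7, 7])
        assert np.allclose(unweighted, weighted)


def test_empty_class_and_mismatched_lengths():
    with pytest.raises(ValueError):
        feature_frequency_profile([], "stem")
    with pytest.raises(ValueError):
        feature_frequency_profile([ANN_STEM, classify_positions("....")], "stem")
    with pytest.raises(ValueError):
        feature_frequency_profile([ANN_STEM], "no_such_feature")


@pytest.mark.parametrize(
    "fa, fb, expected",
    [
        (0.20, 0.10, 1.0),
        (0.004, 0.002, 0.0),  # both floored to 0.005
        (0.05, 0.004, np.log2(0.05 / 0.005)),  # ~3.3219
    ],
)
def test_floor_rule_examples(fa, fb, expected):
    ratio = log2_frequency_ratio(np.array([fa]), np.array([fb]))
    assert ratio[0] == pytest.approx(expected, abs=1e-9)


def test_floor_bounds_ratios():
    rule = FloorRule(0.005)
    bound = np.log2(1 / rule.floor)
    rng = np.random.default_rng(0)
    a, b = rng.random(100), rng.random(100)
    ratios = log2_frequency_ratio(a, b, rule)
    assert np.all(np.abs(ratios) <= bound + 1e-12)
    with pytest.raises(ValueError):
        FloorRule(0.0)
    with pytest.raises(ValueError):
        log2_frequency_ratio(np.zeros(3), np.zeros(4))


def test_target_proportions_single_structure():
    ann = classify_positions("((.((...))))")
    props = target_feature_proportions([ann], pos=3)
    assert props["bulge"] == 1.0
    assert props["single_nt_bulge"] == 1.0
    assert props["between_two_stems"] == 1.0
    assert sum(props[c] for c in CATEGORIES) == pytest.approx(1.0)


def test_target_proportions_partition_and_bounds():
    anns = [ANN_STEM, ANN_FLAT]
    props = target_feature_proportions(anns, pos=1)
    assert sum(props[c] for c in CATEGORIES) == pytest.approx(1.0)
    with pytest.raises(IndexError):
        target_feature_proportions(anns, pos=8)
    with pytest.raises(ValueError):
        target_feature_proportions([], pos=1)


def test_nucleotide_comparison_identical_sets_and_motif_constancy():
    reads = ["A" * 11 + "TACAGAGAA" + "C" * 10, "G" * 11 + "TACAGAGAA" + "T" * 10]
    table = nucleotide_frequency_comparison(reads, reads)
    assert np.allclose(table.log2_ratio, 0.0)
    motif_rows = table[table.in_motif]
    assert set(motif_rows.position.unique()) == set(range(12, 21))
    # the filter guarantees motif positions constant: frequency 1 for the motif base
    a15 = motif_rows[(motif_rows.position == 15) & (motif_rows.base == "A")]
    assert (a15.freq_ip == 1.0).all()


def test_nucleotide_comparison_detects_planted_gc_bias():
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGT"))

    def make(p_gc, n):
        probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
        out = []
        for _ in range(n):
            flanks = rng.choice(bases, size=21, p=probs)
            out.append("".join(flanks[:11]) + "TACAGAGAA" + "".join(flanks[11:]))
        return out

    table = nucleotide_frequency_comparison(make(0.7, 400), make(0.4, 400))
    flank = table[~table.in_motif]
    for base in "GC":
        assert flank[flank.base == base].log2_ratio.mean() > 0.3
    for base in "AT":
        assert flank[flank.base == base].log2_ratio.mean() < -0.3


def test_empty_read_sets_rejected():
    with pytest.raises(ValueError):
        nucleotide_frequency_comparison([], ["ACGT"])
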