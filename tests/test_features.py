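"""Per-position structural classification against hand-annotated structures
and structural invariants on random folds."""

import pytest

from structmethseq import classify_positions, pair_table, target_context
from structmethseq.features import CATEGORIES, helix_lengths


def test_pair_table_direct():
    pt = pair_table("((...))")
    assert pt[1:] == [7, 6, 0, 0, 0, 2, 1]
    assert pair_table("......")[1:] == [0] * 6


def test_pair_table_parses_without_model_validation():
    # min-hairpin violations are the folder's concern, not the parser's
    assert pair_table("(())")[1:] == [4, 3, 2, 1]


@pytest.mark.parametrize("db", ["((...", "...))", ")("])
def test_pair_table_unbalanced(db):
    with pytest.raises(ValueError):
        pair_table(db)


def test_hand_annotated_single_nt_bulge_structure():
    # pairs 1-12, 2-11, 4-10, 5-9; position 3 is a 1-nt bulge between helices
    ann = classify_positions("((.((...))))")
    assert ann.categories == (
        "stem", "stem", "bulge", "stem", "stem",
        "hairpin_loop", "hairpin_loop", "hairpin_loop",
        "stem", "stem", "stem", "stem",
    )
    ctx = target_context(ann, 3)
    assert (ctx.category, ctx.single_nt_bulge, ctx.between_two_stems, ctx.paired) == (
        "bulge", True, True, False,
    )
    assert target_context(ann, 1).category == "stem"
    assert not target_context(ann, 1).between_two_stems


def test_all_unpaired_is_exterior_without_flags():
    ann = classify_positions("........")
    assert set(ann.categories) == {"exterior"}
    assert not any(ann.single_nt_bulge)
    assert not any(ann.between_two_stems)


def test_exterior_junction_between_two_hairpins():
    ann = classify_positions("((((...)))).((((...))))")
    ctx = target_context(ann, 12)
    assert ctx.category == "exterior"
    assert ctx.between_two_stems  # neighbours 11 and 13 are paired


def test_internal_loop_and_multiloop():
    # internal loop: unpaired on both strands of the helix interruption
    ann = classify_positions("((..((...))..))")
    assert ann.categories[2] == ann.categories[3] == "internal_loop"
    assert ann.categories[11] == ann.categories[12] == "internal_loop"
    assert not any(ann.single_nt_bulge)
    # multiloop: closing pair plus two enclosed helices
    ann = classify_positions("((((...))((...))))")
    assert ann.categories[1] == "stem"
    multi = [c for c in ann.categories if c == "multiloop"]
    assert not multi  # no unpaired base inside this tight junction
    ann = classify_positions("((((...)).((...))))")
    assert ann.categories[9] == "multiloop"
    assert ann.between_two_stems[9]


def test_bulge_run_longer_than_one_is_not_single_nt():
    ann = classify_positions("((..((...))))")
    assert ann.categories[2] == ann.categories[3] == "bulge"
    assert not ann.single_nt_bulge[2]
    assert not ann.between_two_stems[2]  # 5' neighbour of position 4 is unpaired


def test_terminal_positions_never_between_two_stems():
    ann = classify_positions(".((...)).")
    assert not ann.between_two_stems[0]
    assert not ann.between_two_stems[-1]


def test_context_bounds():
    ann = classify_positions("...")
    with pytest.raises(IndexError):
        target_context(ann, 0)
    with pytest.raises(IndexError):
        target_context(ann, 4)


def test_partition_and_flag_invariants_on_random_folds(random_structures):
    for st_ in random_structures:
        ann = classify_positions(st_)
        db = st_.dot_bracket
        pt = pair_table(db)
        n = len(db)
        # exactly one primary category per position; stem iff paired
        assert len(ann.categories) == n
        counts = {c: ann.categories.count(c) for c in CATEGORIES}
        assert sum(counts.values()) == n
        for pos in range(1, n + 1):
            assert (ann.categories[pos - 1] == "stem") == (pt[pos] != 0)
            # independent neighbour check for between_two_stems
            expected = (
                pt[pos] == 0
                and 1 < pos < n
                and pt[pos - 1] != 0
                and pt[pos + 1] != 0
            )
            assert ann.between_two_stems[pos - 1] == expected
            if ann.single_nt_bulge[pos - 1]:
                assert ann.categories[pos - 1] == "bulge"
                assert ann.between_two_stems[pos - 1]
        # pure function: re-annotation is identical
        assert classify_positions(db) == ann


def test_helix_lengths():
    assert helix_lengths("(((...)))") == {i: 3 for i in (1, 2, 3, 7, 8, 9)}
    hl = helix_lengths("((.((...))))")
    assert hl[1] == hl[2] == hl[11] == hl[12] == 2
    assert hl[4] == hl[5] == hl[9] == hl[10] == 2
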