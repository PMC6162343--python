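"""The randomized-library generator and simulated IP experiment."""

import numpy as np
import pytest

import structmethseq as sm
from structmethseq.simulate import ErrorRates


def test_empty_and_negative_n():
    assert sm.generate_oligo_library(n=0, seed=1) == []
    with pytest.raises(ValueError):
        sm.generate_oligo_library(n=-1, seed=1)


def test_design_layout_and_determinism():
    oligos = sm.generate_oligo_library(n=1000, seed=1)
    assert len(oligos) == 1000
    for o in oligos:
        assert len(o.sequence) == 30
        assert o.sequence[11:20] == "TACAGAGAA"  # motif at 12-20, 1-based
        assert set(o.sequence) <= set("ACGT")
    again = sm.generate_oligo_library(n=1000, seed=1)
    assert again == oligos
    assert sm.generate_oligo_library(n=1000, seed=2) != oligos


def test_design_target_position():
    design = sm.LibraryDesign()
    assert design.length == 30
    assert design.target_pos == 15
    assert design.motif_start == 12
    with pytest.raises(ValueError):
        sm.LibraryDesign(motif="UACGGAGAA", target_offset_in_motif=4)  # not an A


def test_selection_model_validation():
    with pytest.raises(ValueError):
        sm.SelectionModel(p_ip_structured=0.1, p_ip_background=0.5)
    with pytest.raises(ValueError):
        sm.SelectionModel(input_depth=0)
    with pytest.raises(ValueError):
        ErrorRates(n_substitution=1.5)


def test_empty_oligo_list_rejected():
    with pytest.raises(ValueError):
        sm.simulate_ip_experiment([], None, sm.SelectionModel())


def test_zero_error_rates_give_filter_clean_reads():
    oligos = sm.generate_oligo_library(n=50, seed=3)
    model = sm.SelectionModel(
        input_depth=500, ip_depth=500, error_rates=ErrorRates(0, 0, 0), seed=3
    )
    sim = sm.simulate_ip_experiment(oligos, None, model)
    assert sorted(sim.reads) == ["input_rep1", "input_rep2", "ip_rep1", "ip_rep2"]
    for recs in sim.reads.values():
        kept, report = sm.filter_reads([s for _, s in recs])
        assert report.rejected == 0
        assert len(kept) == 500


def test_simulation_is_deterministic_and_artifacts_appear(planted_sim):
    again = sm.simulate_ip_experiment(
        sm.generate_oligo_library(n=1200, seed=42), None, planted_sim.model
    )
    assert again.reads == planted_sim.reads
    assert again.truth.equals(planted_sim.truth)
    # default artifact rates are nonzero: some reads must fail the filter
    _, report = sm.filter_reads(
        [s for _, s in planted_sim.reads["input_rep1"]]
    )
    assert 0 < report.rejected < report.total * 0.1


def test_ground_truth_class_matches_refolding(planted_sim):
    truth = planted_sim.truth
    sub = truth.head(100)
    for _, row in sub.iterrows():
        st_ = sm.mfe_fold(row.sequence)
        assert st_.dot_bracket == row.dot_bracket
        ann = sm.classify_positions(st_)
        assert ann.between_two_stems[14] == row.structured  # target A at 15
    assert set(truth.p_capture.unique()) <= {0.9, 0.05}


def test_ip_capture_ratio_matches_analytic_expectation(planted_sim):
    """IP/input representation ratio of structured vs background oligos
    approximates p_ip_structured / p_ip_background (= 18) before
    normalization."""
    truth = planted_sim.truth
    structured_ids = set(truth.loc[truth.structured, "sequence"])
    counts = {"input": [0, 0], "ip": [0, 0]}  # [structured, background]
    for lib, recs in planted_sim.reads.items():
        cond = "ip" if lib.startswith("ip") else "input"
        for _, seq in recs:
            if seq in structured_ids:
                counts[cond][0] += 1
            elif len(seq) == 30 and "N" not in seq and seq[11:20] == "TACAGAGAA":
                counts[cond][1] += 1
    ip_ratio = counts["ip"][0] / counts["ip"][1]
    input_ratio = counts["input"][0] / counts["input"][1]
    observed = ip_ratio / input_ratio
    assert observed == pytest.approx(18.0, rel=0.15)


def test_structured_fraction_converges_to_brute_force_estimate():
    """The ground-truth structured fraction equals the fraction of random
    flank pairs folding with the target A between paired neighbours."""
    oligos = sm.generate_oligo_library(n=2000, seed=9)
    model = sm.SelectionModel(input_depth=10, ip_depth=10, seed=9)
    sim = sm.simulate_ip_experiment(oligos, None, model)
    direct = np.mean(
        [
            sm.classify_positions(sm.mfe_fold(o.sequence)).between_two_stems[14]
            for o in oligos
        ]
    )
    assert sim.truth.structured.mean() == direct


def test_write_outputs_are_parseable_and_stable(tmp_path, planted_sim):
    paths = planted_sim.write(tmp_path / "a")
    from structmethseq.reads import read_sequences

    recs = read_sequences(paths["input_rep1"])
    assert recs == planted_sim.reads["input_rep1"]
    paths2 = planted_sim.write(tmp_path / "b")
    assert paths["input_rep1"].read_bytes() == paths2["input_rep1"].read_bytes()


def test_genotyping_read_simulator_mixes_alleles():
    reads = sm.simulate_genotyping_reads(100, ko_fraction=0.5, n_background=20, seed=5)
    assert len(reads) == 120
    assert all(len(r) == 80 for r in reads)
    counts = sm.count_diagnostic_reads(reads)
    assert counts.wt + counts.ko == 100
    assert 25 <= counts.ko <= 75
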