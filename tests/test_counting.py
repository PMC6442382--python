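import numpy as np
import pandas as pd
import pytest

import crisprgi as cg
from crisprgi.counting import CountingError, _marginals
from crisprgi.design import PoolDesign
from crisprgi.simulate import FIXTURE_LINKER


def _tiny_design():
    starting = pd.DataFrame(
        {"target_gene": ["A", "B"], "bioprocess": ["p", "p"], "guide_seq": ["A" * 20, "C" * 20]},
        index=pd.Index(["g1", "g2"], name="guide_id"),
    )
    queries = pd.DataFrame(
        {
            "target_gene": ["X", "Y"],
            "bioprocess": ["p", "p"],
            "barcode": ["G" * 25, "T" * 25],
            "guide_seq": ["G" * 20, "T" * 20],
        },
        index=pd.Index(["q1", "q2"], name="query_id"),
    )
    combos = pd.DataFrame(
        {
            "guide_id": ["g1", "g1", "g2", "g2"],
            "query_id": ["q1", "q2", "q1", "q2"],
            "strain_class": ["double_knockdown"] * 4,
            "present": [True, True, True, False],
        },
        index=pd.Index(["g1:q1", "g1:q2", "g2:q1", "g2:q2"], name="strain_id"),
    )
    return PoolDesign(starting=starting, queries=queries, combos=combos)


def _write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n")


def test_parse_reads_exact_and_mismatch(tmp_path):
    design = _tiny_design()
    good = "A" * 20 + FIXTURE_LINKER + "G" * 25
    one_mm = "A" * 20 + FIXTURE_LINKER + "G" * 24 + "A"  # one barcode mismatch
    fq = tmp_path / "reads.fastq"
    _write_fastq(fq, [good, one_mm])
    ct, unassigned = cg.parse_reads(fq, design, max_mismatches_guide=0, max_mismatches_barcode=1)
    assert ct.counts.loc["g1:q1", "t0"] == 2
    assert unassigned == 0
    ct0, unassigned0 = cg.parse_reads(fq, design, max_mismatches_guide=0, max_mismatches_barcode=0)
    assert ct0.counts.loc["g1:q1", "t0"] == 1
    assert unassigned0 == 1


def test_parse_reads_counts_absent_combos(tmp_path):
    design = _tiny_design()
    chimera = "C" * 20 + FIXTURE_LINKER + "T" * 25  # g2 guide + q2 barcode: absent combo
    fq = tmp_path / "reads.fastq"
    _write_fastq(fq, [chimera])
    ct, _ = cg.parse_reads(fq, design)
    assert ct.counts.loc["g2:q2", "t0"] == 1


def test_parse_reads_ambiguous_design_rejected(tmp_path):
    design = _tiny_design()
    design.starting.loc["g2", "guide_seq"] = "A" * 19 + "C"  # 1 mismatch from g1
    fq = tmp_path / "reads.fastq"
    _write_fastq(fq, ["A" * 20 + FIXTURE_LINKER + "G" * 25])
    with pytest.raises(CountingError, match="ambiguous"):
        cg.parse_reads(fq, design, max_mismatches_guide=1)


def test_fastq_from_simulation_round_trips_exactly(tmp_path, small_design, small_truth):
    tensors = cg.simulate_counts(
        small_design, small_truth, conditions=["YPD24hr"], replicates=1, n_cycles=1, depth=10_000, seed=2
    )
    fq = tmp_path / "sim.fastq"
    n = cg.write_fastq(tensors[0], small_design, "t0", fq)
    assert n == 10_000
    ct, unassigned = cg.parse_reads(fq, small_design, max_mismatches_guide=0, max_mismatches_barcode=0)
    assert unassigned == 0
    pd.testing.assert_series_equal(
        ct.counts["t0"].sort_index(), tensors[0].counts["t0"].sort_index(), check_names=False
    )


def test_chimera_rate_zero_when_absent_combos_clean():
    design = _tiny_design()
    counts = pd.DataFrame({"t0": [500, 300, 200, 0]}, index=design.combos.index)
    ct = cg.CountTensor(condition="c", replicate=1, counts=counts)
    model = cg.estimate_chimera_rate(ct, design)
    assert model.rho == 0.0


def test_chimera_rate_hand_computed_value():
    """One absent combo with n=10 of N=1e6 reads and marginal product 1e-4
    gives rho = 10 / (1e6 * 1e-4) = 0.1."""
    design = _tiny_design()
    counts = pd.DataFrame({"t0": [980010, 9990, 9990, 10]}, index=design.combos.index)
    ct = cg.CountTensor(condition="c", replicate=1, counts=counts)
    pg, pb, total = _marginals(counts["t0"], design)
    assert total == 1e6
    assert pg["g2"] * pb["q2"] == pytest.approx(1e-4)
    model = cg.estimate_chimera_rate(ct, design)
    assert model.rho == pytest.approx(0.1)


def test_chimera_rate_no_absent_combos_warns(small_design):
    spec = [{"query_id": "q1", "target_gene": "Z"}]
    design = cg.design_pool(2, 0, spec, holdout_fraction=0.0, seed=0)
    counts = pd.DataFrame({"t0": [10, 20]}, index=design.combos.index)
    ct = cg.CountTensor(condition="c", replicate=1, counts=counts)
    model = cg.estimate_chimera_rate(ct, design)
    assert model.rho == 0.0 and model.warning


def test_correction_identity_monotone_and_cleans_absent(small_design):
    truth = cg.simulate_truth(small_design, chimera_rate=0.05, seed=21)
    ct = cg.simulate_counts(
        small_design, truth, conditions=["YPD24hr"], replicates=1, n_cycles=2, depth=10**6, seed=21
    )[0]
    model = cg.estimate_chimera_rate(ct, small_design)
    assert 0.03 < model.rho < 0.07
    corrected = cg.correct_chimeras(ct, model, small_design)
    raw = ct.counts.to_numpy(dtype=float)
    cor = corrected.counts.to_numpy()
    assert (cor <= raw + 1e-9).all()
    assert (cor >= 0).all()
    absent = small_design.absent_combos.index
    before = ct.counts.loc[absent].to_numpy().sum()
    after = corrected.counts.loc[absent].to_numpy().sum()
    assert after <= 0.05 * before
    # rho = 0 leaves counts untouched
    zero = cg.ChimeraModel(rho=0.0, rho_per_timepoint={}, n_absent_used=0)
    same = cg.correct_chimeras(ct, zero, small_design)
    np.testing.assert_array_equal(same.counts.to_numpy(), ct.counts.to_numpy())


def test_correction_reduces_error_against_chimera_free_truth(small_design):
    """Mean absolute relative error vs the chimera-free counts improves for
    well-covered strains after correction."""
    truth_clean = cg.simulate_truth(small_design, chimera_rate=0.0, seed=33)
    truth_chim = cg.simulate_truth(small_design, chimera_rate=0.08, seed=33)
    clean = cg.simulate_counts(
        small_design, truth_clean, conditions=["YPD24hr"], replicates=1, n_cycles=1, depth=10**6, seed=33
    )[0]
    chim = cg.simulate_counts(
        small_design, truth_chim, conditions=["YPD24hr"], replicates=1, n_cycles=1, depth=10**6, seed=33
    )[0]
    model = cg.estimate_chimera_rate(chim, small_design)
    corrected = cg.correct_chimeras(chim, model, small_design)
    strains = clean.counts.index[clean.counts["t0"] >= 100]
    ref = clean.counts.loc[strains, "t0"].to_numpy(dtype=float) * (1 - truth_chim.chimera_rate)
    err_raw = np.abs(chim.counts.loc[strains, "t0"].to_numpy() - ref) / ref
    err_cor = np.abs(corrected.counts.loc[strains, "t0"].to_numpy() - ref) / ref
    assert err_cor.mean() < err_raw.mean()


def test_negative_counts_rejected():
    design = _tiny_design()
    counts = pd.DataFrame({"t0": [1, -1, 0, 0]}, index=design.combos.index)
    with pytest.raises(CountingError):
        cg.CountTensor(condition="c", replicate=1, counts=counts)
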