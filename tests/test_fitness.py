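import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crisprgi as cg
from crisprgi.fitness import FitnessError, aggregate_replicates, normalize_frequencies


def _tensor(counts, condition="c", replicate=1, G=2.0):
    return cg.CountTensor(condition=condition, replicate=replicate, counts=counts, generations_per_cycle=G)


def test_normalize_simple_and_round_trip():
    counts = pd.DataFrame({"t0": [10, 30]}, index=["a", "b"])
    freq = normalize_frequencies(_tensor(counts))
    assert freq["t0"].tolist() == [0.25, 0.75]
    np.testing.assert_allclose(freq["t0"] * counts["t0"].sum(), counts["t0"])


def test_normalize_all_zero_timepoint_names_sample():
    counts = pd.DataFrame({"t0": [1, 1], "t1": [0, 0]}, index=["a", "b"])
    with pytest.raises(FitnessError, match="c/rep1"):
        normalize_frequencies(_tensor(counts))


@settings(derandomize=True, max_examples=25)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=3, max_size=3),
        min_size=2,
        max_size=8,
    )
)
def test_normalized_columns_sum_to_one(rows):
    counts = pd.DataFrame(rows, columns=["t0", "t1", "t2"])
    if (counts.sum(axis=0) == 0).any():
        return
    freq = normalize_frequencies(_tensor(counts))
    np.testing.assert_allclose(freq.sum(axis=0), 1.0)


def _two_strain_design():
    return cg.design_pool(
        1, 1, [{"query_id": "NTq1", "target_gene": None}], guides_per_gene=1, seed=0
    )


def test_closed_form_half_fitness():
    """A strain whose frequency ratio to a neutral control decays by 0.25
    per 2-generation cycle has w = exp(ln 0.25 / 2) = 0.5."""
    design = _two_strain_design()
    # sg0000:NTq1 is the test strain (single knockdown); sgNT000:NTq1 the control
    counts = pd.DataFrame(
        {
            "t0": [400.0, 400.0],
            "t1": [100.0, 400.0],
            "t2": [25.0, 400.0],
        },
        index=["sg0000:NTq1", "sgNT000:NTq1"],
    )
    fit = cg.estimate_fitness(_tensor(counts), design, min_count=1)
    assert fit.loc["sg0000:NTq1", "w"] == pytest.approx(0.5, abs=1e-12)
    assert fit.loc["sgNT000:NTq1", "w"] == pytest.approx(1.0, abs=1e-12)


def test_constant_frequency_strain_is_neutral():
    design = _two_strain_design()
    counts = pd.DataFrame(
        {"t0": [300.0, 300.0], "t1": [300.0, 300.0], "t2": [300.0, 300.0]},
        index=["sg0000:NTq1", "sgNT000:NTq1"],
    )
    fit = cg.estimate_fitness(_tensor(counts), design, min_count=1)
    assert fit["w"].tolist() == pytest.approx([1.0, 1.0])


def test_noiseless_recovery_matches_truth(small_design, small_truth, noiseless_counts):
    fit = cg.estimate_fitness(noiseless_counts[0], small_design, min_count=0)
    truth_w = small_truth.double_fitness(small_design, "YPD24hr")
    ok = fit["measurable"]
    np.testing.assert_allclose(
        fit.loc[ok, "w"].to_numpy(), truth_w.loc[fit.index[ok]].to_numpy(), atol=1e-9
    )


def test_fitness_invariant_to_depth_rescaling(small_design, noisy_counts):
    ct = noisy_counts[0]
    scaled = ct.copy_with(ct.counts * 10)
    a = cg.estimate_fitness(ct, small_design, min_count=10)
    b = cg.estimate_fitness(scaled, small_design, min_count=100)
    ok = a["measurable"] & b["measurable"]
    np.testing.assert_allclose(a.loc[ok, "w"], b.loc[ok, "w"], atol=1e-12)


def test_min_count_marks_unmeasurable():
    design = _two_strain_design()
    counts = pd.DataFrame(
        {"t0": [5.0, 400.0], "t1": [4.0, 400.0], "t2": [2.0, 400.0]},
        index=["sg0000:NTq1", "sgNT000:NTq1"],
    )
    fit = cg.estimate_fitness(_tensor(counts), design, min_count=10)
    assert not fit.loc["sg0000:NTq1", "measurable"]
    assert np.isnan(fit.loc["sg0000:NTq1", "w"])


def test_control_trajectory_required():
    design = _two_strain_design()
    counts = pd.DataFrame(
        {"t0": [400.0, 5.0], "t1": [400.0, 2.0], "t2": [400.0, 1.0]},
        index=["sg0000:NTq1", "sgNT000:NTq1"],
    )
    with pytest.raises(FitnessError, match="control"):
        cg.estimate_fitness(_tensor(counts), design, min_count=10)


def _per_rep_frame(ws, measurable=None):
    measurable = measurable if measurable is not None else [True] * len(ws)
    return pd.DataFrame(
        {
            "condition": "c",
            "replicate": range(1, len(ws) + 1),
            "w": ws,
            "n_timepoints": 4,
            "measurable": measurable,
        },
        index=["s1"] * len(ws),
    )


def test_aggregate_replicates_mean_and_exclusion():
    agg = aggregate_replicates(_per_rep_frame([0.8, 1.0, 1.2]), required=3)
    assert agg.loc["s1", "w_mean"] == pytest.approx(1.0)
    assert agg.loc["s1", "measurable"]
    assert agg.loc["s1", "w_sd"] == pytest.approx(np.std([0.8, 1.0, 1.2], ddof=1))
    # one unmeasurable replicate drops the mean but keeps the row
    agg2 = aggregate_replicates(_per_rep_frame([0.8, 1.0, 1.2], [True, False, True]), required=3)
    assert not agg2.loc["s1", "measurable"]
    assert np.isnan(agg2.loc["s1", "w_mean"])


def test_single_mutant_fitness_averages_replicate_strains(small_design, fitness_table):
    singles = fitness_table.singles
    assert {"starting", "query"} <= set(singles.index.get_level_values("role"))
    # each starting guide's single fitness averages its nontargeting-query strains
    some = singles.xs("starting", level="role").iloc[0]
    assert some["n_strains"] >= 1
    agg = fitness_table.aggregated
    nt_queries = small_design.queries.index[small_design.queries["target_gene"] == cg.NONTARGETING]
    gid = singles.xs("starting", level="role").index.get_level_values(0)[0]
    cond = singles.xs("starting", level="role").index.get_level_values(1)[0]
    sids = [f"{gid}:{q}" for q in nt_queries]
    sub = agg[(agg["condition"] == cond) & agg["measurable"]]
    manual = sub.loc[sub.index.intersection(sids), "w_mean"].mean()
    got = singles.loc[("starting", gid, cond), "w"]
    assert got == pytest.approx(manual)


def test_no_knockdown_controls_center_at_one(small_design, small_truth, noiseless_counts):
    fit = cg.estimate_fitness(noiseless_counts[0], small_design, min_count=0)
    ctrl = small_design.present_combos.index[
        small_design.present_combos["strain_class"] == cg.NONE_CLASS
    ]
    assert abs(fit.loc[ctrl, "w"].mean() - 1.0) < 0.01


def test_estimated_order_matches_true_order_mostly(small_design, small_truth):
    """Strains whose true fitness differs by >= 0.05 should preserve the
    ordering of single vs double knockdowns nearly always at high depth."""
    ct = cg.simulate_counts(
        small_design, small_truth, conditions=["YPD24hr"], replicates=1, depth=10**6, seed=77
    )[0]
    fit = cg.estimate_fitness(ct, small_design, min_count=10)
    truth = small_truth.double_fitness(small_design, "YPD24hr")
    ok = fit[fit["measurable"]].index
    genes = small_design.combo_genes().loc[ok]
    singles = genes[genes["strain_class"] == cg.SINGLE].index
    doubles = genes[genes["strain_class"] == cg.DOUBLE].index
    wins = total = 0
    for g in small_design.starting.index[:20]:
        s_ids = [s for s in singles if s.startswith(f"{g}:")]
        d_ids = [s for s in doubles if s.startswith(f"{g}:")]
        for s in s_ids:
            for d in d_ids:
                if truth[s] - truth[d] >= 0.05:
                    total += 1
                    wins += fit.loc[s, "w"] > fit.loc[d, "w"]
    assert total > 50
    assert wins / total >= 0.95
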