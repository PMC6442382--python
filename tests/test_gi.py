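import warnings

import numpy as np
import pandas as pd
import pytest

import crisprgi as cg
from crisprgi.gi import GIError, LINEAR, MULTIPLICATIVE

from _oracles import (
    condition_specific_oracle,
    hypergeom_upper_tail_oracle,
    ols_oracle,
)


def test_multiplicative_expectation():
    assert cg.expected_multiplicative(1.0, 1.0) == 1.0
    assert cg.expected_multiplicative(0.8, 0.9) == pytest.approx(0.72)
    assert 0.72 - cg.expected_multiplicative(0.8, 0.9) == pytest.approx(0.0)


def test_query_model_exact_line_and_zero_residuals():
    x = np.array([0.2, 0.5, 0.7, 0.9, 1.0])
    y = 0.2 + 0.8 * x
    m = cg.fit_query_model(x, y, min_points=3)
    assert m.beta0 == pytest.approx(0.2, abs=1e-12)
    assert m.beta1 == pytest.approx(0.8, abs=1e-12)
    resid = y - (m.beta0 + m.beta1 * x)
    assert abs(resid.sum()) < 1e-12


def test_query_model_matches_normal_equations_oracle():
    x = [0.31, 0.55, 0.62, 0.81, 0.97]
    y = [0.45, 0.58, 0.70, 0.66, 0.93]
    m = cg.fit_query_model(x, y, min_points=3)
    b0, b1 = ols_oracle(x, y)
    assert m.beta0 == pytest.approx(b0, abs=1e-10)
    assert m.beta1 == pytest.approx(b1, abs=1e-10)


def test_query_model_degenerate_or_sparse_falls_back():
    with pytest.warns(UserWarning, match="multiplicative"):
        m = cg.fit_query_model([0.5] * 40, np.linspace(0, 1, 40), min_points=3)
    assert m.model_used == MULTIPLICATIVE
    with pytest.warns(UserWarning, match="multiplicative"):
        m2 = cg.fit_query_model([0.1, 0.2], [0.1, 0.2], min_points=30)
    assert m2.model_used == MULTIPLICATIVE


@pytest.fixture(scope="module")
def noiseless_records(small_design, small_truth):
    tensors = cg.simulate_counts(small_design, small_truth, analytic=True)
    fit = cg.FitnessTable.from_tensors(tensors, small_design, min_count=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, models = cg.gi_scores(fit, small_design, min_points=10)
    return records, models


def test_noiseless_null_scores_vanish(noiseless_records):
    records, models = noiseless_records
    assert (records["score"].abs() < 1e-9).all()
    assert all(m.model_used == LINEAR for m in models)


def test_residuals_sum_to_zero_per_query_condition(gi_records):
    sums = gi_records[gi_records["model_used"] == LINEAR].groupby(["query_id", "condition"])["score"].sum()
    assert (sums.abs() < 1e-9).all()


def test_suppressor_query_scores_positive(small_design):
    truth = cg.simulate_truth(small_design, suppressor_query="QGENE000_q1", seed=19)
    tensors = cg.simulate_counts(small_design, truth, analytic=True, conditions=["YPD24hr"], replicates=3)
    fit = cg.FitnessTable.from_tensors(tensors, small_design, min_count=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, _ = cg.gi_scores(fit, small_design, suppressor_queries={"QGENE000_q1"}, min_points=10)
    sup = records[records["query_id"] == "QGENE000_q1"]
    assert (sup["model_used"] == MULTIPLICATIVE).all()
    # defect rescue: strains whose starting guide has a fitness defect sit
    # above the multiplicative expectation
    w_a = truth.single_fitness["YPD24hr"].reindex(sup["guide_id"]).to_numpy()
    defect = w_a < 0.95
    assert defect.sum() > 10
    assert (sup["score"].to_numpy()[defect] > 0).all()
    assert sup["score"].mean() > 0


def test_injected_interaction_recovered(small_design):
    truth = cg.simulate_truth(small_design, gi_density=0.0, seed=23)
    gid, qid = "sg0000", "QGENE000_q1"
    truth.gi_effects = pd.DataFrame(
        {"eps": [0.2]},
        index=pd.MultiIndex.from_tuples([(gid, qid, "YPD24hr")], names=["guide_id", "query_id", "condition"]),
    )
    tensors = cg.simulate_counts(small_design, truth, analytic=True, conditions=["YPD24hr"], replicates=3)
    fit = cg.FitnessTable.from_tensors(tensors, small_design, min_count=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, _ = cg.gi_scores(fit, small_design, min_points=10)
    line = truth.query_lines.loc[(qid, "YPD24hr")]
    w_a = truth.single_fitness.loc[gid, "YPD24hr"]
    expected_score = 0.2 * (line["beta0"] + line["beta1"] * w_a)
    got = records.loc[f"{gid}:{qid}", "score"]
    assert got == pytest.approx(expected_score, abs=0.01)


def test_injected_interactions_called_with_high_sensitivity_low_fdr():
    """On a 200-guide x 5-query screen at depth 10^6, interactions injected
    well above the noise scale (6 sigma) are recovered at |z| > 2 with
    sensitivity >= 0.9 and FDR <= 0.1."""
    spec = cg.make_query_spec(n_targeting=5, n_genes=5, n_nontargeting=1, seed=31)
    design = cg.design_pool(200, 10, spec, holdout_fraction=0.0, guides_per_gene=1, seed=31)

    def run_screen(truth, sim_seed):
        tensors = cg.simulate_counts(design, truth, conditions=["YPD24hr"], replicates=3,
                                     depth=10**6, seed=sim_seed)
        fit = cg.FitnessTable.from_tensors(tensors, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records, _ = cg.gi_scores(fit, design)
        return cg.standardize_and_call(records)

    truth = cg.simulate_truth(design, gi_density=0.0, seed=32)
    sigma_noise = run_screen(truth, 33).attrs["sigma_global"]

    # inject |eps| = 6 sigma_noise (on the score scale) into 8% of pairs
    rng = np.random.default_rng(34)
    doubles = design.combos[design.combos["strain_class"] == cg.DOUBLE]
    hit = rng.random(len(doubles)) < 0.08
    lines = truth.query_lines.xs("YPD24hr", level="condition")
    rows = []
    for sid, row in doubles[hit].iterrows():
        w_a = truth.single_fitness.loc[row["guide_id"], "YPD24hr"]
        base = lines.loc[row["query_id"], "beta0"] + lines.loc[row["query_id"], "beta1"] * w_a
        sign = rng.choice([-1.0, 1.0])
        rows.append((row["guide_id"], row["query_id"], "YPD24hr", sign * 6 * sigma_noise / base))
    truth.gi_effects = pd.DataFrame(
        rows, columns=["guide_id", "query_id", "condition", "eps"]
    ).set_index(["guide_id", "query_id", "condition"])

    records = run_screen(truth, 33)
    key = pd.MultiIndex.from_arrays(
        [records["guide_id"], records["query_id"], records["condition"]]
    )
    is_true_gi = key.isin(truth.gi_effects.index)
    called = records["significant"].to_numpy()
    sensitivity = called[is_true_gi].mean()
    fdr = (~is_true_gi[called]).mean() if called.any() else 0.0
    assert sensitivity >= 0.9
    assert fdr <= 0.1


def test_standardize_hand_case_and_monotonicity():
    recs = pd.DataFrame({"score": [-1.0, 1.0], "condition": "c"})
    out = cg.standardize_and_call(recs, z_threshold=2)
    assert out.attrs["sigma_global"] == pytest.approx(np.sqrt(2))
    np.testing.assert_allclose(out["z"], [-0.7071067811865475, 0.7071067811865475])
    rng = np.random.default_rng(0)
    recs = pd.DataFrame({"score": rng.normal(0, 1, 500), "condition": "c"})
    n_sig = [
        cg.standardize_and_call(recs, z_threshold=zt)["significant"].sum() for zt in (1.0, 2.0, 3.0)
    ]
    assert n_sig[0] >= n_sig[1] >= n_sig[2]


def test_standardize_degenerate_sigma_raises():
    recs = pd.DataFrame({"score": [0.5, 0.5, 0.5], "condition": "c"})
    with pytest.raises(GIError, match="sigma"):
        cg.standardize_and_call(recs)


def _records_from_z(zmap):
    rows = []
    for (g, q), zs in zmap.items():
        for cond, z in zip("ABCDE", zs):
            rows.append((g, q, cond, z))
    df = pd.DataFrame(rows, columns=["guide_id", "query_id", "condition", "z"])
    df["score"] = df["z"]
    return df


@pytest.mark.parametrize(
    "zs,expected",
    [
        ((2.5, 0.2, 0.3, -0.5, 0.9), True),
        ((2.5, 1.5, 0.0, 0.0, 0.0), False),
        ((2.5, -2.5, 0.0, 0.0, 0.0), False),
        ((-2.1, 0.0, 0.0, 0.0, 0.0), True),
        ((2.0, 0.0, 0.0, 0.0, 0.0), False),  # exactly 2 is not > 2
    ],
)
def test_condition_specific_examples(zs, expected):
    recs = _records_from_z({("g", "q"): zs})
    flags = cg.classify_condition_specific(recs, conditions=list("ABCDE"))
    assert bool(flags.loc[("g", "q"), "condition_specific"]) is expected


def test_condition_specific_requires_all_conditions():
    recs = _records_from_z({("g", "q"): (2.5, 0.0, 0.0, 0.0, 0.0)})
    recs = recs[recs["condition"] != "E"]
    flags = cg.classify_condition_specific(recs, conditions=list("ABCDE"))
    assert not flags.loc[("g", "q"), "eligible"]
    assert not flags.loc[("g", "q"), "condition_specific"]


def test_gene_pair_aggregation_t_interval():
    recs = pd.DataFrame(
        {
            "gene_a": "GA",
            "gene_b": "GB",
            "condition": "c",
            "z": [2.0, 2.1, 1.9],
            "score": [0.2, 0.21, 0.19],
        }
    )
    out = cg.aggregate_gene_pairs(recs, min_strains=3)
    row = out.iloc[0]
    # Student-t interval: 2.0 +/- 4.3027 * 0.1 / sqrt(3)
    assert row["ci_low"] == pytest.approx(2.0 - 4.302652729911275 * 0.1 / np.sqrt(3), abs=1e-6)
    assert row["ci_high"] == pytest.approx(2.0 + 4.302652729911275 * 0.1 / np.sqrt(3), abs=1e-6)
    assert row["significant"]
    mixed = recs.assign(z=[1.5, -1.5, 0.0])
    assert not cg.aggregate_gene_pairs(mixed, min_strains=3)["significant"].iloc[0]
    assert cg.aggregate_gene_pairs(recs.iloc[:2], min_strains=3).empty


def test_compare_call_sets_contingency_and_hypergeometric():
    universe = {f"p{i}" for i in range(100)}
    calls = {(f"p{i}", -1) for i in range(10)}
    res = cg.compare_call_sets(calls, calls, universe)
    assert res["counts"]["both"] == 10
    assert res["p_overlap"]["negative"] == pytest.approx(
        hypergeom_upper_tail_oracle(10, 100, 10, 10), abs=1e-12
    )
    other = {(f"p{i}", -1) for i in range(10, 20)}
    res2 = cg.compare_call_sets(calls, other, universe)
    assert res2["counts"]["both"] == 0
    assert res2["p_overlap"]["negative"] > 0.6
    # partial overlap of 3 against the exact tail-sum oracle
    b = {(f"p{i}", -1) for i in range(7, 17)}
    res3 = cg.compare_call_sets(calls, b, universe)
    assert res3["counts"]["both"] == 3
    assert res3["p_overlap"]["negative"] == pytest.approx(
        hypergeom_upper_tail_oracle(3, 100, 10, 10), abs=1e-12
    )
    # sign switches are tracked
    flipped = {(f"p{i}", 1) for i in range(10)}
    res4 = cg.compare_call_sets(calls, flipped, universe)
    assert res4["counts"]["sign_switched"] == 10


def test_compare_call_sets_empty_universe():
    with pytest.raises(GIError):
        cg.compare_call_sets(set(), set(), set())


def test_condition_specific_matches_rule_on_sample_grid():
    rng = np.random.default_rng(1)
    grid = np.array([0.0, 0.9, -0.9, 1.1, -1.1, 2.1, -2.1])
    for _ in range(50):
        zs = tuple(rng.choice(grid, size=5))
        recs = _records_from_z({("g", "q"): zs})
        flags = cg.classify_condition_specific(recs, conditions=list("ABCDE"))
        assert bool(flags.loc[("g", "q"), "condition_specific"]) == condition_specific_oracle(zs)
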