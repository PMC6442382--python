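import warnings

import numpy as np
import pandas as pd
import pytest

import crisprgi as cg


@pytest.fixture(scope="session")
def small_design() -> cg.PoolDesign:
    """40 targeting + 4 control starting guides x (6 targeting over 3 genes
    + 2 nontargeting) queries, 5% of double combos held out."""
    spec = cg.make_query_spec(n_targeting=6, n_genes=3, n_nontargeting=2, seed=11)
    return cg.design_pool(40, 4, spec, holdout_fraction=0.05, guides_per_gene=2, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_design) -> cg.SimTruth:
    return cg.simulate_truth(small_design, gi_density=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_counts(small_design, small_truth):
    return cg.simulate_counts(small_design, small_truth, conditions=["YPD24hr"], replicates=1, analytic=True)


@pytest.fixture(scope="session")
def noisy_counts(small_design, small_truth):
    return cg.simulate_counts(small_design, small_truth, depth=200_000, seed=11)


@pytest.fixture(scope="session")
def fitness_table(small_design, noisy_counts) -> cg.FitnessTable:
    return cg.FitnessTable.from_tensors(noisy_counts, small_design)


@pytest.fixture(scope="session")
def gi_records(small_design, fitness_table) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, _ = cg.gi_scores(fitness_table, small_design, min_points=10)
    return cg.standardize_and_call(records)


def make_structured_profiles(
    n_genes: int = 40,
    guides_per_gene: int = 2,
    n_queries: int = 20,
    conditions=("c1", "c2", "c3", "c4", "c5"),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> cg.ProfileMatrix:
    """Profile fixture where guides targeting the same gene share a true GI
    vector plus independent noise — the regime in which profile similarity
    predicts shared gene targets."""
    rng = np.random.default_rng(seed)
    cols = pd.MultiIndex.from_product(
        [[f"q{j}" for j in range(n_queries)], list(conditions)], names=["query_id", "condition"]
    )
    rows, genes = [], []
    index = []
    for gidx in range(n_genes):
        truth = rng.normal(0, 1, size=len(cols))
        for k in range(guides_per_gene):
            rows.append(truth + rng.normal(0, noise_sd, size=len(cols)))
            genes.append(f"G{gidx:03d}")
            index.append(f"g{gidx:03d}_{k}")
    scores = pd.DataFrame(np.asarray(rows), index=index, columns=cols)
    genes = pd.Series(genes, index=index)
    bioproc = pd.Series([f"BP{int(g[1:]) % 5}" for g in genes], index=index)
    return cg.ProfileMatrix(scores, genes, bioproc)
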