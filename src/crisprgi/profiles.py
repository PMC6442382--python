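"""GI-profile similarity and functional classification.

A starting-pool guide's GI profile is its vector of interaction scores
across the query guides, concatenated over growth conditions. Guides
targeting the same gene (or the same GO-Slim bioprocess) have correlated
profiles, so profile similarity — Spearman's rho on pairwise-complete
entries — predicts shared function. Classification power is quantified with
ROC curves over a fixed grid of rho thresholds (-1 to 1, step 0.05; trapezoid
AUC), precision-recall curves, per-column permutation nulls, and subset
analyses over conditions or random sets of query measurements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import PoolDesign

DEFAULT_THRESHOLDS = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.05), 10)


class ProfileError(ValueError):
    pass


@dataclass
class ProfileMatrix:
    """Rows = starting-pool guides; columns = (query guide, condition)
    measurements; entries = GI scores with NaN for strain dropout."""

    scores: pd.DataFrame  # MultiIndex columns (query_id, condition)
    row_genes: pd.Series
    row_bioprocess: pd.Series

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.scores.columns.get_level_values("condition")))

    @property
    def queries(self) -> list[str]:
        return sorted(set(self.scores.columns.get_level_values("query_id")))

    def missing_fraction(self) -> pd.Series:
        return self.scores.isna().mean(axis=1)

    def subset(self, conditions=None, queries=None) -> "ProfileMatrix":
        df = self.scores
        if conditions is not None:
            keep = df.columns.get_level_values("condition").isin(conditions)
            df = df.loc[:, keep]
        if queries is not None:
            keep = df.columns.get_level_values("query_id").isin(queries)
            df = df.loc[:, keep]
        if df.shape[1] == 0:
            raise ProfileError("empty column subset")
        return ProfileMatrix(df, self.row_genes, self.row_bioprocess)

    def subset_columns(self, columns) -> "ProfileMatrix":
        return ProfileMatrix(self.scores.loc[:, columns], self.row_genes, self.row_bioprocess)


def build_profiles(
    records: pd.DataFrame,
    design: PoolDesign,
    conditions: list[str] | None = None,
    queries: list[str] | None = None,
) -> ProfileMatrix:
    """Pivot GI records into a profile matrix, restricted to the chosen
    conditions/queries; missingness is preserved. Column order is
    deterministic (sorted query, then condition)."""
    df = records
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    if queries is not None:
        df = df[df["query_id"].isin(queries)]
    if df.empty:
        raise ProfileError("no records in the requested subset")
    mat = df.pivot_table(index="guide_id", columns=["query_id", "condition"], values="score")
    mat = mat.sort_index(axis=1)
    mat.columns = mat.columns.set_names(["query_id", "condition"])
    genes = design.starting["target_gene"].reindex(mat.index)
    bioproc = design.starting["bioprocess"].reindex(mat.index)
    return ProfileMatrix(mat, genes, bioproc)


def profile_correlations(profiles: ProfileMatrix | pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rho between guide profiles using pairwise-complete
    observations (midranks for ties); pairs sharing fewer than
    ``min_overlap`` measured entries are left missing."""
    if min_overlap < 3:
        raise ProfileError("min_overlap must be >= 3")
    df = profiles.scores if isinstance(profiles, ProfileMatrix) else profiles
    return df.T.corr(method="spearman", min_periods=min_overlap)


def pair_table(pm: ProfileMatrix, rhos: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangle pair list with rho and pair class (same_gene /
    same_bioprocess / different)."""
    guides = list(rhos.index)
    genes = pm.row_genes.reindex(guides).to_numpy()
    bio = pm.row_bioprocess.reindex(guides).to_numpy()
    iu, ju = np.triu_indices(len(guides), k=1)
    same_gene = genes[iu] == genes[ju]
    same_bio = (bio[iu] == bio[ju]) & ~same_gene
    cls = np.where(same_gene, "same_gene", np.where(same_bio, "same_bioprocess", "different"))
    return pd.DataFrame(
        {
            "guide_a": np.asarray(guides)[iu],
            "guide_b": np.asarray(guides)[ju],
            "rho": rhos.to_numpy()[iu, ju],
            "pair_class": cls,
            "same_gene": same_gene,
        }
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    auc_roc: float
    auc_pr: float
    n_pos: int
    n_neg: int
    subset: str = ""
    permuted: bool = False
    extras: dict = field(default_factory=dict)


def roc_curve(
    rhos, labels, thresholds: np.ndarray | None = None, subset: str = "", permuted: bool = False
) -> ROCResult:
    """Threshold sweep over similarity values.

    At each threshold theta (a call is rho >= theta): TPR = fraction of
    positive pairs called, FPR = fraction of negative pairs called,
    precision = TP/(TP+FP) (NaN when nothing is called). AUC_roc is the
    trapezoid integral of TPR over FPR; AUC_pr of precision over recall
    (defined points only). Missing rho values are excluded.
    """
    rhos = np.asarray(rhos, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = np.isfinite(rhos)
    rhos, labels = rhos[keep], labels[keep]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ProfileError("need at least one positive and one negative pair")
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    pos = np.sort(rhos[labels])
    neg = np.sort(rhos[~labels])
    # counts >= theta via searchsorted on sorted arrays
    tp = n_pos - np.searchsorted(pos, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg, thresholds, side="left")
    tpr = tp / n_pos
    fpr = fp / n_neg
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
    # sweep from high to low threshold: FPR and TPR are then non-decreasing,
    # which is the correct traversal order for the trapezoid rule (sorting by
    # FPR alone would scramble vertical segments of the staircase)
    auc_roc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    ok = np.isfinite(precision)[::-1]
    rec = tpr[::-1][ok]
    prec = precision[::-1][ok]
    auc_pr = float(np.trapezoid(prec, rec)) if ok.sum() >= 2 else float("nan")
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        auc_roc=auc_roc,
        auc_pr=auc_pr,
        n_pos=n_pos,
        n_neg=n_neg,
        subset=subset,
        permuted=permuted,
    )


def classification_roc(
    pm: ProfileMatrix,
    min_overlap: int = 3,
    thresholds: np.ndarray | None = None,
    positive: str = "same_gene",
    subset: str = "",
    permuted: bool = False,
) -> ROCResult:
    """Correlate profiles, label pairs, sweep thresholds. The negative class
    is every non-same-gene pair (same-bioprocess pairs included)."""
    rhos = profile_correlations(pm, min_overlap=min_overlap)
    pairs = pair_table(pm, rhos)
    return roc_curve(
        pairs["rho"], pairs[positive] if positive in pairs else pairs["pair_class"] == positive,
        thresholds=thresholds, subset=subset, permuted=permuted,
    )


def permute_profiles(pm: ProfileMatrix, seed: int = 0) -> ProfileMatrix:
    """Independently permute each column's entries across rows (missing
    values travel with the permutation); row labels stay put. Destroys
    profile structure while preserving every column's score distribution."""
    rng = np.random.default_rng(seed)
    arr = pm.scores.to_numpy().copy()
    for j in range(arr.shape[1]):
        arr[:, j] = arr[rng.permutation(arr.shape[0]), j]
    return ProfileMatrix(
        pd.DataFrame(arr, index=pm.scores.index, columns=pm.scores.columns),
        pm.row_genes,
        pm.row_bioprocess,
    )


def subset_analysis(
    pm: ProfileMatrix,
    mode: str = "conditions",
    sizes: list[int] | None = None,
    reps: int = 8,
    seed: int = 0,
    min_overlap: int = 3,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Classification AUC across data subsets.

    mode='conditions': every subset of conditions of each requested size is
    enumerated (all queries kept). mode='query_measurements': ``reps``
    random samples of ``size`` (query, condition) columns per size. Returns
    one row per evaluated subset with auc_roc and auc_pr."""
    rng = np.random.default_rng(seed)
    rows = []
    if mode == "conditions":
        conds = pm.conditions
        sizes = sizes or list(range(1, len(conds) + 1))
        for size in sizes:
            if size > len(conds):
                raise ProfileError(f"size {size} exceeds available conditions ({len(conds)})")
            for combo in itertools.combinations(conds, size):
                res = classification_roc(
                    pm.subset(conditions=list(combo)),
                    min_overlap=min_overlap,
                    thresholds=thresholds,
                    subset=",".join(combo),
                )
                rows.append((size, ",".join(combo), 0, res.auc_roc, res.auc_pr, res.n_pos, res.n_neg))
    elif mode == "query_measurements":
        cols = list(pm.scores.columns)
        sizes = sizes or [20, 40, 60, 80]
        for size in sizes:
            if size > len(cols):
                raise ProfileError(f"size {size} exceeds available columns ({len(cols)})")
            for rep in range(reps):
                pick = rng.choice(len(cols), size=size, replace=False)
                sub = pm.subset_columns([cols[i] for i in sorted(pick)])
                res = classification_roc(
                    sub, min_overlap=min_overlap, thresholds=thresholds, subset=f"sample{rep}"
                )
                rows.append((size, f"sample{rep}", rep, res.auc_roc, res.auc_pr, res.n_pos, res.n_neg))
    else:
        raise ProfileError(f"unknown mode: {mode!r}")
    return pd.DataFrame(
        rows, columns=["size", "subset", "rep", "auc_roc", "auc_pr", "n_pos", "n_neg"]
    )


def enrichment_test(hit_set: set, annotation_set: set, universe: set) -> float:
    """Upper-tail hypergeometric probability of the observed overlap between
    a hit list and an annotation set drawn from a common universe."""
    if not universe:
        raise ProfileError("empty universe")
    if not set(hit_set) <= set(universe) or not set(annotation_set) <= set(universe):
        raise ProfileError("hit/annotation sets must be subsets of the universe")
    k = len(set(hit_set) & set(annotation_set))
    return float(stats.hypergeom.sf(k - 1, len(universe), len(annotation_set), len(hit_set)))
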