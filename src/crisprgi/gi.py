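"""Genetic-interaction scores for guide pairs.

The classical expectation for a double mutant is multiplicative,
E[w_ab] = w_a * w_b. Pooled double-CRISPRi data show a positive bias from
that expectation (partial knockdowns compete for dCas9), so under the
assumption that most pairs do not interact the expectation is re-estimated
empirically: for each query guide and condition, observed double-mutant
fitness is regressed (OLS) on the starting-guide single-mutant fitness, and
the residual is the GI score. Suppressor-like queries (e.g. a knockdown that
globally alleviates other defects, breaking the linear fit) instead use the
multiplicative expectation. Scores are standardized by one global standard
deviation pooled over all guide pairs in all conditions; |z| > 2 calls
significance, and a GI is condition-specific when |z| > 2 in exactly one
condition and |z| < 1 in all others.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DOUBLE, PoolDesign
from .fitness import FitnessTable

logger = logging.getLogger(__name__)

LINEAR = "linear"
MULTIPLICATIVE = "multiplicative"


class GIError(ValueError):
    pass


def expected_multiplicative(w_a, w_b):
    """Multiplicative double-mutant expectation w_a * w_b."""
    return np.asarray(w_a) * np.asarray(w_b) if np.ndim(w_a) or np.ndim(w_b) else w_a * w_b


@dataclass
class QueryModel:
    query_id: str
    condition: str
    beta0: float
    beta1: float
    n: int
    model_used: str
    r_squared: float = float("nan")


def fit_query_model(
    x, y, query_id: str = "", condition: str = "", min_points: int = 30
) -> QueryModel:
    """OLS of double-mutant fitness (y) on starting-guide single fitness (x)
    for one query x condition. Falls back to the multiplicative model (slope
    = mean(y/x) through the origin is NOT used; the caller switches to
    w_a * w_q) when there are too few points or x is degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_points or np.ptp(x) < 1e-12:
        warnings.warn(
            f"query {query_id}/{condition}: {n} points or degenerate spread; "
            "falling back to multiplicative expectation",
            stacklevel=2,
        )
        return QueryModel(query_id, condition, float("nan"), float("nan"), n, MULTIPLICATIVE)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    beta1 = float(((x - xbar) * (y - ybar)).sum()) / sxx
    beta0 = ybar - beta1 * xbar
    resid = y - (beta0 + beta1 * x)
    tss = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else float("nan")
    return QueryModel(query_id, condition, float(beta0), beta1, n, LINEAR, r2)


def _lack_of_fit_warning(model: QueryModel, r2_floor: float = 0.1) -> None:
    # advisory only: a suppressor-like query shows poor fit / shallow slope
    if model.model_used == LINEAR and (model.r_squared < r2_floor or model.beta1 < 0):
        logger.warning(
            "query %s/%s: linear expectation fits poorly (R^2=%.3f, slope=%.3f); "
            "consider listing it as a suppressor query",
            model.query_id,
            model.condition,
            model.r_squared,
            model.beta1,
        )


def gi_scores(
    fit: FitnessTable,
    design: PoolDesign,
    suppressor_queries: set[str] | None = None,
    min_points: int = 30,
) -> tuple[pd.DataFrame, list[QueryModel]]:
    """GI score records for every measurable double-knockdown strain.

    score = w_ab - expected, with expected from the per-query linear model,
    or from the multiplicative model for queries listed in
    ``suppressor_queries``. Records missing the double or the starting-guide
    single fitness are dropped (reason logged).
    """
    suppressor_queries = suppressor_queries or set()
    unknown = suppressor_queries - set(design.queries.index)
    if unknown:
        raise GIError(f"suppressor_queries not in design: {sorted(unknown)}")
    genes = design.combo_genes()
    doubles = genes[(genes["strain_class"] == DOUBLE) & genes["present"]]
    agg = fit.aggregated
    singles = fit.singles

    records = []
    models: list[QueryModel] = []
    for cond, cond_fit in agg.groupby("condition"):
        ok = cond_fit[cond_fit["measurable"]]["w_mean"]
        sub = doubles.join(ok.rename("w_ab"), how="inner")
        try:
            s_start = singles.xs(("starting", cond), level=("role", "condition"))["w"]
        except KeyError:
            s_start = pd.Series(dtype=float)
        try:
            s_query = singles.xs(("query", cond), level=("role", "condition"))["w"]
        except KeyError:
            s_query = pd.Series(dtype=float)
        sub = sub.assign(
            w_a=s_start.reindex(sub["guide_id"]).to_numpy(),
            w_q=s_query.reindex(sub["query_id"]).to_numpy(),
        )
        n_drop = int(sub["w_a"].isna().sum())
        if n_drop:
            logger.info("%s: dropped %d records lacking a starting-guide single fitness", cond, n_drop)
        sub = sub.dropna(subset=["w_a"])
        for qid, qgrp in sub.groupby("query_id"):
            if qid in suppressor_queries:
                if qgrp["w_q"].isna().any():
                    logger.info("%s/%s: dropped records lacking query single fitness", cond, qid)
                    qgrp = qgrp.dropna(subset=["w_q"])
                expected = qgrp["w_a"].to_numpy() * qgrp["w_q"].to_numpy()
                model = QueryModel(qid, cond, float("nan"), float("nan"), len(qgrp), MULTIPLICATIVE)
            else:
                model = fit_query_model(
                    qgrp["w_a"], qgrp["w_ab"], query_id=qid, condition=cond, min_points=min_points
                )
                _lack_of_fit_warning(model)
                if model.model_used == LINEAR:
                    expected = model.beta0 + model.beta1 * qgrp["w_a"].to_numpy()
                else:
                    qgrp = qgrp.dropna(subset=["w_q"])
                    expected = qgrp["w_a"].to_numpy() * qgrp["w_q"].to_numpy()
            models.append(model)
            rec = qgrp[["guide_id", "query_id", "gene_a", "gene_b"]].copy()
            rec["condition"] = cond
            rec["w_ab"] = qgrp["w_ab"]
            rec["expected"] = expected
            rec["score"] = rec["w_ab"] - rec["expected"]
            rec["model_used"] = model.model_used
            records.append(rec)
    if not records:
        raise GIError("no GI records could be computed")
    out = pd.concat(records)
    out.index.name = "strain_id"
    return out, models


def standardize_and_call(
    records: pd.DataFrame, z_threshold: float = 2.0, center: str = "zero"
) -> pd.DataFrame:
    """Global-SD z-scores and significance calls.

    sigma_global is the standard deviation (ddof=1) of scores pooled over
    ALL guide pairs in ALL conditions; z = (score - mu)/sigma with mu = 0 by
    default (linear residuals are centered by construction) or the global
    mean with ``center='mean'``. significant <=> |z| > z_threshold.
    """
    if len(records) < 2:
        raise GIError("need at least 2 records to standardize")
    scores = records["score"].to_numpy(dtype=float)
    sigma = float(np.std(scores, ddof=1))
    if sigma == 0:
        raise GIError("degenerate score distribution: sigma_global = 0")
    mu = float(np.mean(scores)) if center == "mean" else 0.0
    out = records.copy()
    out["z"] = (out["score"] - mu) / sigma
    out["significant"] = out["z"].abs() > z_threshold
    out.attrs["sigma_global"] = sigma
    out.attrs["z_threshold"] = z_threshold
    return out


def classify_condition_specific(
    records: pd.DataFrame,
    conditions: list[str] | None = None,
    outer_threshold: float = 2.0,
    inner_threshold: float = 1.0,
) -> pd.DataFrame:
    """Condition-specificity per guide pair: |z| > 2 in exactly one condition
    and |z| < 1 in every other. Pairs lacking a z in any of ``conditions``
    are ineligible (flag NA-like False with eligible=False)."""
    conds = conditions or sorted(records["condition"].unique())
    z = records.pivot_table(index=["guide_id", "query_id"], columns="condition", values="z")
    z = z.reindex(columns=conds)
    eligible = z.notna().all(axis=1)
    absz = z.abs()
    n_outer = (absz > outer_threshold).sum(axis=1)
    inner_ok = ((absz < inner_threshold) | (absz > outer_threshold)).all(axis=1)
    specific = eligible & (n_outer == 1) & inner_ok
    which = pd.Series(pd.NA, index=z.index, dtype=object)
    if specific.any():
        which[specific] = absz[specific].idxmax(axis=1)
    out = pd.DataFrame(
        {"eligible": eligible, "condition_specific": specific, "specific_condition": which}
    )
    return out


def annotate_condition_specific(records: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Mark each record as the condition-specific call of its pair."""
    key = pd.MultiIndex.from_frame(records[["guide_id", "query_id"]])
    spec_cond = flags["specific_condition"].reindex(key).fillna("").to_numpy(dtype=object)
    out = records.copy()
    out["condition_specific"] = out["condition"].to_numpy(dtype=object) == spec_cond
    return out


def aggregate_gene_pairs(
    records: pd.DataFrame,
    min_strains: int = 3,
    inner_threshold: float = 1.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Gene-pair GI per condition from replicate strains (distinct guide
    combinations targeting the same two genes): mean z, Student-t CI on the
    mean, significant iff the CI lies entirely outside [-inner, +inner]."""
    recs = records.copy()
    pair = [tuple(sorted(p)) for p in zip(recs["gene_a"], recs["gene_b"])]
    recs["gene_pair"] = pair
    rows = []
    for (gp, cond), grp in recs.groupby(["gene_pair", "condition"]):
        z = grp["z"].to_numpy(dtype=float)
        n = len(z)
        if n < min_strains:
            continue
        mean = float(z.mean())
        sd = float(z.std(ddof=1))
        tcrit = float(stats.t.ppf(0.5 + ci_level / 2, n - 1))
        half = tcrit * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
        sig = lo > inner_threshold or hi < -inner_threshold
        rows.append((gp[0], gp[1], cond, mean, n, lo, hi, sig))
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "condition", "mean_z", "n_strains", "ci_low", "ci_high", "significant"],
    )


def compare_call_sets(
    calls_a: set[tuple], calls_b: set[tuple], universe: set
) -> dict:
    """Overlap of two signed call sets over a shared universe of gene pairs.

    Each call is (gene_pair, sign) with sign in {+1, -1}. Returns the
    contingency counts and, per sign, the one-sided hypergeometric
    probability of an overlap at least as large as observed.
    """
    if not universe:
        raise GIError("empty universe")
    pairs_a = {p for p, _ in calls_a}
    pairs_b = {p for p, _ in calls_b}
    if not pairs_a <= universe or not pairs_b <= universe:
        raise GIError("call sets must be subsets of the universe")
    sign_a = {p: s for p, s in calls_a}
    sign_b = {p: s for p, s in calls_b}
    both = pairs_a & pairs_b
    switched = {p for p in both if sign_a[p] != sign_b[p]}
    counts = {
        "both": len(both),
        "a_only": len(pairs_a - pairs_b),
        "b_only": len(pairs_b - pairs_a),
        "neither": len(universe) - len(pairs_a | pairs_b),
        "sign_switched": len(switched),
    }
    pvals = {}
    M = len(universe)
    for sign, label in ((1, "positive"), (-1, "negative")):
        a_s = {p for p, s in calls_a if s == sign}
        b_s = {p for p, s in calls_b if s == sign}
        k = len(a_s & b_s)
        pvals[label] = float(stats.hypergeom.sf(k - 1, M, len(a_s), len(b_s)))
    return {"counts": counts, "p_overlap": pvals}
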