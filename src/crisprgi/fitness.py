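"""Relative fitness from pooled count trajectories.

A strain with per-generation relative fitness w changes its (log) pool
frequency linearly in generations: ln f_i(g) = const + g * ln w_i - ln Z(g),
with Z the pool normalizer. Regressing ln(f_i / f_ctrl) on generations —
where f_ctrl is the pooled frequency of the no-knockdown control strains
(true w = 1) — cancels Z exactly, so the least-squares slope is ln w_i and
fitness is anchored at wildtype = 1 (as the multiplicative GI expectation
requires). Both trajectories are evaluated on the strain's own usable
timepoints, so the cancellation holds for any timepoint subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountTensor
from .design import NONE_CLASS, NONTARGETING, SINGLE, PoolDesign


class FitnessError(ValueError):
    pass


def normalize_frequencies(tensor: CountTensor) -> pd.DataFrame:
    """Counts -> relative frequencies; columns sum to 1. No pseudocounts:
    zero counts give zero frequency."""
    totals = tensor.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise FitnessError(
            f"all-zero timepoint(s) {list(zero.index)} in sample {tensor.sample_name}"
        )
    return tensor.counts / totals


def _masked_slopes(y: np.ndarray, g: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rowwise OLS slope of y on g using only masked entries; returns
    (slopes, n_used). Rows with < 2 usable points get NaN."""
    m = mask.astype(float)
    n = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ym = np.where(mask, y, 0.0)
        gbar = (m * g).sum(axis=1) / n
        ybar = ym.sum(axis=1) / n
        dg = (g[None, :] - gbar[:, None]) * m
        dy = (ym - ybar[:, None] * m) * m
        sxx = (dg * dg).sum(axis=1)
        slope = (dg * dy).sum(axis=1) / sxx
    slope[(n < 2) | ~np.isfinite(slope)] = np.nan
    return slope, n.astype(int)


def estimate_fitness(
    tensor: CountTensor,
    design: PoolDesign,
    control_ids: set[str] | None = None,
    min_count: float = 10,
) -> pd.DataFrame:
    """Per-replicate fitness for one condition x replicate sample.

    Timepoints where a strain's count falls below ``min_count`` are dropped
    for that strain; strains with fewer than two usable timepoints, or below
    ``min_count`` at t0, are flagged unmeasurable (low relative frequency).
    The reference is the summed trajectory of the no-knockdown control
    strains; w = exp(slope of ln(f_strain / f_ctrl) over generations).
    """
    if control_ids is None:
        control_ids = set(
            design.combos.index[(design.combos["strain_class"] == NONE_CLASS) & design.combos["present"]]
        )
    if not control_ids:
        raise FitnessError("control_ids is empty: no no-knockdown reference strains")
    freq = normalize_frequencies(tensor)
    g = tensor.generations
    ctrl_rows = freq.index.intersection(sorted(control_ids))
    ctrl_freq = freq.loc[ctrl_rows].sum(axis=0).to_numpy()
    ctrl_count = tensor.counts.loc[ctrl_rows].sum(axis=0).to_numpy()
    ctrl_ok = ctrl_count >= max(min_count, np.finfo(float).tiny)
    if ctrl_ok.sum() < 2 or not ctrl_ok[0]:
        raise FitnessError(f"control trajectory unmeasurable in sample {tensor.sample_name}")

    ids = design.strain_ids(present_only=True)
    counts = tensor.counts.loc[ids].to_numpy(dtype=float)
    f = freq.loc[ids].to_numpy(dtype=float)
    usable = (counts >= max(min_count, np.finfo(float).tiny)) & ctrl_ok[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(np.where(usable, f, np.nan) / ctrl_freq[None, :])
    slope, n_used = _masked_slopes(np.nan_to_num(y, nan=0.0), g, usable)
    measurable = usable[:, 0] & (n_used >= 2) & np.isfinite(slope)
    w = np.where(measurable, np.exp(slope), np.nan)
    return pd.DataFrame(
        {
            "condition": tensor.condition,
            "replicate": tensor.replicate,
            "w": w,
            "n_timepoints": n_used,
            "measurable": measurable,
        },
        index=ids,
    )


def aggregate_replicates(per_rep: pd.DataFrame, required: int = 3) -> pd.DataFrame:
    """Replicate-mean fitness per strain x condition. A strain must be
    measurable in all ``required`` replicates to keep a mean (the flag and
    per-replicate values are retained either way)."""
    out = []
    for (cond,), grp in per_rep.groupby(["condition"]):
        ok = grp[grp["measurable"]]
        stats = ok.groupby(level=0)["w"].agg(["mean", "std", "count"])
        stats = stats.reindex(grp.index.unique())
        measurable = stats["count"].fillna(0).astype(int) >= required
        out.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "w_mean": stats["mean"].where(measurable),
                    "w_sd": stats["std"].where(measurable),
                    "n_replicates": stats["count"].fillna(0).astype(int),
                    "measurable": measurable,
                },
                index=stats.index,
            )
        )
    return pd.concat(out)


def single_mutant_fitness(agg: pd.DataFrame, design: PoolDesign) -> pd.DataFrame:
    """Per-guide single-knockdown fitness per condition, averaged over the
    replicate single-knockdown control strains that carry the guide.

    Returns rows keyed by (role, guide id, condition) where role is
    'starting' (guide paired with a nontargeting query) or 'query' (guide
    delivered on a plasmid into a nontargeting starting strain)."""
    genes = design.combo_genes()
    singles = genes[(genes["strain_class"] == SINGLE) & genes["present"]]
    rows = []
    for cond, grp in agg.groupby("condition"):
        ok = grp[grp["measurable"]]
        sub = singles.join(ok["w_mean"], how="inner").dropna(subset=["w_mean"])
        from_starting = sub[sub["gene_b"] == NONTARGETING]
        by_guide = from_starting.groupby("guide_id")["w_mean"].agg(["mean", "count"])
        for gid, r in by_guide.iterrows():
            rows.append(("starting", gid, cond, r["mean"], int(r["count"])))
        from_query = sub[sub["gene_a"] == NONTARGETING]
        by_query = from_query.groupby("query_id")["w_mean"].agg(["mean", "count"])
        for qid, r in by_query.iterrows():
            rows.append(("query", qid, cond, r["mean"], int(r["count"])))
    return pd.DataFrame(rows, columns=["role", "id", "condition", "w", "n_strains"]).set_index(
        ["role", "id", "condition"]
    )


@dataclass
class FitnessTable:
    """Bundle of per-replicate and aggregated fitness plus singles."""

    per_replicate: pd.DataFrame
    aggregated: pd.DataFrame
    singles: pd.DataFrame

    @classmethod
    def from_tensors(
        cls,
        tensors: list[CountTensor],
        design: PoolDesign,
        min_count: float = 10,
        required_replicates: int = 3,
    ) -> "FitnessTable":
        per_rep = pd.concat([estimate_fitness(t, design, min_count=min_count) for t in tensors])
        agg = aggregate_replicates(per_rep, required=required_replicates)
        singles = single_mutant_fitness(agg, design)
        return cls(per_replicate=per_rep, aggregated=agg, singles=singles)


def write_fitness_tsv(table: FitnessTable, path) -> None:
    wide = table.per_replicate.reset_index(names="strain_id").pivot_table(
        index=["strain_id", "condition"], columns="replicate", values="w"
    )
    wide.columns = [f"w_rep{r}" for r in wide.columns]
    merged = wide.join(table.aggregated.reset_index(names="strain_id").set_index(["strain_id", "condition"]))
    merged.to_csv(path, sep="\t")
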