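"""GI-profile correlation networks and condition-specific GI networks.

Profile networks connect starting-pool guides whose GI-profile Spearman rho
passes a threshold chosen so that fewer than a target fraction (default
0.5%) of guide pairs with *different* gene and bioprocess targets pass —
an empirical false-edge control. Guides with more than 25% missing profile
entries (strain dropout) are removed before thresholding. Condition GI
networks are bipartite query x starting-guide graphs of significant
interactions, annotated with sign and condition specificity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .profiles import ProfileMatrix, pair_table, profile_correlations

DEFAULT_GRID = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.01), 10)


class NetworkError(ValueError):
    pass


def select_threshold(
    rhos: pd.DataFrame | np.ndarray,
    different_mask: np.ndarray,
    max_fpr: float = 0.005,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Smallest grid threshold theta such that the fraction of
    different-target pairs with rho >= theta is below ``max_fpr``.

    ``rhos``/``different_mask`` are aligned 1-D arrays over pairs (use
    :func:`pair_table`). Returns (theta, achieved_rate). If max_fpr >= 1 the
    grid minimum is returned (every pair may pass)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rho = np.asarray(rhos, dtype=float)
    mask = np.asarray(different_mask, dtype=bool)
    diff = rho[mask & np.isfinite(rho)]
    if len(diff) == 0:
        raise NetworkError("no different-target pair with a non-missing rho")
    if max_fpr >= 1.0:
        theta = float(grid.min())
        return theta, float(np.mean(diff >= theta))
    diff_sorted = np.sort(diff)
    n = len(diff_sorted)
    frac = (n - np.searchsorted(diff_sorted, grid, side="left")) / n
    ok = np.nonzero(frac < max_fpr)[0]
    if len(ok) == 0:
        raise NetworkError(f"no grid threshold achieves different-target rate < {max_fpr}")
    theta = float(grid[ok[0]])
    return theta, float(frac[ok[0]])


def build_network(
    pm: ProfileMatrix,
    rhos: pd.DataFrame | None = None,
    theta: float | None = None,
    max_fpr: float = 0.005,
    max_missing: float = 0.25,
    min_overlap: int = 3,
    grid: np.ndarray | None = None,
) -> nx.Graph:
    """Profile-similarity network.

    Guides whose missing-entry fraction exceeds ``max_missing`` are dropped
    first; correlations are then computed (or taken from ``rhos``), the
    threshold chosen by :func:`select_threshold` unless given, and edges
    added for pairs with rho >= theta. Node attributes carry target gene,
    bioprocess and missingness; edge attributes rho and edge class; graph
    attributes the threshold and achieved different-target edge rate."""
    missing = pm.missing_fraction()
    keep = missing[missing <= max_missing].index
    sub = ProfileMatrix(pm.scores.loc[keep], pm.row_genes.loc[keep], pm.row_bioprocess.loc[keep])
    if rhos is None:
        rhos = profile_correlations(sub, min_overlap=min_overlap)
    else:
        rhos = rhos.loc[keep, keep]
    pairs = pair_table(sub, rhos)
    different = (pairs["pair_class"] == "different").to_numpy()
    if theta is None:
        theta, achieved = select_threshold(pairs["rho"], different, max_fpr=max_fpr, grid=grid)
    else:
        diff_rho = pairs.loc[different, "rho"].dropna()
        achieved = float((diff_rho >= theta).mean()) if len(diff_rho) else float("nan")

    g = nx.Graph(threshold=theta, achieved_different_rate=achieved, max_fpr=max_fpr)
    for gid in keep:
        g.add_node(
            gid,
            target_gene=str(pm.row_genes.get(gid, "")),
            bioprocess=str(pm.row_bioprocess.get(gid, "")),
            missing_fraction=float(missing[gid]),
        )
    hits = pairs[(pairs["rho"] >= theta) & pairs["rho"].notna()]
    for _, row in hits.iterrows():
        g.add_edge(row["guide_a"], row["guide_b"], rho=float(row["rho"]), edge_class=row["pair_class"])
    return g


def condition_gi_network(records: pd.DataFrame) -> nx.Graph:
    """Bipartite network of significant GIs: query guides x starting guides,
    one edge per significant record, with sign, condition and (when present)
    the condition-specific flag."""
    if "significant" not in records:
        raise NetworkError("records must be standardized (run standardize_and_call first)")
    g = nx.MultiGraph()  # a pair can interact in several conditions
    sig = records[records["significant"]]
    for _, row in sig.iterrows():
        u = f"start:{row['guide_id']}"
        v = f"query:{row['query_id']}"
        g.add_node(u, bipartite=0, gene=str(row["gene_a"]))
        g.add_node(v, bipartite=1, gene=str(row["gene_b"]))
        g.add_edge(
            u,
            v,
            condition=row["condition"],
            sign=int(np.sign(row["score"])),
            z=float(row["z"]),
            condition_specific=bool(row.get("condition_specific", False)),
        )
    return g


def write_network(g: nx.Graph, graphml_path=None, edgelist_path=None, nodes_path=None) -> None:
    """GraphML + TSV exports (layout is left to viewers)."""
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        rows = [{"source": u, "target": v, **d} for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows).to_csv(edgelist_path, sep="\t", index=False)
    if nodes_path is not None:
        rows = [{"node": n, **d} for n, d in g.nodes(data=True)]
        pd.DataFrame(rows).to_csv(nodes_path, sep="\t", index=False)
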