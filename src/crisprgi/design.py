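"""Pool designs for double-CRISPRi genetic-interaction screens.

A screen combines a *starting pool* of genomically integrated guides (each
strain carries one gRNA at a fixed locus) with barcoded *query* plasmids that
integrate a second gRNA plus a unique 25-nt DNA barcode. Every strain is then
identified by the (starting guide, query barcode) amplicon. Crucially, not
every guide x barcode combination is constructed: intentionally absent
combinations provide a null against which PCR chimeras can be quantified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NONTARGETING = "NONTARGETING"

GUIDE_LEN = 20
BARCODE_LEN = 25

DOUBLE = "double_knockdown"
SINGLE = "single_knockdown_control"
NONE_CLASS = "no_knockdown_control"


class DesignError(ValueError):
    """Raised for invalid pool designs (e.g. duplicated barcodes)."""


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random DNA sequences of a fixed length."""
    seqs: list[str] = []
    seen: set[str] = set()
    bases = np.array(list("ACGT"))
    while len(seqs) < n:
        s = "".join(bases[rng.integers(0, 4, size=length)])
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def strain_id(guide_id: str, query_id: str) -> str:
    return f"{guide_id}:{query_id}"


@dataclass
class PoolDesign:
    """Annotation of a double-CRISPRi pool.

    Attributes
    ----------
    starting : DataFrame indexed by guide_id with columns
        ``target_gene`` (``NONTARGETING`` for controls), ``bioprocess``,
        ``guide_seq`` (20 nt).
    queries : DataFrame indexed by query_id with columns ``target_gene``,
        ``bioprocess``, ``barcode`` (25 nt, unique), ``guide_seq``.
    combos : DataFrame indexed by strain_id with columns ``guide_id``,
        ``query_id``, ``strain_class``, ``present``. Rows with
        ``present=False`` are intentionally absent combinations used for
        chimera quantification.
    """

    starting: pd.DataFrame
    queries: pd.DataFrame
    combos: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = self.queries["barcode"][self.queries["barcode"].duplicated()]
        if len(dup):
            raise DesignError(f"duplicate query barcode(s): {sorted(set(dup))}")
        bad = set(self.combos["guide_id"]) - set(self.starting.index)
        bad |= set(self.combos["query_id"]) - set(self.queries.index)
        if bad:
            raise DesignError(f"combos reference unknown guides/queries: {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    @property
    def present_combos(self) -> pd.DataFrame:
        return self.combos[self.combos["present"]]

    @property
    def absent_combos(self) -> pd.DataFrame:
        return self.combos[~self.combos["present"]]

    def strain_ids(self, present_only: bool = True) -> pd.Index:
        return (self.present_combos if present_only else self.combos).index

    def combo_genes(self) -> pd.DataFrame:
        """Per-combo gene/bioprocess annotation (gene_a from the starting
        guide, gene_b from the query guide)."""
        out = self.combos.copy()
        out["gene_a"] = self.starting["target_gene"].reindex(out["guide_id"]).to_numpy()
        out["gene_b"] = self.queries["target_gene"].reindex(out["query_id"]).to_numpy()
        out["bioprocess_a"] = self.starting["bioprocess"].reindex(out["guide_id"]).to_numpy()
        out["bioprocess_b"] = self.queries["bioprocess"].reindex(out["query_id"]).to_numpy()
        return out

    def gene_pair_strains(self) -> dict[tuple[str, str], list[str]]:
        """Map each unordered gene pair to its replicate double-knockdown
        strains (distinct guide combinations targeting the same two genes)."""
        doubles = self.combo_genes()
        doubles = doubles[(doubles["strain_class"] == DOUBLE) & doubles["present"]]
        out: dict[tuple[str, str], list[str]] = {}
        for sid, row in doubles.iterrows():
            key = tuple(sorted((row["gene_a"], row["gene_b"])))
            out.setdefault(key, []).append(sid)
        return out


def classify_strain(gene_a: str, gene_b: str) -> str:
    a = gene_a != NONTARGETING
    b = gene_b != NONTARGETING
    if a and b:
        return DOUBLE
    if a or b:
        return SINGLE
    return NONE_CLASS


def make_query_spec(
    n_targeting: int = 20,
    n_genes: int = 17,
    n_nontargeting: int = 3,
    gene_prefix: str = "QGENE",
    bioprocesses: list[str] | None = None,
    seed: int = 0,
) -> list[dict]:
    """Build a query-guide specification: ``n_targeting`` guides spread over
    ``n_genes`` genes (up to two guides per gene, as in typical query panels)
    plus ``n_nontargeting`` control guides. Barcodes/sequences are filled in
    by :func:`design_pool` if omitted here."""
    if n_targeting < n_genes:
        raise DesignError("n_targeting must be >= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i:03d}" for i in range(n_genes)]
    if bioprocesses is None:
        bioprocesses = ["proteasome", "secretory", "ribosome_small", "ribosome_large", "chromatin"]
    assign = [genes[i % n_genes] for i in range(n_targeting)]
    spec = []
    per_gene_count: dict[str, int] = {}
    for gene in assign:
        k = per_gene_count.get(gene, 0) + 1
        per_gene_count[gene] = k
        spec.append(
            {
                "query_id": f"{gene}_q{k}",
                "target_gene": gene,
                "bioprocess": bioprocesses[genes.index(gene) % len(bioprocesses)],
            }
        )
    for i in range(n_nontargeting):
        spec.append({"query_id": f"NTq{i + 1}", "target_gene": NONTARGETING, "bioprocess": "none"})
    rng.shuffle(spec)  # deterministic but unordered, like a cloning batch
    return spec


def design_pool(
    n_starting_targeting: int,
    n_starting_control: int,
    query_spec: list[dict],
    holdout_fraction: float = 0.0,
    guides_per_gene: int = 2,
    n_bioprocesses: int = 10,
    seed: int = 0,
) -> PoolDesign:
    """Construct a pool design.

    All gene-targeting x gene-targeting combinations are formed, minus a
    random ``holdout_fraction`` of them which are recorded as intentionally
    absent (the chimera-quantification null). Control combinations follow the
    strain-class rules: targeting query x control starting guide and
    nontargeting query x targeting starting guide give single-knockdown
    controls; nontargeting x nontargeting gives no-knockdown controls.

    Deterministic given ``seed``.
    """
    if n_starting_targeting < 1:
        raise DesignError("need at least one targeting starting guide")
    if not (0 <= holdout_fraction < 0.5):
        raise DesignError("holdout_fraction must be in [0, 0.5)")
    barcodes = [q.get("barcode") for q in query_spec if q.get("barcode")]
    if len(barcodes) != len(set(barcodes)):
        dup = sorted({b for b in barcodes if barcodes.count(b) > 1})
        raise DesignError(f"duplicate query barcode(s) in spec: {dup}")

    rng = np.random.default_rng(seed)
    n_genes = max(1, int(np.ceil(n_starting_targeting / max(1, guides_per_gene))))
    bioprocs = [f"BP{i:02d}" for i in range(n_bioprocesses)]
    gene_bioproc = {f"SGENE{i:04d}": bioprocs[i % n_bioprocesses] for i in range(n_genes)}
    genes = list(gene_bioproc)

    srows = []
    for i in range(n_starting_targeting):
        gene = genes[i % n_genes]
        srows.append((f"sg{i:04d}", gene, gene_bioproc[gene]))
    for i in range(n_starting_control):
        srows.append((f"sgNT{i:03d}", NONTARGETING, "none"))
    starting = pd.DataFrame(srows, columns=["guide_id", "target_gene", "bioprocess"]).set_index("guide_id")
    starting["guide_seq"] = _random_seqs(rng, len(starting), GUIDE_LEN)

    qrows = []
    for q in query_spec:
        qrows.append(
            (
                q["query_id"],
                q.get("target_gene") or NONTARGETING,
                q.get("bioprocess", "none"),
                q.get("barcode"),
                q.get("guide_seq"),
            )
        )
    queries = pd.DataFrame(
        qrows, columns=["query_id", "target_gene", "bioprocess", "barcode", "guide_seq"]
    ).set_index("query_id")
    need_bc = queries["barcode"].isna()
    if need_bc.any():
        queries.loc[need_bc, "barcode"] = _random_seqs(rng, int(need_bc.sum()), BARCODE_LEN)
    need_seq = queries["guide_seq"].isna()
    if need_seq.any():
        queries.loc[need_seq, "guide_seq"] = _random_seqs(rng, int(need_seq.sum()), GUIDE_LEN)

    rows = []
    for gid, qid in itertools.product(starting.index, queries.index):
        cls = classify_strain(starting.at[gid, "target_gene"], queries.at[qid, "target_gene"])
        rows.append((strain_id(gid, qid), gid, qid, cls))
    combos = pd.DataFrame(rows, columns=["strain_id", "guide_id", "query_id", "strain_class"]).set_index(
        "strain_id"
    )
    combos["present"] = True

    doubles = combos.index[combos["strain_class"] == DOUBLE]
    n_hold = int(np.floor(holdout_fraction * len(doubles)))
    if n_hold:
        held = rng.choice(doubles.to_numpy(), size=n_hold, replace=False)
        combos.loc[held, "present"] = False

    return PoolDesign(
        starting=starting,
        queries=queries,
        combos=combos,
        meta={"seed": seed, "holdout_fraction": holdout_fraction, "n_holdout": n_hold},
    )


def validate_design(design: PoolDesign) -> list[dict]:
    """Report-only design checks: barcode uniqueness (already fatal at
    construction), availability of absent combos per barcode for chimera
    quantification, and single-mutant coverage per guide."""
    issues: list[dict] = []
    absent = design.absent_combos
    for qid in design.queries.index:
        if not (absent["query_id"] == qid).any():
            issues.append(
                {
                    "severity": "warning",
                    "code": "no_absent_combo_for_barcode",
                    "message": f"barcode of query {qid} has no intentionally absent combination; "
                    "chimera rate cannot be checked against it",
                    "ids": [qid],
                }
            )
    genes = design.combo_genes()
    singles = genes[(genes["strain_class"] == SINGLE) & genes["present"]]
    for gid, row in design.starting.iterrows():
        if row["target_gene"] == NONTARGETING:
            continue
        if not ((singles["guide_id"] == gid)).any():
            issues.append(
                {
                    "severity": "warning",
                    "code": "no_single_mutant_control",
                    "message": f"starting guide {gid} has no single-knockdown control strain",
                    "ids": [gid],
                }
            )
    for qid, row in design.queries.iterrows():
        if row["target_gene"] == NONTARGETING:
            continue
        if not ((singles["query_id"] == qid)).any():
            issues.append(
                {
                    "severity": "warning",
                    "code": "no_single_mutant_control",
                    "message": f"query guide {qid} has no single-knockdown control strain",
                    "ids": [qid],
                }
            )
    return issues
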