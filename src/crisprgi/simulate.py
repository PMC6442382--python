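"""Synthetic pooled-screen generator.

Emulates the statistical structure of a serial-batch pooled CRISPRi fitness
assay: a shared starting pool with lognormal abundance spread, growth by
w^G per cycle (G generations per cycle, G = log2 of the dilution factor; 1:4
per 24 h ~ 2 generations, 1:8 per 48 h ~ 3), a multinomial cell bottleneck at
each dilution, multinomial read sampling at a chosen depth, and PCR chimeras
formed at a tunable per-read rate with parents drawn from the marginal
guide/barcode frequencies (so chimeric reads land on absent combinations
too).

Ground truth composes double-mutant fitness as
``w_ab = (beta0 + beta1 * w_a) * (1 + eps)`` where the per-query line
(beta0, beta1) models the positive bias from the multiplicative expectation
and eps is the true genetic interaction on the fitness scale; the downstream
per-query linear scoring model is therefore exactly recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountTensor, write_counts_tsv
from .design import DOUBLE, NONTARGETING, PoolDesign

__all__ = [
    "Condition",
    "SimTruth",
    "simulate_truth",
    "simulate_counts",
    "write_fixture",
    "read_design_tsv",
    "write_fastq",
    "simulate_flow",
]


@dataclass(frozen=True)
class Condition:
    """A growth condition: name plus transfer scheme."""

    name: str
    dilution_factor: float = 4.0
    n_cycles: int = 3
    replicates: int = 3

    @property
    def generations_per_cycle(self) -> float:
        return float(np.log2(self.dilution_factor))


DEFAULT_CONDITIONS = (
    Condition("YPD24hr", 4.0),
    Condition("YPD48hr", 8.0),
    Condition("YPD37C", 4.0),
    Condition("YPEG", 4.0),
    Condition("SC-URA", 4.0),
)


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Ground truth for a simulated screen.

    ``single_fitness``: DataFrame (rows = starting guide_ids + query_ids,
    columns = condition names) of true single-guide relative fitness
    (wildtype = 1; nontargeting guides exactly 1).
    ``query_lines``: DataFrame indexed by (query_id, condition) with beta0,
    beta1 mapping starting-guide single fitness to baseline double fitness.
    ``gi_effects``: DataFrame indexed by (guide_id, query_id, condition) with
    the true interaction eps (only nonzero entries stored).
    """

    conditions: tuple[Condition, ...]
    single_fitness: pd.DataFrame
    query_lines: pd.DataFrame
    gi_effects: pd.DataFrame
    suppressor_query: str | None
    chimera_rate: float
    bottleneck: int
    depth_per_strain: float
    initial_abundance: pd.Series
    seed: int
    params: dict = field(default_factory=dict)

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise SimulationError(f"unknown condition label: {name!r}")

    def double_fitness(self, design: PoolDesign, condition: str) -> pd.Series:
        """True fitness of every present strain in one condition."""
        self.condition(condition)
        combos = design.present_combos
        w_a = self.single_fitness[condition].reindex(combos["guide_id"]).to_numpy()
        lines = self.query_lines.xs(condition, level="condition")
        b0 = lines["beta0"].reindex(combos["query_id"]).to_numpy()
        b1 = lines["beta1"].reindex(combos["query_id"]).to_numpy()
        eps = np.zeros(len(combos))
        if len(self.gi_effects):
            key = pd.MultiIndex.from_arrays(
                [combos["guide_id"], combos["query_id"], [condition] * len(combos)]
            )
            eps = self.gi_effects["eps"].reindex(key).fillna(0.0).to_numpy()
        w = (b0 + b1 * w_a) * (1.0 + eps)
        return pd.Series(np.maximum(w, 1e-6), index=combos.index, name=condition)


def simulate_truth(
    design: PoolDesign,
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS,
    gi_density: float = 0.0,
    suppressor_query: str | None = None,
    seed: int = 0,
    fitness_range: tuple[float, float] = (0.5, 1.1),
    query_fitness_range: tuple[float, float] = (0.5, 1.0),
    bias_range: tuple[float, float] = (0.02, 0.12),
    suppressor_beta0_range: tuple[float, float] = (0.35, 0.45),
    suppressor_beta1_range: tuple[float, float] = (0.5, 0.7),
    gi_magnitude: tuple[float, float] = (0.15, 0.35),
    chimera_rate: float = 0.0,
    bottleneck: int = 10_000_000,
    depth_per_strain: float = 100.0,
    initial_spread: float = 0.65,
) -> SimTruth:
    """Draw ground truth for a design.

    gi_density is the fraction of (targeting guide, targeting query,
    condition) triples carrying a nonzero interaction eps (magnitude uniform
    in ``gi_magnitude``, random sign). The suppressor query's line has
    beta1 < 1 and a large intercept, pulling baseline double fitness toward
    wildtype (fitness-defect rescue); other targeting queries' lines pass
    through (1, w_query) so a nontargeting starting partner recovers the
    query single fitness exactly.
    """
    if not 0 <= gi_density <= 1:
        raise SimulationError("gi_density must be in [0, 1]")
    if suppressor_query is not None and suppressor_query not in design.queries.index:
        raise SimulationError(f"unknown suppressor query: {suppressor_query!r}")
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise SimulationError("duplicate condition labels")
    rng = np.random.default_rng(seed)

    rows = {}
    for gid, row in design.starting.iterrows():
        if row["target_gene"] == NONTARGETING:
            rows[gid] = np.ones(len(names))
        else:
            rows[gid] = rng.uniform(*fitness_range, size=len(names))
    for qid, row in design.queries.iterrows():
        if row["target_gene"] == NONTARGETING:
            rows[qid] = np.ones(len(names))
        else:
            rows[qid] = rng.uniform(*query_fitness_range, size=len(names))
    single = pd.DataFrame.from_dict(rows, orient="index", columns=names)

    line_rows = []
    for qid, row in design.queries.iterrows():
        for cond in names:
            if qid == suppressor_query:
                b0 = rng.uniform(*suppressor_beta0_range)
                b1 = rng.uniform(*suppressor_beta1_range)
                single.loc[qid, cond] = b0 + b1  # keep singles consistent with the line
            elif row["target_gene"] == NONTARGETING:
                b0, b1 = 0.0, 1.0
            else:
                wq = single.at[qid, cond]
                b0 = rng.uniform(*bias_range)
                b1 = wq - b0  # line through (1, w_query): positive bias below w_a = 1
            line_rows.append((qid, cond, b0, b1))
    query_lines = pd.DataFrame(line_rows, columns=["query_id", "condition", "beta0", "beta1"]).set_index(
        ["query_id", "condition"]
    )

    doubles = design.combos[design.combos["strain_class"] == DOUBLE]
    gi_rows = []
    if gi_density > 0 and len(doubles):
        for cond in names:
            hit = rng.random(len(doubles)) < gi_density
            mags = rng.uniform(*gi_magnitude, size=int(hit.sum()))
            signs = rng.choice([-1.0, 1.0], size=int(hit.sum()))
            for (sid, row), eps in zip(doubles[hit].iterrows(), mags * signs):
                gi_rows.append((row["guide_id"], row["query_id"], cond, eps))
    gi_effects = pd.DataFrame(gi_rows, columns=["guide_id", "query_id", "condition", "eps"])
    gi_effects = gi_effects.set_index(["guide_id", "query_id", "condition"])

    # one physical pool: abundances shared by every condition/replicate
    abund = pd.Series(
        rng.lognormal(mean=0.0, sigma=initial_spread, size=len(design.present_combos)),
        index=design.present_combos.index,
    )

    return SimTruth(
        conditions=tuple(conditions),
        single_fitness=single,
        query_lines=query_lines,
        gi_effects=gi_effects,
        suppressor_query=suppressor_query,
        chimera_rate=chimera_rate,
        bottleneck=int(bottleneck),
        depth_per_strain=depth_per_strain,
        initial_abundance=abund,
        seed=seed,
        params={
            "gi_density": gi_density,
            "fitness_range": fitness_range,
            "query_fitness_range": query_fitness_range,
            "bias_range": bias_range,
            "gi_magnitude": gi_magnitude,
            "initial_spread": initial_spread,
        },
    )


def _sample_reads(
    rng: np.random.Generator,
    freq: np.ndarray,
    depth: int,
    rho: float,
    combos: pd.DataFrame,
    present_pos: np.ndarray,
    guide_codes: np.ndarray,
    query_codes: np.ndarray,
    n_guides: int,
    n_queries: int,
) -> np.ndarray:
    """One sequencing sample over ALL combos (present + absent): real reads
    multinomial on present-strain frequencies, chimeric reads multinomial on
    the outer product of marginal guide/barcode frequencies."""
    counts = np.zeros(len(combos), dtype=np.int64)
    n_chim = rng.binomial(depth, rho) if rho > 0 else 0
    real = rng.multinomial(depth - n_chim, freq)
    counts[present_pos] = real
    if n_chim:
        pg = np.bincount(guide_codes[present_pos], weights=freq, minlength=n_guides)
        pb = np.bincount(query_codes[present_pos], weights=freq, minlength=n_queries)
        p_combo = pg[guide_codes] * pb[query_codes]
        p_combo = p_combo / p_combo.sum()
        counts += rng.multinomial(n_chim, p_combo)
    return counts


def simulate_counts(
    design: PoolDesign,
    truth: SimTruth,
    n_cycles: int = 3,
    replicates: int | None = None,
    depth: int | None = None,
    seed: int | None = None,
    conditions: list[str] | None = None,
    analytic: bool = False,
) -> list[CountTensor]:
    """Simulate count tensors for every condition x replicate.

    ``analytic=True`` returns exact expected read counts (real-valued, no
    bottleneck, no sampling) — the infinite-depth limit used for noiseless
    recovery checks. Deterministic given the seed (default: the truth's
    seed); per-sample substreams are derived from (seed, condition index,
    replicate index) so samples are independent but reproducible.
    """
    if n_cycles < 1:
        raise SimulationError("n_cycles must be >= 1")
    master = truth.seed if seed is None else seed
    combos = design.combos
    present_mask = combos["present"].to_numpy()
    present_pos = np.nonzero(present_mask)[0]
    guide_codes = pd.Categorical(combos["guide_id"], categories=design.starting.index).codes
    query_codes = pd.Categorical(combos["query_id"], categories=design.queries.index).codes
    n_present = len(present_pos)
    if depth is None:
        depth = int(round(truth.depth_per_strain * n_present))
    if depth < 0:
        raise SimulationError("depth must be >= 0")
    warn_zero = depth == 0

    wanted = conditions or [c.name for c in truth.conditions]
    out: list[CountTensor] = []
    abund0 = truth.initial_abundance.reindex(combos.index[present_pos]).to_numpy()
    for ci, cname in enumerate(wanted):
        cond = truth.condition(cname)
        G = cond.generations_per_cycle
        w = truth.double_fitness(design, cname).to_numpy()
        growth = w**G
        n_rep = cond.replicates if replicates is None else replicates
        for rep in range(1, n_rep + 1):
            rng = np.random.default_rng([master, ci, rep])
            freq = abund0 / abund0.sum()
            cols = {}
            for t in range(n_cycles + 1):
                if analytic:
                    col = np.zeros(len(combos))
                    col[present_pos] = freq * depth * (1 - truth.chimera_rate)
                    if truth.chimera_rate > 0:
                        pg = np.bincount(
                            guide_codes[present_pos], weights=freq, minlength=len(design.starting)
                        )
                        pb = np.bincount(
                            query_codes[present_pos], weights=freq, minlength=len(design.queries)
                        )
                        pc = pg[guide_codes] * pb[query_codes]
                        col += truth.chimera_rate * depth * pc / pc.sum()
                    cols[f"t{t}"] = col
                else:
                    cols[f"t{t}"] = _sample_reads(
                        rng,
                        freq,
                        depth,
                        truth.chimera_rate,
                        combos,
                        present_pos,
                        guide_codes,
                        query_codes,
                        len(design.starting),
                        len(design.queries),
                    )
                if t < n_cycles:
                    freq = freq * growth
                    freq = freq / freq.sum()
                    if not analytic and truth.bottleneck > 0:
                        cells = rng.multinomial(truth.bottleneck, freq)
                        total = cells.sum()
                        if total == 0:
                            raise SimulationError(f"bottleneck extinguished sample {cname}/rep{rep}")
                        freq = cells / total
            counts = pd.DataFrame(cols, index=combos.index)
            if not analytic:
                counts = counts.astype(np.int64)
            out.append(
                CountTensor(
                    condition=cname,
                    replicate=rep,
                    counts=counts,
                    generations_per_cycle=G,
                    meta={
                        "seed": [master, ci, rep],
                        "depth": depth,
                        "analytic": analytic,
                        "all_zero_warning": warn_zero,
                    },
                )
            )
    return out


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

FIXTURE_LINKER = "GTTTAAGAGCTAAGCTGGAAACAGCATAGCAAG"


def write_fixture(
    design: PoolDesign,
    truth: SimTruth | None,
    counts: list[CountTensor],
    out_dir: str | Path,
    fastq: bool = False,
) -> dict[str, Path]:
    """Write a design TSV trio, optional truth tables, per-sample count TSVs
    and optionally FASTQ files; everything round-trips through the package
    readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes = design.combo_genes()
    genes["barcode"] = design.queries["barcode"].reindex(genes["query_id"]).to_numpy()
    cols = [
        "guide_id",
        "query_id",
        "barcode",
        "strain_class",
        "gene_a",
        "gene_b",
        "bioprocess_a",
        "bioprocess_b",
        "present",
    ]
    paths["design"] = out / "design.tsv"
    genes[cols].to_csv(paths["design"], sep="\t", index_label="strain_id")
    paths["starting"] = out / "starting_guides.tsv"
    design.starting.to_csv(paths["starting"], sep="\t", index_label="guide_id")
    paths["queries"] = out / "query_guides.tsv"
    design.queries.to_csv(paths["queries"], sep="\t", index_label="query_id")

    if truth is not None:
        paths["truth_single"] = out / "truth_single_fitness.tsv"
        truth.single_fitness.to_csv(paths["truth_single"], sep="\t", index_label="id")
        paths["truth_lines"] = out / "truth_query_lines.tsv"
        truth.query_lines.to_csv(paths["truth_lines"], sep="\t")
        paths["truth_gi"] = out / "truth_gi_effects.tsv"
        truth.gi_effects.to_csv(paths["truth_gi"], sep="\t")

    for ct in counts:
        stem = f"counts_{ct.condition}_rep{ct.replicate}"
        p = out / f"{stem}.tsv"
        write_counts_tsv(ct, p)
        paths[stem] = p
        if fastq:
            for tp in ct.timepoints:
                fq = out / f"{stem}_{tp}.fastq"
                write_fastq(ct, design, tp, fq)
                paths[f"{stem}_{tp}_fastq"] = fq
    manifest = {
        "samples": [
            {"condition": ct.condition, "replicate": ct.replicate, "timepoints": ct.timepoints}
            for ct in counts
        ]
    }
    paths["manifest"] = out / "fixture_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def write_fastq(tensor: CountTensor, design: PoolDesign, timepoint: str, path: str | Path) -> int:
    """Expand one timepoint's integer counts into 4-line FASTQ records
    (read = guide_seq + linker + barcode). Returns reads written."""
    col = tensor.counts[timepoint]
    if not np.issubdtype(col.dtype, np.integer):
        raise SimulationError("FASTQ export needs integer counts (not analytic tensors)")
    gseq = design.starting["guide_seq"].reindex(design.combos["guide_id"]).to_numpy()
    bseq = design.queries["barcode"].reindex(design.combos["query_id"]).to_numpy()
    n = 0
    with open(path, "w") as fh:
        for (sid, cnt), g, b in zip(col.items(), gseq, bseq):
            if cnt <= 0:
                continue
            read = g + FIXTURE_LINKER + b
            qual = "I" * len(read)
            for k in range(int(cnt)):
                fh.write(f"@{sid}_{k}\n{read}\n+\n{qual}\n")
                n += 1
    return n


def read_design_tsv(
    design_path: str | Path, starting_path: str | Path, queries_path: str | Path
) -> PoolDesign:
    combos = pd.read_csv(design_path, sep="\t", index_col="strain_id")
    starting = pd.read_csv(starting_path, sep="\t", index_col="guide_id")
    queries = pd.read_csv(queries_path, sep="\t", index_col="query_id")
    return PoolDesign(
        starting=starting,
        queries=queries,
        combos=combos[["guide_id", "query_id", "strain_class", "present"]],
    )


# ---------------------------------------------------------------------------
# synthetic flow-cytometry events (for the GFP knockdown assay)
# ---------------------------------------------------------------------------


def simulate_flow(
    n_events: int = 10_000,
    knockdown_fraction: float = 0.0,
    debris_fraction: float = 0.0,
    noise_sd: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic flow events: forward scatter lognormal; fluorescence linear
    in cell size, scaled down by ``knockdown_fraction`` (0 = uninduced),
    plus Gaussian noise. ``debris_fraction`` of events get very low FSC and
    dim fluorescence (dead cells / particulates removed by gating)."""
    rng = np.random.default_rng(seed)
    fsc = rng.lognormal(mean=np.log(500.0), sigma=0.25, size=n_events)
    fl = (50.0 + 0.8 * fsc) * (1.0 - knockdown_fraction) + rng.normal(0, noise_sd, size=n_events)
    is_debris = rng.random(n_events) < debris_fraction
    fsc[is_debris] = rng.uniform(5.0, 60.0, size=int(is_debris.sum()))
    fl[is_debris] = rng.uniform(0.0, 20.0, size=int(is_debris.sum()))
    return pd.DataFrame({"fsc": fsc, "fl": np.maximum(fl, 0.1), "debris": is_debris})
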