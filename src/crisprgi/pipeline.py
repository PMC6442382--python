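"""End-to-end orchestration: counts -> fitness -> GI -> profiles -> network.

A run is driven by a :class:`RunConfig` (constructible from YAML). Inputs
are either simulated in place or loaded from a fixture directory written by
:func:`crisprgi.simulate.write_fixture`. Every stage writes TSV artifacts
plus a manifest with the seed, a config hash and per-stage row counts, so a
rerun with the same inputs and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counting import CountTensor, correct_chimeras, estimate_chimera_rate, read_counts_tsv
from .design import PoolDesign, design_pool, make_query_spec, validate_design
from .fitness import FitnessTable, write_fitness_tsv
from .gi import (
    aggregate_gene_pairs,
    annotate_condition_specific,
    classify_condition_specific,
    gi_scores,
    standardize_and_call,
)
from .network import build_network, condition_gi_network, write_network
from .profiles import build_profiles, profile_correlations
from .simulate import Condition, read_design_tsv, simulate_counts, simulate_truth

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "crisprgi_run"
    seed: int = 0
    conditions: list = field(
        default_factory=lambda: [
            {"name": "YPD24hr", "dilution_factor": 4},
            {"name": "YPD48hr", "dilution_factor": 8},
            {"name": "YPD37C", "dilution_factor": 4},
            {"name": "YPEG", "dilution_factor": 4},
            {"name": "SC-URA", "dilution_factor": 4},
        ]
    )
    n_cycles: int = 3
    replicates: int = 3
    counts_dir: str | None = None  # load a fixture instead of simulating
    simulate: dict = field(
        default_factory=lambda: {
            "n_starting_targeting": 60,
            "n_starting_control": 6,
            "n_query_targeting": 6,
            "n_query_genes": 3,
            "n_query_nontargeting": 2,
            "holdout_fraction": 0.05,
            "gi_density": 0.05,
            "chimera_rate": 0.02,
            "depth_per_strain": 300,
        }
    )
    suppressor_queries: list = field(default_factory=list)
    min_count: float = 10
    min_points: int = 30
    z_threshold: float = 2.0
    inner_threshold: float = 1.0
    min_strains: int = 3
    max_missing: float = 0.25
    max_fpr: float = 0.005
    rho_grid_step: float = 0.01
    allow_any_dilution: bool = False

    def __post_init__(self) -> None:
        for c in self.conditions:
            if not self.allow_any_dilution and c.get("dilution_factor", 4) not in (4, 8):
                raise PipelineError(
                    f"condition {c.get('name')}: dilution factor must be 4 or 8 "
                    "(set allow_any_dilution to override)"
                )
        for name in ("min_count", "z_threshold", "inner_threshold", "min_strains", "max_missing", "max_fpr"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def condition_objects(self) -> tuple[Condition, ...]:
        return tuple(
            Condition(
                name=c["name"],
                dilution_factor=float(c.get("dilution_factor", 4)),
                n_cycles=int(c.get("n_cycles", self.n_cycles)),
                replicates=int(c.get("replicates", self.replicates)),
            )
            for c in self.conditions
        )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # paths do not affect the analysis
        payload.pop("counts_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_fixture(cfg: RunConfig) -> tuple[PoolDesign, list[CountTensor]]:
    base = Path(cfg.counts_dir)
    design = read_design_tsv(base / "design.tsv", base / "starting_guides.tsv", base / "query_guides.tsv")
    schemes = {c.name: c for c in cfg.condition_objects()}
    manifest_path = base / "fixture_manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"fixture manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    tensors = []
    for s in manifest["samples"]:
        cond, rep = s["condition"], s["replicate"]
        path = base / f"counts_{cond}_rep{rep}.tsv"
        if not path.exists():
            raise PipelineError(f"stage counting: missing counts for sample {cond}/rep{rep}: {path}")
        scheme = schemes.get(cond)
        g = scheme.generations_per_cycle if scheme else 2.0
        tensors.append(read_counts_tsv(path, condition=cond, replicate=rep, generations_per_cycle=g))
    return design, tensors


def _simulate_inputs(cfg: RunConfig) -> tuple[PoolDesign, list[CountTensor]]:
    sim = cfg.simulate
    qspec = make_query_spec(
        n_targeting=sim.get("n_query_targeting", 6),
        n_genes=sim.get("n_query_genes", 3),
        n_nontargeting=sim.get("n_query_nontargeting", 2),
        seed=cfg.seed,
    )
    design = design_pool(
        n_starting_targeting=sim.get("n_starting_targeting", 60),
        n_starting_control=sim.get("n_starting_control", 6),
        query_spec=qspec,
        holdout_fraction=sim.get("holdout_fraction", 0.05),
        seed=cfg.seed,
    )
    truth = simulate_truth(
        design,
        conditions=cfg.condition_objects(),
        gi_density=sim.get("gi_density", 0.05),
        suppressor_query=sim.get("suppressor_query"),
        chimera_rate=sim.get("chimera_rate", 0.0),
        depth_per_strain=sim.get("depth_per_strain", 100),
        seed=cfg.seed,
    )
    tensors = simulate_counts(design, truth, n_cycles=cfg.n_cycles, replicates=cfg.replicates)
    return design, tensors


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write artifacts under ``cfg.out_dir``. Returns the
    manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    design, tensors = _load_fixture(cfg) if cfg.counts_dir else _simulate_inputs(cfg)
    issues = validate_design(design)
    (out / "design_issues.json").write_text(json.dumps(issues, indent=2) + "\n")
    stage_counts["strains_present"] = int(design.present_combos.shape[0])
    stage_counts["samples"] = len(tensors)

    # chimera correction (needs absent combos; otherwise counts pass through)
    rho_by_sample = {}
    corrected = []
    for t in tensors:
        try:
            model = estimate_chimera_rate(t, design)
        except Exception as exc:  # noqa: BLE001 - stage failures must name the sample
            raise PipelineError(f"stage chimera: sample {t.sample_name}: {exc}") from exc
        rho_by_sample[t.sample_name] = model.rho
        corrected.append(correct_chimeras(t, model, design) if model.rho > 0 else t)
    (out / "chimera_rates.json").write_text(json.dumps(rho_by_sample, indent=2) + "\n")

    try:
        fit = FitnessTable.from_tensors(
            corrected, design, min_count=cfg.min_count, required_replicates=cfg.replicates
        )
    except Exception as exc:
        raise PipelineError(f"stage fitness: {exc}") from exc
    write_fitness_tsv(fit, out / "fitness.tsv")
    stage_counts["fitness_rows"] = int(fit.aggregated.shape[0])

    try:
        records, _models = gi_scores(
            fit, design, suppressor_queries=set(cfg.suppressor_queries), min_points=cfg.min_points
        )
        records = standardize_and_call(records, z_threshold=cfg.z_threshold)
        flags = classify_condition_specific(records, outer_threshold=cfg.z_threshold,
                                            inner_threshold=cfg.inner_threshold)
        records = annotate_condition_specific(records, flags)
    except Exception as exc:
        raise PipelineError(f"stage gi: {exc}") from exc
    gi_out = records.reset_index()[
        ["guide_id", "query_id", "gene_a", "gene_b", "condition", "score", "z",
         "significant", "condition_specific", "model_used"]
    ]
    gi_out.to_csv(out / "gi_scores.tsv", sep="\t", index=False)
    stage_counts["gi_records"] = len(records)
    pairs = aggregate_gene_pairs(records, min_strains=cfg.min_strains, inner_threshold=cfg.inner_threshold)
    pairs.to_csv(out / "gene_pair_gi.tsv", sep="\t", index=False)
    stage_counts["gene_pairs"] = len(pairs)

    try:
        pm = build_profiles(records, design)
        pm.scores.to_csv(out / "profiles.tsv", sep="\t")
        rhos = profile_correlations(pm)
        g = build_network(pm, rhos=rhos, max_fpr=cfg.max_fpr, max_missing=cfg.max_missing)
        write_network(
            g,
            graphml_path=out / "profile_network.graphml",
            edgelist_path=out / "profile_network_edges.tsv",
            nodes_path=out / "profile_network_nodes.tsv",
        )
        cg = condition_gi_network(records)
        write_network(cg, edgelist_path=out / "condition_gi_edges.tsv")
        stage_counts["profile_network_edges"] = g.number_of_edges()
        stage_counts["condition_gi_edges"] = cg.number_of_edges()
        network_info = {
            "threshold": g.graph["threshold"],
            "achieved_different_rate": g.graph["achieved_different_rate"],
        }
    except Exception as exc:
        raise PipelineError(f"stage network: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "conditions": [c["name"] for c in cfg.conditions],
        "replicates": cfg.replicates,
        "sigma_global": records.attrs.get("sigma_global"),
        "stage_counts": stage_counts,
        "network": network_info,
        "chimera_rho": rho_by_sample,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
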