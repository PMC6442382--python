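"""Amplicon counting and PCR-chimera correction.

Each sequencing read covers the starting-pool guide (20 nt) and the query
barcode (25 nt) in a fixed amplicon architecture. During PCR, template
switching creates *chimeric* reads that pair the guide of one template with
the barcode of another. Because some guide x barcode combinations are
intentionally absent from the pool, reads assigned to them must be chimeras;
their excess over zero, relative to the product of marginal frequencies,
estimates the per-sample chimera fraction, which is then subtracted from all
counts (marginal-product model).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .design import PoolDesign, strain_id

DEFAULT_LINKER = "GTTTAAGAGCTAAGCTGGAAACAGCATAGCAAG"


class CountingError(ValueError):
    pass


@dataclass
class CountTensor:
    """Integer (or, for analytic simulations, real-valued) read counts per
    strain per timepoint for one condition x replicate sample series.

    ``counts`` is indexed by strain_id (present and absent combos) with one
    column per timepoint (``t0`` = pre-assay pool); ``generations_per_cycle``
    comes from the transfer scheme (log2 of the dilution factor)."""

    condition: str
    replicate: int
    counts: pd.DataFrame
    generations_per_cycle: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise CountingError("counts must be non-negative")

    @property
    def timepoints(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def generations(self) -> np.ndarray:
        return np.arange(self.counts.shape[1], dtype=float) * self.generations_per_cycle

    @property
    def sample_name(self) -> str:
        return f"{self.condition}/rep{self.replicate}"

    def copy_with(self, counts: pd.DataFrame) -> "CountTensor":
        return CountTensor(
            condition=self.condition,
            replicate=self.replicate,
            counts=counts,
            generations_per_cycle=self.generations_per_cycle,
            meta=dict(self.meta),
        )


@dataclass
class ChimeraModel:
    """Estimated chimera fraction for one sample (per timepoint)."""

    rho: float
    rho_per_timepoint: dict[str, float]
    n_absent_used: int
    warning: str | None = None


def _hamming_lookup(seqs: pd.Series, max_mismatches: int) -> None:
    """Hard error if two sequences lie within each other's mismatch radius
    (a read could then be assigned ambiguously)."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    for i in range(len(arr)):
        d = (arr[i + 1 :] != arr[i]).sum(axis=1)
        bad = np.nonzero(d <= 2 * max_mismatches)[0]
        if len(bad):
            j = int(bad[0]) + i + 1
            raise CountingError(
                f"ambiguous design: sequences for {seqs.index[i]} and {seqs.index[j]} "
                f"are within {2 * max_mismatches} mismatches of each other"
            )


def _match(segment: str, exact: dict[str, str], seqs: pd.Series, max_mm: int) -> str | None:
    hit = exact.get(segment)
    if hit is not None or max_mm == 0:
        return hit
    best = None
    for sid, seq in seqs.items():
        d = sum(a != b for a, b in zip(segment, seq))
        if d <= max_mm:
            best = sid
            break  # ambiguity excluded at load time
    return best


def parse_reads(
    fastq_path: str | Path,
    design: PoolDesign,
    guide_offset: int = 0,
    barcode_offset: int | None = None,
    linker: str = DEFAULT_LINKER,
    max_mismatches_guide: int = 1,
    max_mismatches_barcode: int = 2,
    condition: str = "fastq",
    replicate: int = 1,
    timepoint: str = "t0",
) -> tuple[CountTensor, int]:
    """Assign each read to a (guide, barcode) combination by matching both
    fixed-offset segments within a Hamming tolerance; reads failing either
    segment go to an unassigned bin. Absent combinations are counted too —
    they feed chimera-rate estimation. Returns the single-timepoint tensor
    and the number of unassigned reads."""
    guide_seqs = design.starting["guide_seq"]
    bc_seqs = design.queries["barcode"]
    _hamming_lookup(guide_seqs, max_mismatches_guide)
    _hamming_lookup(bc_seqs, max_mismatches_barcode)
    g_exact = {seq: gid for gid, seq in guide_seqs.items()}
    b_exact = {seq: qid for qid, seq in bc_seqs.items()}
    glen = len(guide_seqs.iloc[0])
    blen = len(bc_seqs.iloc[0])
    if barcode_offset is None:
        barcode_offset = guide_offset + glen + len(linker)

    counts = pd.Series(0, index=design.combos.index, dtype=np.int64)
    unassigned = 0
    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            read = str(rec.seq)
            g = _match(read[guide_offset : guide_offset + glen], g_exact, guide_seqs, max_mismatches_guide)
            b = _match(
                read[barcode_offset : barcode_offset + blen], b_exact, bc_seqs, max_mismatches_barcode
            )
            if g is None or b is None:
                unassigned += 1
                continue
            sid = strain_id(g, b)
            if sid in counts.index:
                counts[sid] += 1
            else:  # combination outside the design universe
                unassigned += 1
    tensor = CountTensor(
        condition=condition,
        replicate=replicate,
        counts=counts.to_frame(timepoint),
        meta={"unassigned": unassigned, "fastq": str(path)},
    )
    return tensor, unassigned


# ---------------------------------------------------------------------------
# chimera estimation / correction
# ---------------------------------------------------------------------------


def _marginals(counts: pd.Series, design: PoolDesign) -> tuple[pd.Series, pd.Series, float]:
    combo = design.combos
    total = float(counts.sum())
    if total == 0:
        raise CountingError("cannot compute marginals of an all-zero sample")
    pg = counts.groupby(combo["guide_id"]).sum() / total
    pb = counts.groupby(combo["query_id"]).sum() / total
    return pg, pb, total


def estimate_chimera_rate(raw: CountTensor, design: PoolDesign) -> ChimeraModel:
    """Estimate the chimera fraction rho from intentionally absent combos.

    For each timepoint: rho_hat = sum over absent (g,b) of n_{g,b} divided by
    N * sum over absent (g,b) of p_g * p_b, with p_g/p_b the marginal read
    fractions of each guide/barcode and N the total assigned reads; clipped
    to [0, 1]. Reported rho is the mean over timepoints."""
    absent = design.absent_combos
    warning = None
    if len(absent) == 0:
        return ChimeraModel(rho=0.0, rho_per_timepoint={}, n_absent_used=0, warning="no absent combos; rho set to 0")
    per_tp: dict[str, float] = {}
    for tp in raw.timepoints:
        col = raw.counts[tp]
        pg, pb, total = _marginals(col, design)
        expected_frac = float(
            (pg.reindex(absent["guide_id"]).to_numpy() * pb.reindex(absent["query_id"]).to_numpy()).sum()
        )
        if expected_frac <= 0:
            per_tp[tp] = 0.0
            warning = "absent combos have zero-marginal parents; rho set to 0"
            continue
        rho = float(col.loc[absent.index].sum()) / (total * expected_frac)
        per_tp[tp] = float(np.clip(rho, 0.0, 1.0))
    rho_mean = float(np.mean(list(per_tp.values()))) if per_tp else 0.0
    return ChimeraModel(rho=rho_mean, rho_per_timepoint=per_tp, n_absent_used=len(absent), warning=warning)


def correct_chimeras(
    raw: CountTensor, model: ChimeraModel, design: PoolDesign, iterations: int = 2
) -> CountTensor:
    """Subtract the expected chimeric contribution rho*N*p_g*p_b from every
    combination, recomputing marginals from the corrected counts and
    repeating (marginals are themselves chimera-contaminated; two passes
    suffice for rho <= 0.1). Output is clamped at 0 and never exceeds the
    raw counts."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    out = raw.counts.astype(float).copy()
    combo = design.combos
    for tp in raw.timepoints:
        rho = model.rho_per_timepoint.get(tp, model.rho)
        if rho <= 0:
            continue
        raw_col = raw.counts[tp].astype(float)
        n_total = float(raw_col.sum())
        corrected = raw_col.copy()
        for _ in range(iterations):
            pg, pb, _ = _marginals(corrected, design)
            expected = (
                rho
                * n_total
                * pg.reindex(combo["guide_id"]).to_numpy()
                * pb.reindex(combo["query_id"]).to_numpy()
            )
            corrected = (raw_col - expected).clip(lower=0.0)
        out[tp] = corrected
    result = raw.copy_with(out)
    result.meta["chimera_rho"] = model.rho
    return result


def read_counts_tsv(
    path: str | Path, condition: str = "tsv", replicate: int = 1, generations_per_cycle: float = 2.0
) -> CountTensor:
    df = pd.read_csv(path, sep="\t", index_col="strain_id")
    return CountTensor(
        condition=condition, replicate=replicate, counts=df, generations_per_cycle=generations_per_cycle
    )


def write_counts_tsv(tensor: CountTensor, path: str | Path) -> None:
    tensor.counts.to_csv(path, sep="\t", index_label="strain_id")
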