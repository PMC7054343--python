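"""Synthetic stage-grouped aberration data with planted recurrent regions.

Emulates the inputs of a staged tumour-cohort copy-number study: per-stage
ternary call matrices over a shared probe map, a gene annotation table and a
pathway database, plus a planted-truth table so detector recovery can be
scored without any external download.

Carriers of a planted region are drawn once per region; ``carrier_overlap``
controls the fraction of carriers that span the full region (the rest get a
random sub-span), which is what makes the planted block homogeneous.
Background noise is i.i.d. per cell and per type; a cell hit by both a
background gain and a background loss is resolved by a seeded coin flip.
Each stage consumes its own RNG stream split from the master seed, so adding
a stage never perturbs the data of earlier stages.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import AberrationCallMatrix, GAIN, LOSS, ProbeMap

_PROBE_SPACING_BP = 1000


@dataclasses.dataclass
class PlantedRegion:
    """Ground-truth recurrent aberration planted into one stage."""

    stage: str
    chromosome: str
    probe_start: int        # 0-based index within the chromosome
    probe_end: int          # inclusive
    aberration_type: str    # gain|loss
    frequency: float
    carrier_overlap: float = 1.0

    def __post_init__(self):
        if self.aberration_type not in ("gain", "loss"):
            raise ValueError("aberration_type must be gain|loss")
        if not (0 < self.frequency <= 1):
            raise ValueError("frequency must be in (0,1]")
        if not (0 <= self.carrier_overlap <= 1):
            raise ValueError("carrier_overlap must be in [0,1]")
        if self.probe_start > self.probe_end:
            raise ValueError("probe_start must be <= probe_end")


@dataclasses.dataclass
class SimConfig:
    """Study design of a simulated cohort."""

    stages: list[str]
    n_samples_per_stage: list[int]
    n_probes: int
    chromosomes: list[tuple[str, int]]  # (name, number of probes)
    planted_regions: list[PlantedRegion] = dataclasses.field(default_factory=list)
    background_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if len(self.stages) != len(self.n_samples_per_stage):
            raise ValueError("stages and n_samples_per_stage must align")
        if any(n < 1 for n in self.n_samples_per_stage):
            raise ValueError("every stage needs at least one sample")
        if sum(span for _, span in self.chromosomes) != self.n_probes:
            raise ValueError("chromosome probe spans must sum to n_probes")
        if not (0 <= self.background_rate < 1):
            raise ValueError("background_rate must be in [0,1)")
        spans = dict(self.chromosomes)
        stage_set = set(self.stages)
        for pr in self.planted_regions:
            if pr.stage not in stage_set:
                raise ValueError(f"planted region references unknown stage {pr.stage!r}")
            if pr.chromosome not in spans:
                raise ValueError(f"planted region references unknown chromosome {pr.chromosome!r}")
            if pr.probe_end >= spans[pr.chromosome]:
                raise ValueError("planted region exceeds its chromosome's probe span")
        # a cell holds one ternary value: opposite-type plants may not overlap
        by_stage_chrom: dict[tuple[str, str], list[PlantedRegion]] = {}
        for pr in self.planted_regions:
            by_stage_chrom.setdefault((pr.stage, pr.chromosome), []).append(pr)
        for group in by_stage_chrom.values():
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    if (a.aberration_type != b.aberration_type
                            and a.probe_start <= b.probe_end
                            and b.probe_start <= a.probe_end):
                        raise ValueError(
                            "planted gain and loss overlap on "
                            f"{a.chromosome} [{b.probe_start},{a.probe_end}]"
                        )


def build_probe_map(chromosomes: list[tuple[str, int]]) -> ProbeMap:
    """Evenly spaced probe map over the given chromosome spans."""
    rows = []
    for chrom, span in chromosomes:
        for i in range(span):
            rows.append((f"{chrom}_P{i + 1}", chrom, (i + 1) * _PROBE_SPACING_BP))
    return ProbeMap(pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"]))


def _chrom_offsets(chromosomes: list[tuple[str, int]]) -> dict[str, int]:
    off, total = {}, 0
    for chrom, span in chromosomes:
        off[chrom] = total
        total += span
    return off


def simulate_stage_calls(
    cfg: SimConfig,
) -> tuple[dict[str, AberrationCallMatrix], ProbeMap, pd.DataFrame]:
    """Simulate per-stage ternary call matrices.

    Returns (matrices keyed by stage, probe map, planted-truth table).  The
    truth table records the genome-rank span and realised carrier count of
    every planted region.  Fully deterministic for a fixed config.
    """
    probe_map = build_probe_map(cfg.chromosomes)
    offsets = _chrom_offsets(cfg.chromosomes)
    master = np.random.SeedSequence(cfg.seed)
    stage_streams = master.spawn(len(cfg.stages))

    matrices: dict[str, AberrationCallMatrix] = {}
    truth_rows = []
    for stage, n, ss in zip(cfg.stages, cfg.n_samples_per_stage, stage_streams):
        rng = np.random.default_rng(ss)
        vals = np.zeros((n, cfg.n_probes), dtype=np.int8)
        if cfg.background_rate > 0:
            gains = rng.random((n, cfg.n_probes)) < cfg.background_rate
            losses = rng.random((n, cfg.n_probes)) < cfg.background_rate
            both = gains & losses
            flips = rng.random((n, cfg.n_probes)) < 0.5
            vals[gains & ~both] = GAIN
            vals[losses & ~both] = LOSS
            vals[both & flips] = GAIN
            vals[both & ~flips] = LOSS
        for pr in cfg.planted_regions:
            if pr.stage != stage:
                continue
            lo = offsets[pr.chromosome] + pr.probe_start
            hi = offsets[pr.chromosome] + pr.probe_end  # inclusive ranks
            carriers = np.flatnonzero(rng.random(n) < pr.frequency)
            value = GAIN if pr.aberration_type == "gain" else LOSS
            span = hi - lo + 1
            full = rng.random(carriers.size) < pr.carrier_overlap
            for idx, is_full in zip(carriers, full):
                if is_full or span == 1:
                    vals[idx, lo:hi + 1] = value
                else:
                    sub_len = int(rng.integers(1, span))
                    sub_start = int(rng.integers(0, span - sub_len + 1))
                    vals[idx, lo + sub_start:lo + sub_start + sub_len] = value
            truth_rows.append((
                stage, pr.chromosome, pr.aberration_type, lo, hi,
                int(probe_map.positions[lo]), int(probe_map.positions[hi]),
                pr.frequency, int(carriers.size),
            ))
        sample_ids = [f"{stage}_S{i + 1}" for i in range(n)]
        matrices[stage] = AberrationCallMatrix(vals, sample_ids, probe_map, stage)
    truth = pd.DataFrame(truth_rows, columns=[
        "stage", "chromosome", "type", "l", "r", "start_bp", "end_bp",
        "frequency", "n_carriers",
    ])
    return matrices, probe_map, truth


def simulate_gene_annotation(
    probe_map: ProbeMap,
    n_genes: int,
    length_dist: tuple[int, int] = (2_000, 50_000),
    seed: int = 0,
    anchor_regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Random gene table over the probe map's chromosomes.

    Genes are uniform in position with lengths uniform in ``length_dist``
    (bp, 1-based inclusive coordinates).  If ``anchor_regions`` is given
    (each a ``(chrom, start_bp, end_bp)`` span), three extra genes are
    emitted per region: one fully inside, one straddling the left boundary,
    and one entirely outside — a constructed fixture for containment tests.
    """
    if len(probe_map) == 0:
        raise ValueError("probe map is empty")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo_len, hi_len = length_dist
    if lo_len <= 0 or hi_len < lo_len:
        raise ValueError("invalid length_dist")
    rng = np.random.default_rng(seed)
    chrom_span: dict[str, int] = {}
    for chrom, a, b in probe_map.chromosome_blocks():
        chrom_span[chrom] = int(probe_map.positions[b - 1])
    chrom_names = list(chrom_span)
    rows = []
    for i in range(n_genes):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(1, max(2, chrom_span[chrom] - length + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"G{i + 1:05d}", f"GENE{i + 1}", chrom, start, start + length - 1, strand))
    if anchor_regions:
        for k, (chrom, start_bp, end_bp) in enumerate(anchor_regions):
            width = max(1, (end_bp - start_bp) // 4)
            rows.append((f"GA{k}_in", f"ANCH{k}_IN", chrom,
                         start_bp + width, min(end_bp, start_bp + 2 * width), "+"))
            rows.append((f"GA{k}_straddle", f"ANCH{k}_STR", chrom,
                         max(1, start_bp - width), start_bp + width, "+"))
            rows.append((f"GA{k}_out", f"ANCH{k}_OUT", chrom,
                         end_bp + 10 * width, end_bp + 11 * width, "+"))
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])


def simulate_pathway_db(
    gene_pool: list[str],
    n_pathways: int,
    size_range: tuple[int, int],
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pathway table (pathway_id, name, genes) with controlled overlap.

    Each pathway draws ``round(overlap_fraction * size)`` genes from a shared
    pool of ``max(size_range)`` genes and fills up with genes private to it.
    Different pathway pairs therefore share different (hypergeometrically
    distributed) subsets — the diffuse overlap structure of real pathway
    databases — while the degenerate settings stay exact: overlap 0 gives
    pairwise-disjoint sets, overlap 1 with equal sizes gives identical sets.
    """
    if not gene_pool:
        raise ValueError("gene pool is empty")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    if hi > len(gene_pool):
        raise ValueError("size_range max exceeds the gene pool")
    if not (0 <= overlap_fraction <= 1):
        raise ValueError("overlap_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    pool = list(gene_pool)
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_pathways)]
    shared_size = hi if overlap_fraction > 0 else 0
    shared = list(rng.choice(pool, size=min(shared_size, len(pool)), replace=False))
    rest = [g for g in pool if g not in set(shared)]
    rng.shuffle(rest)
    rows = []
    cursor = 0
    for i, size in enumerate(sizes):
        n_shared = min(int(round(overlap_fraction * size)), size, len(shared))
        genes = list(rng.choice(shared, size=n_shared, replace=False)) if n_shared else []
        need = size - n_shared
        if cursor + need > len(rest):
            raise ValueError("gene pool too small for disjoint pathway parts")
        genes.extend(rest[cursor:cursor + need])
        cursor += need
        rows.append((f"PW{i + 1:04d}", f"Pathway {i + 1}", sorted(genes)))
    return pd.DataFrame(rows, columns=["pathway_id", "name", "genes"])


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
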