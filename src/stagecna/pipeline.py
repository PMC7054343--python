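"""End-to-end orchestration: simulate -> detect -> annotate -> pathways -> network.

A single YAML-style config drives all stages; every intermediate artifact is
written to disk and recorded in a JSON manifest together with the config
hash, master seed and per-stage record counts.  Running twice with the same
config and seed reproduces every output byte for byte (no timestamps are
written anywhere).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import annotation, matrix, network, pathways, recurrence, simulate


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    stage_order: list[str] | None = None
    detection: recurrence.DetectionConfig = dataclasses.field(
        default_factory=recurrence.DetectionConfig)
    sim: simulate.SimConfig | None = None
    call_matrix: str | None = None
    probe_map: str | None = None
    stage_map: str | None = None
    genes_bed: str | None = None
    pathways_gmt: str | None = None
    min_pathway_size: int = 5
    min_stages: int = 2
    gene_basis: str = "hit"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        det = recurrence.DetectionConfig(**raw.pop("detection", {}))
        sim_raw = raw.pop("simulate", None)
        sim_cfg = None
        if sim_raw is not None:
            plants = [simulate.PlantedRegion(**p) for p in sim_raw.pop("planted_regions", [])]
            chroms = [tuple(c) for c in sim_raw.pop("chromosomes")]
            sim_cfg = simulate.SimConfig(planted_regions=plants, chromosomes=chroms, **sim_raw)
        cfg = cls(detection=det, sim=sim_cfg, **raw)
        if cfg.sim is None and not (cfg.call_matrix and cfg.probe_map and cfg.stage_map):
            raise ValueError("config needs either a simulate block or matrix input paths")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.canonical(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _detection_seed(master: int, stage_index: int, type_index: int) -> int:
    ss = np.random.SeedSequence([master, stage_index, type_index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages in order and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages_run": [],
        "stages_skipped": [],
        "counts": {},
        "files": [],
    }

    def record(path: Path) -> None:
        manifest["files"].append(str(path.relative_to(outdir)))

    # ---- simulate or load -------------------------------------------------
    if cfg.sim is not None:
        try:
            matrices, probe_map, truth = simulate.simulate_stage_calls(cfg.sim)
            matrix.write_call_matrices(matrices, outdir / "calls.tsv",
                                       outdir / "stages.tsv")
            probe_map.write_tsv(outdir / "probe_map.tsv")
            simulate.write_truth_table(truth, outdir / "planted_truth.tsv")
            for p in ("calls.tsv", "stages.tsv", "probe_map.tsv", "planted_truth.tsv"):
                record(outdir / p)
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("simulate", exc) from exc
        manifest["stages_run"].append("simulate")
    else:
        try:
            matrices = matrix.read_call_matrix(cfg.call_matrix, cfg.probe_map, cfg.stage_map)
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("load", exc) from exc
        manifest["stages_run"].append("load")

    stage_order = cfg.stage_order or list(matrices)
    missing = sorted(set(matrices) - set(stage_order))
    if missing:
        raise StageFailure("load", ValueError(f"stages missing from stage_order: {missing}"))
    manifest["counts"]["samples_per_stage"] = {s: matrices[s].n_samples for s in stage_order}

    # ---- detect -----------------------------------------------------------
    regions_by_stage: dict[str, list[recurrence.RecurrentRegion]] = {}
    try:
        all_regions: list[recurrence.RecurrentRegion] = []
        for si, stage in enumerate(stage_order):
            al, ad = matrix.split_matrix(matrices[stage])
            stage_regions: list[recurrence.RecurrentRegion] = []
            for ti, B in enumerate((al, ad)):
                det = dataclasses.replace(
                    cfg.detection, seed=_detection_seed(cfg.seed, si, ti))
                res = recurrence.RecurrentAberrationModel(B, det).fit()
                stage_regions.extend(res.regions)
                track = recurrence.frequency_track(B)
                track_path = outdir / f"freq_{stage}_{B.aberration_type}.bedgraph"
                recurrence.write_bedgraph(track, track_path)
                record(track_path)
            regions_by_stage[stage] = stage_regions
            all_regions.extend(stage_regions)
        recurrence.write_regions_tsv(all_regions, outdir / "regions.tsv")
        recurrence.write_regions_bed(all_regions, outdir / "regions.bed")
        record(outdir / "regions.tsv")
        record(outdir / "regions.bed")
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("detect", exc) from exc
    manifest["stages_run"].append("detect")
    manifest["counts"]["regions_per_stage"] = {
        s: len(regions_by_stage[s]) for s in stage_order}

    # ---- annotate ---------------------------------------------------------
    if cfg.genes_bed is None:
        manifest["stages_skipped"].extend(["annotate", "pathways", "network"])
        _write_manifest(manifest, outdir)
        return manifest
    try:
        genes = annotation.read_genes_bed(cfg.genes_bed)
        gene_sets = {
            s: annotation.genes_fully_within(regions_by_stage[s], genes, s)
            for s in stage_order
        }
        annotation.write_stage_gene_sets(gene_sets, outdir / "stage_genes.tsv")
        record(outdir / "stage_genes.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("annotate", exc) from exc
    manifest["stages_run"].append("annotate")
    manifest["counts"]["genes_per_stage"] = {
        s: len(gene_sets[s].all_genes) for s in stage_order}

    # ---- pathways ---------------------------------------------------------
    if cfg.pathways_gmt is None:
        manifest["stages_skipped"].extend(["pathways", "network"])
        _write_manifest(manifest, outdir)
        return manifest
    try:
        db = pathways.read_gmt(cfg.pathways_gmt)
        assigned: list[pathways.StagePathway] = []
        for s in stage_order:
            if gene_sets[s].all_genes:
                assigned.extend(pathways.assign_genes_to_pathways(gene_sets[s], db))
        per_stage = pathways.filter_and_cross_stage(
            assigned, cfg.min_pathway_size, cfg.min_stages)
        pathways.write_stage_pathways(per_stage, outdir / "stage_pathways.tsv")
        record(outdir / "stage_pathways.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("pathways", exc) from exc
    manifest["stages_run"].append("pathways")
    manifest["counts"]["pathways_per_stage"] = {
        s: len(per_stage.get(s, [])) for s in stage_order}

    # ---- network ----------------------------------------------------------
    n_with_pathways = sum(1 for s in stage_order if per_stage.get(s))
    if n_with_pathways < 2:
        manifest["stages_skipped"].append("network")
        _write_manifest(manifest, outdir)
        return manifest
    try:
        net = network.build_evolution_network(
            per_stage, stage_order, gene_basis=cfg.gene_basis, db=db)
        network.export_network(net, "graphml", outdir / "evolution_network.graphml")
        network.export_network(net, "edge-tsv", outdir / "evolution_network.tsv")
        record(outdir / "evolution_network.graphml")
        record(outdir / "evolution_network.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("network", exc) from exc
    manifest["stages_run"].append("network")
    manifest["counts"]["network_nodes"] = net.number_of_nodes()
    manifest["counts"]["network_edges"] = net.number_of_edges()

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
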