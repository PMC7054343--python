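"""Pathway assignment and the size / cross-stage filters.

Aberrant genes of each stage (amplified and deleted pooled) are mapped into
pathways by set membership.  Pathways then pass two filters: the database
gene-set size must exceed ``min_pathway_size`` (strictly, so size-5 sets are
dropped at the default of 5), and the pathway must appear in at least
``min_stages`` distinct stages.  No enrichment statistic is computed —
membership plus filters is the whole procedure.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .annotation import StageGeneSet


@dataclasses.dataclass
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty gene set")


@dataclasses.dataclass
class StagePathway:
    """A pathway observed in one stage with the aberrant genes hitting it."""

    pathway_id: str
    name: str
    stage: str
    hit_genes: frozenset
    pathway_size: int

    def __post_init__(self):
        self.hit_genes = frozenset(self.hit_genes)
        if not self.hit_genes:
            raise ValueError("StagePathway requires at least one hit gene")


def read_gmt(path: str | Path) -> list[Pathway]:
    """Read a GMT file (id <tab> description <tab> gene...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
            out.append(Pathway(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return out


def write_gmt(pathways: list[Pathway] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(pathways, pd.DataFrame):
        pathways = [Pathway(r.pathway_id, r.name, frozenset(r.genes))
                    for r in pathways.itertuples(index=False)]
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def assign_genes_to_pathways(
    stage_set: StageGeneSet, db: list[Pathway],
) -> list[StagePathway]:
    """One StagePathway per pathway intersecting the stage's aberrant genes
    (amplified and deleted pooled; multi-membership of a gene is preserved)."""
    if not db:
        raise ValueError("pathway database is empty")
    genes = stage_set.all_genes
    out = []
    for pw in sorted(db, key=lambda p: p.pathway_id):
        hits = pw.genes & genes
        if hits:
            out.append(StagePathway(pw.pathway_id, pw.name, stage_set.stage,
                                    hits, len(pw.genes)))
    return out


def filter_and_cross_stage(
    records: list[StagePathway],
    min_pathway_size: int = 5,
    min_stages: int = 2,
) -> dict[str, list[StagePathway]]:
    """Apply the strict size filter (keep pathway_size > min_pathway_size),
    deduplicate exact (pathway, stage) repeats, and keep only pathways seen
    in >= min_stages distinct stages.  Returns per-stage lists."""
    if min_pathway_size < 1 or min_stages < 1:
        raise ValueError("filter thresholds must be >= 1")
    sized = [r for r in records if r.pathway_size > min_pathway_size]
    seen: set[tuple[str, str]] = set()
    dedup = []
    for r in sized:
        key = (r.pathway_id, r.stage)
        if key not in seen:
            seen.add(key)
            dedup.append(r)
    stages_of: dict[str, set[str]] = {}
    for r in dedup:
        stages_of.setdefault(r.pathway_id, set()).add(r.stage)
    kept = [r for r in dedup if len(stages_of[r.pathway_id]) >= min_stages]
    out: dict[str, list[StagePathway]] = {}
    for r in sorted(kept, key=lambda r: (r.stage, r.pathway_id)):
        out.setdefault(r.stage, []).append(r)
    return out


def write_stage_pathways(per_stage: dict[str, list[StagePathway]], path: str | Path) -> None:
    rows = []
    for stage in per_stage:
        for r in per_stage[stage]:
            rows.append((stage, r.pathway_id, r.name, r.pathway_size,
                         len(r.hit_genes), ";".join(sorted(r.hit_genes))))
    pd.DataFrame(rows, columns=[
        "stage", "pathway_id", "name", "pathway_size", "n_hit_genes", "hit_genes",
    ]).to_csv(path, sep="\t", index=False)


def read_stage_pathways(path: str | Path) -> dict[str, list[StagePathway]]:
    frame = pd.read_csv(path, sep="\t", dtype={"stage": str, "pathway_id": str,
                                               "name": str, "hit_genes": str})
    out: dict[str, list[StagePathway]] = {}
    for rec in frame.itertuples(index=False):
        out.setdefault(rec.stage, []).append(StagePathway(
            rec.pathway_id, rec.name, rec.stage,
            frozenset(str(rec.hit_genes).split(";")), int(rec.pathway_size),
        ))
    return out
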