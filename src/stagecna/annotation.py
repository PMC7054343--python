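"""Gene annotation of recurrent regions by full interval containment.

A gene is attributed to a region only when its whole span lies inside the
region (closed-interval containment, 1-based inclusive coordinates, both
boundaries counting as inside).  Strand is carried through but ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .recurrence import RecurrentRegion

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


@dataclasses.dataclass
class StageGeneSet:
    """Amplified/deleted gene ids of one stage, with per-gene provenance
    (which significant regions contain the gene)."""

    stage: str
    amplified: set[str]
    deleted: set[str]
    provenance: dict[str, list[str]]

    @property
    def all_genes(self) -> set[str]:
        return self.amplified | self.deleted


def _region_label(reg: RecurrentRegion) -> str:
    return f"{reg.aberration_type}:{reg.chromosome}:{reg.start_bp}-{reg.end_bp}"


def genes_fully_within(
    regions: list[RecurrentRegion], genes: pd.DataFrame, stage: str = "",
) -> StageGeneSet:
    """Select genes fully contained in significant regions, per type.

    gene g is amplified iff some gain region satisfies
    ``region.start_bp <= g.start and g.end <= region.end_bp`` on g's
    chromosome (deleted likewise for loss regions).  A gene may appear in
    both sets via different regions.  Region chromosomes absent from the
    gene table raise, since that almost always signals a naming mismatch
    (e.g. ``chr1`` vs ``1``).
    """
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    gene_chroms = set(genes["chrom"].astype(str))
    unmatched = sorted({reg.chromosome for reg in regions} - gene_chroms)
    if regions and unmatched and not genes.empty:
        raise ValueError(f"region chromosomes absent from gene table: {unmatched}")

    amplified: set[str] = set()
    deleted: set[str] = set()
    provenance: dict[str, list[str]] = {}
    chrom = genes["chrom"].astype(str).to_numpy()
    start = genes["start"].to_numpy(dtype=np.int64)
    end = genes["end"].to_numpy(dtype=np.int64)
    ids = genes["gene_id"].astype(str).to_numpy()
    for reg in regions:
        inside = (chrom == reg.chromosome) & (start >= reg.start_bp) & (end <= reg.end_bp)
        for gid in ids[inside]:
            (amplified if reg.aberration_type == "gain" else deleted).add(gid)
            provenance.setdefault(gid, []).append(_region_label(reg))
    return StageGeneSet(stage, amplified, deleted, provenance)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene table from BED (0-based half-open on disk; converted to
    1-based inclusive).  The name field holds ``gene_id|symbol``."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line with fewer than 4 fields: {line!r}")
            chrom, bed_start, bed_end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "."
            gene_id, _, symbol = name.partition("|")
            rows.append((gene_id, symbol or gene_id, chrom,
                         int(bed_start) + 1, int(bed_end), strand))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in genes.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{int(rec.start) - 1}\t{int(rec.end)}\t"
                     f"{rec.gene_id}|{rec.symbol}\t0\t{rec.strand}\n")


def write_stage_gene_sets(sets_by_stage: dict[str, StageGeneSet], path: str | Path) -> None:
    """Per-stage gene list TSV (stage, type, gene_id, supporting regions)."""
    rows = []
    for stage, sgs in sets_by_stage.items():
        for kind, members in (("gain", sgs.amplified), ("loss", sgs.deleted)):
            for gid in sorted(members):
                support = ";".join(r for r in sgs.provenance.get(gid, [])
                                   if r.startswith(kind))
                rows.append((stage, kind, gid, support))
    pd.DataFrame(rows, columns=["stage", "type", "gene_id", "regions"]).to_csv(
        path, sep="\t", index=False)


def read_stage_gene_sets(path: str | Path) -> dict[str, StageGeneSet]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, StageGeneSet] = {}
    for rec in frame.itertuples(index=False):
        sgs = out.setdefault(rec.stage, StageGeneSet(rec.stage, set(), set(), {}))
        (sgs.amplified if rec.type == "gain" else sgs.deleted).add(rec.gene_id)
        if rec.regions:
            sgs.provenance.setdefault(rec.gene_id, []).extend(rec.regions.split(";"))
    return out
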