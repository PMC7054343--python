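"""Pathway evolution network across adjacent pathology stages.

Nodes are pathways (with the set of stages they appear in); an edge connects
two distinct pathways observed in consecutive stages whenever they share
genes, weighted by the overlap score

    W = k^2 / (p * q)

with k the shared gene count and p, q the two gene-set sizes.  By default
the stage-specific hit-gene sets are compared (so W evolves with the
stages); ``gene_basis="full"`` compares the full database gene sets instead.

The container is a :class:`networkx.MultiGraph` keyed by stage pair, since
the same pathway pair can be linked across several adjacent stage pairs
with different weights.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .pathways import Pathway, StagePathway


def overlap_score(genes_i: frozenset | set, genes_j: frozenset | set) -> tuple[int, int, int, float]:
    """(k, p, q, W) for two non-empty gene sets; W = k^2/(p*q) in [0,1],
    reaching 1 exactly when the sets are identical."""
    if not genes_i or not genes_j:
        raise ValueError("overlap score requires non-empty gene sets")
    k = len(set(genes_i) & set(genes_j))
    p, q = len(genes_i), len(genes_j)
    return k, p, q, (k * k) / (p * q)


def build_evolution_network(
    per_stage: dict[str, list[StagePathway]],
    stage_order: list[str],
    gene_basis: str = "hit",
    db: list[Pathway] | None = None,
) -> nx.MultiGraph:
    """Connect gene-sharing pathways of consecutive stages.

    Edges carry ``stage_pair``, ``k``, ``p``, ``q``, ``W``; nodes carry the
    pathway name, their stage membership and a size attribute (total
    distinct hit genes across stages).  Self pairs (same pathway in both
    stages) become node stage-membership, never edges.
    """
    unknown = sorted(set(per_stage) - set(stage_order))
    if unknown:
        raise ValueError(f"stages absent from stage_order: {unknown}")
    present = [s for s in stage_order if s in per_stage and per_stage[s]]
    if len(present) < 2:
        raise ValueError("evolution network needs pathways in at least 2 stages")
    if gene_basis not in ("hit", "full"):
        raise ValueError("gene_basis must be 'hit' or 'full'")
    full_sets: dict[str, frozenset] = {}
    if gene_basis == "full":
        if db is None:
            raise ValueError("gene_basis='full' requires the pathway database")
        full_sets = {pw.pathway_id: frozenset(pw.genes) for pw in db}

    net = nx.MultiGraph()
    hit_union: dict[str, set] = {}
    names: dict[str, str] = {}
    stages_of: dict[str, list[str]] = {}
    for stage in stage_order:
        for rec in per_stage.get(stage, []):
            names[rec.pathway_id] = rec.name
            hit_union.setdefault(rec.pathway_id, set()).update(rec.hit_genes)
            stages_of.setdefault(rec.pathway_id, [])
            if stage not in stages_of[rec.pathway_id]:
                stages_of[rec.pathway_id].append(stage)
    for pid in sorted(names):
        net.add_node(
            pid,
            name=names[pid],
            stages=";".join(stages_of[pid]),
            n_hit_genes=len(hit_union[pid]),
        )

    def basis(rec: StagePathway) -> frozenset:
        if gene_basis == "hit":
            return rec.hit_genes
        if rec.pathway_id not in full_sets:
            raise ValueError(f"pathway {rec.pathway_id!r} missing from database")
        return full_sets[rec.pathway_id]

    for s, t in zip(stage_order, stage_order[1:]):
        left = sorted(per_stage.get(s, []), key=lambda r: r.pathway_id)
        right = sorted(per_stage.get(t, []), key=lambda r: r.pathway_id)
        pair_label = f"{s}|{t}"
        for ri in left:
            for rj in right:
                if ri.pathway_id == rj.pathway_id:
                    continue
                gi, gj = basis(ri), basis(rj)
                k = len(gi & gj)
                if k == 0:
                    continue
                _, p, q, w = overlap_score(gi, gj)
                a, b = sorted((ri.pathway_id, rj.pathway_id))
                if not net.has_edge(a, b, key=pair_label):
                    net.add_edge(a, b, key=pair_label,
                                 stage_pair=pair_label, k=k, p=p, q=q, W=w)
    return net


def edge_table(net: nx.MultiGraph) -> pd.DataFrame:
    rows = [
        (min(u, v), max(u, v), d["stage_pair"], d["k"], d["p"], d["q"], d["W"])
        for u, v, d in net.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=[
        "pathway_i", "pathway_j", "stage_pair", "k", "p", "q", "W",
    ])
    return frame.sort_values(["stage_pair", "pathway_i", "pathway_j"]).reset_index(drop=True)


def export_network(net: nx.MultiGraph, fmt: str, path: str | Path) -> None:
    """Write the network as graphml, sif (+ .edges.tsv attributes) or edge-tsv."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(net.edges(data=True),
                                  key=lambda e: (e[2]["stage_pair"], min(e[0], e[1]), max(e[0], e[1]))):
                fh.write(f"{min(u, v)}\t{d['stage_pair']}\t{max(u, v)}\n")
        edge_table(net).to_csv(path.with_suffix(path.suffix + ".edges.tsv"),
                               sep="\t", index=False)
    elif fmt == "edge-tsv":
        edge_table(net).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def read_graphml(path: str | Path) -> nx.MultiGraph:
    """Read a GraphML export back as a MultiGraph (keys preserved)."""
    return nx.read_graphml(path, force_multigraph=True)
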