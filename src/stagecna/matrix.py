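"""Core matrix containers and file I/O for aberration-call data.

The pipeline's central object is a ternary call matrix A (samples x probes,
with +1 gain / -1 loss / 0 neutral per cell) grouped by pathology stage, plus
a probe map giving each marker a genomic coordinate.  A is split into two
binary indicator matrices, one per aberration type, before detection.

Coordinate conventions: in-memory genomic intervals are 1-based inclusive;
BED on disk is 0-based half-open and converted at the I/O boundary only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

GAIN = 1
LOSS = -1
NEUTRAL = 0

_TYPE_TO_VALUE = {"gain": GAIN, "loss": LOSS}


class ProbeMap:
    """Ordered genome-wide marker map.

    Wraps a DataFrame with columns ``probe_id``, ``chrom``, ``pos`` (1-based
    bp).  Probes are kept in genome order: chromosomes in order of first
    appearance, positions strictly increasing within a chromosome.  The row
    index after ordering is the genome-wide probe rank (0-based).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        frame = frame.loc[:, ["probe_id", "chrom", "pos"]].copy()
        frame["chrom"] = frame["chrom"].astype(str)
        frame["pos"] = frame["pos"].astype(np.int64)
        if frame["probe_id"].duplicated().any():
            dup = frame.loc[frame["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicated probe id: {dup!r}")
        chrom_order = list(dict.fromkeys(frame["chrom"]))
        rank_of_chrom = {c: i for i, c in enumerate(chrom_order)}
        order = np.lexsort(
            (frame["pos"].to_numpy(), frame["chrom"].map(rank_of_chrom).to_numpy())
        )
        frame = frame.iloc[order].reset_index(drop=True)
        for chrom, sub in frame.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.frame = frame
        self.chrom_order = [c for c in chrom_order]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeMap) and self.frame.equals(other.frame)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.frame["probe_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    def chromosome_blocks(self) -> Iterator[tuple[str, int, int]]:
        """Yield ``(chrom, start_rank, stop_rank)`` half-open rank spans."""
        chroms = self.chroms
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                yield str(chroms[start]), start, i
                start = i

    def block_bounds(self) -> np.ndarray:
        """Per-probe ``(block_start, block_stop)`` rank bounds, half-open."""
        bounds = np.empty((len(self), 2), dtype=np.int64)
        for _, a, b in self.chromosome_blocks():
            bounds[a:b, 0] = a
            bounds[a:b, 1] = b
        return bounds

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProbeMap":
        frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
        return cls(frame)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class AberrationCallMatrix:
    """Ternary call matrix for one pathology stage (+1 gain, -1 loss, 0 none)."""

    values: np.ndarray
    sample_ids: list[str]
    probe_map: ProbeMap
    stage: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x probes)")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one sample and one probe")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.probe_map) != m:
            raise ValueError("probe_map length does not match column count")
        bad = ~np.isin(self.values, (-1, 0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"cell outside {{-1,0,1}} at sample {self.sample_ids[i]!r}, "
                f"probe {self.probe_map.probe_ids[j]!r}: {self.values[i, j]}"
            )
        if len(set(self.sample_ids)) != n:
            seen: set[str] = set()
            for s in self.sample_ids:
                if s in seen:
                    raise ValueError(f"duplicated sample id: {s!r}")
                seen.add(s)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class BinaryAberrationMatrix:
    """0/1 indicator matrix for a single aberration type (gain or loss)."""

    values: np.ndarray
    aberration_type: str
    sample_ids: list[str]
    probe_map: ProbeMap
    stage: str = ""

    def __post_init__(self):
        if self.aberration_type not in _TYPE_TO_VALUE:
            raise ValueError(f"aberration_type must be gain|loss, got {self.aberration_type!r}")
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix cells must be 0 or 1")
        if len(self.probe_map) != self.values.shape[1]:
            raise ValueError("probe_map length does not match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


def split_matrix(A: AberrationCallMatrix) -> tuple[BinaryAberrationMatrix, BinaryAberrationMatrix]:
    """Split a ternary matrix into gain (AL) and loss (AD) indicator matrices.

    AL - AD reconstructs A exactly, and AL*AD = 0 elementwise.
    """
    al = BinaryAberrationMatrix(
        (A.values == GAIN).astype(np.int8), "gain", list(A.sample_ids), A.probe_map, A.stage
    )
    ad = BinaryAberrationMatrix(
        (A.values == LOSS).astype(np.int8), "loss", list(A.sample_ids), A.probe_map, A.stage
    )
    return al, ad


def discretize_log2(
    seg_values: pd.DataFrame, gain_thr: float, loss_thr: float, *,
    probe_map: ProbeMap | None = None, stage: str = "",
) -> AberrationCallMatrix:
    """Threshold a samples x probes log2-ratio matrix into ternary calls.

    Strict inequalities: value > gain_thr -> +1, value < loss_thr -> -1,
    anything else (ties at a threshold included) -> 0.
    """
    if not (gain_thr > 0 > loss_thr):
        raise ValueError("need gain_thr > 0 > loss_thr")
    arr = seg_values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite log2 value at sample {seg_values.index[i]!r}, "
            f"probe {seg_values.columns[j]!r}"
        )
    calls = np.zeros(arr.shape, dtype=np.int8)
    calls[arr > gain_thr] = GAIN
    calls[arr < loss_thr] = LOSS
    if probe_map is None:
        probe_map = ProbeMap(pd.DataFrame({
            "probe_id": [str(c) for c in seg_values.columns],
            "chrom": "chr1",
            "pos": np.arange(1, arr.shape[1] + 1),
        }))
    return AberrationCallMatrix(calls, [str(s) for s in seg_values.index], probe_map, stage)


def expand_segments(seg: pd.DataFrame, probe_map: ProbeMap) -> pd.DataFrame:
    """Expand SEG-like records (sample, chrom, start, end, log2) to a
    samples x probes log2 matrix on the probe map (1-based inclusive spans).

    Probes not covered by any segment of a sample get 0.0.
    """
    for col in ("sample", "chrom", "start", "end", "log2"):
        if col not in seg.columns:
            raise ValueError(f"segment table missing column {col!r}")
    samples = list(dict.fromkeys(seg["sample"].astype(str)))
    mat = np.zeros((len(samples), len(probe_map)), dtype=float)
    row_of = {s: i for i, s in enumerate(samples)}
    chroms = probe_map.chroms
    pos = probe_map.positions
    for rec in seg.itertuples(index=False):
        mask = (chroms == str(rec.chrom)) & (pos >= int(rec.start)) & (pos <= int(rec.end))
        mat[row_of[str(rec.sample)], mask] = float(rec.log2)
    return pd.DataFrame(mat, index=samples, columns=probe_map.probe_ids)


def read_call_matrix(
    path: str | Path, probe_map_path: str | Path, stage_map_path: str | Path,
) -> dict[str, AberrationCallMatrix]:
    """Read a call-matrix TSV plus probe map and stage sidecar.

    The matrix TSV has sample ids in the first column and probe ids as the
    header; cells are in {-1,0,1}.  Columns are re-sorted into genome order,
    so downstream results do not depend on the column order on disk.
    Returns one matrix per stage, keyed by stage label.
    """
    probe_map = ProbeMap.read_tsv(probe_map_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    known = set(probe_map.probe_ids)
    for col in raw.columns:
        if col not in known:
            raise ValueError(f"unknown probe id in matrix: {col!r}")
    if set(raw.columns) != known:
        missing = sorted(known - set(raw.columns))
        raise ValueError(f"matrix is missing probes from the probe map: {missing[:5]}")
    # re-sort to genome order
    raw = raw.loc[:, list(probe_map.probe_ids)]

    stage_map = pd.read_csv(stage_map_path, sep="\t", dtype=str)
    if not {"sample_id", "stage"} <= set(stage_map.columns):
        raise ValueError("stage sidecar needs columns sample_id, stage")
    stage_of = dict(zip(stage_map["sample_id"], stage_map["stage"]))
    for s in raw.index:
        if s not in stage_of:
            raise ValueError(f"sample without stage label: {s!r}")

    out: dict[str, AberrationCallMatrix] = {}
    stages_in_order = list(dict.fromkeys(stage_of[s] for s in raw.index))
    for stage in stages_in_order:
        rows = [s for s in raw.index if stage_of[s] == stage]
        sub = raw.loc[rows]
        out[stage] = AberrationCallMatrix(
            sub.to_numpy(), [str(s) for s in rows], probe_map, stage
        )
    return out


def write_call_matrices(
    matrices: Mapping[str, AberrationCallMatrix],
    path: str | Path, stage_map_path: str | Path,
) -> None:
    """Write per-stage matrices as one TSV plus the stage sidecar."""
    frames = []
    stage_rows = []
    for stage, mat in matrices.items():
        frames.append(pd.DataFrame(
            mat.values, index=mat.sample_ids, columns=mat.probe_map.probe_ids
        ))
        stage_rows.extend((s, stage) for s in mat.sample_ids)
    combined = pd.concat(frames)
    combined.index.name = "sample_id"
    combined.to_csv(path, sep="\t")
    pd.DataFrame(stage_rows, columns=["sample_id", "stage"]).to_csv(
        stage_map_path, sep="\t", index=False
    )
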