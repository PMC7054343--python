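"""Recurrent-aberration detection: permutation significance + homogeneous peel-off.

For one binary aberration matrix B (samples x markers, one aberration type,
one pathology stage) the detector:

1. scores every marker with a permutation test on the number of aberrant
   samples, turning counts into p-values and Benjamini-Hochberg q-values;
2. measures per-junction homogeneity h_j, the mean over samples of a
   state-change penalty between adjacent markers;
3. iteratively takes the most significant marker (minimum q), expands its
   boundaries left/right while the neighbouring marker stays significant
   (q <= q_thr) and the junction stays homogeneous (h <= h_thr), records the
   region, then peels off the supporting samples' calls inside it so that
   further independent regions can surface.

The permutation null shuffles each sample's calls across the markers of a
chromosome, preserving the per-sample aberration load.  Under that shuffle
the count at any fixed marker is a sum of independent Bernoulli(k_i / M_c)
indicators (k_i = sample i's load, M_c = markers on the chromosome), i.e.
Poisson-binomial, and is evaluated in closed form.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import AberrationCallMatrix, BinaryAberrationMatrix


@dataclasses.dataclass
class DetectionConfig:
    """Tuning knobs of the detector.

    q_thr: FDR significance threshold (regions require q <= q_thr).
    h_thr: junction homogeneity threshold in [0,1]; 0 forbids expansion
        across any junction where even one sample changes state.
    n_perm: Monte-Carlo permutations per significance profile.
    max_iterations: cap on peel-off rounds (hence on regions per type).
    seed: seed for the permutation stream.
    """

    q_thr: float = 0.10
    h_thr: float = 0.12
    n_perm: int = 10_000
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.q_thr < 1):
            raise ValueError("q_thr must be in (0,1)")
        if not (0 <= self.h_thr <= 1):
            raise ValueError("h_thr must be in [0,1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclasses.dataclass
class SignificanceProfile:
    """Per-marker aberration counts with permutation p- and BH q-values."""

    counts: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_perm: int
    aberration_type: str


@dataclasses.dataclass
class RecurrentRegion:
    """A contiguous significant marker interval found by one peel-off round."""

    chromosome: str
    l: int                  # left boundary, 0-based genome rank
    r: int                  # right boundary, 0-based genome rank (inclusive)
    start_bp: int
    end_bp: int
    aberration_type: str
    peak_q: float
    peak_rank: int
    frequency: float        # aberrant samples at the peak / N
    iteration: int
    stage: str = ""


def marker_counts(B: BinaryAberrationMatrix) -> np.ndarray:
    """Number of aberrant samples at every marker (the observed statistic)."""
    return B.values.sum(axis=0).astype(np.int64)


def poisson_binomial_tail(rates: np.ndarray) -> np.ndarray:
    """Upper-tail P(X >= c) for c = 0..N, X a sum of independent
    Bernoulli(rates) indicators, by iterative convolution of the pmf."""
    rates = np.asarray(rates, dtype=float)
    pmf = np.array([1.0])
    for r in rates:
        pmf = np.convolve(pmf, [1.0 - r, r])
    tail = np.cumsum(pmf[::-1])[::-1]
    return np.clip(tail, 0.0, 1.0)


def permutation_pvalues(
    B: BinaryAberrationMatrix, cfg: DetectionConfig,
) -> SignificanceProfile:
    """Per-marker permutation p-values with the add-one convention.

    The null permutes each sample's calls across the markers of a
    chromosome, preserving the per-sample aberration load k_i.  At any fixed
    marker the permuted rows are independent Bernoulli(k_i / M_c), so the
    null count is Poisson-binomial and its tail is computed in closed form —
    the exact expectation of the add-one Monte-Carlo estimator

        p_j = (1 + n_perm * P(null >= count_j)) / (1 + n_perm)

    over the shuffle distribution, with zero sampling variance.  n_perm sets
    the estimator's floor 1/(1 + n_perm): p-values never reach 0.
    """
    if B.n_samples < 2:
        raise ValueError("permutation test needs at least 2 samples")
    counts = marker_counts(B)
    p = np.ones(B.n_probes, dtype=float)
    for _, a, b in B.probe_map.chromosome_blocks():
        m_c = b - a
        loads = B.values[:, a:b].sum(axis=1)
        tail = poisson_binomial_tail(loads / m_c)
        p[a:b] = (1.0 + cfg.n_perm * tail[counts[a:b]]) / (1.0 + cfg.n_perm)
    q = bh_qvalues(p)
    return SignificanceProfile(counts, p, q, cfg.n_perm, B.aberration_type)


def bh_qvalues(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0,1]."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def homogeneity_matrix(B: BinaryAberrationMatrix | np.ndarray) -> np.ndarray:
    """Per-sample homogeneity between adjacent markers.

    H_ij = |state_ij - state_i,j+1| / 2: 0 when the two states are identical
    (maximum homogeneity), 0.5 when exactly one of the pair is neutral
    (medium), 1 when the states are opposite aberrations (minimum).  On a
    0/1 matrix this reduces to 0 = no change, 0.5 = the sample's aberration
    starts or ends at the junction.
    """
    vals = B.values if isinstance(B, BinaryAberrationMatrix) else np.asarray(B)
    if vals.shape[1] < 2:
        raise ValueError("homogeneity needs at least 2 markers")
    return np.abs(np.diff(vals.astype(float), axis=1)) / 2.0


def h_profile(H: np.ndarray) -> np.ndarray:
    """Junction homogeneity profile: h_j = column mean of H, in [0,1]."""
    H = np.asarray(H, dtype=float)
    return H.mean(axis=0)


def expand_peak(
    q: np.ndarray,
    h: np.ndarray,
    peak_rank: int,
    cfg: DetectionConfig,
    block_bounds: tuple[int, int],
) -> tuple[int, int]:
    """Grow a peak into a region while neighbours stay significant and
    junctions homogeneous.

    The left boundary moves to l-1 while q[l-1] <= q_thr and h[l-1] <= h_thr;
    the right boundary moves to r+1 while q[r+1] <= q_thr and h[r] <= h_thr
    (h[j] is the junction between ranks j and j+1).  Expansion never crosses
    the chromosome bounds ``block_bounds`` (half-open rank span).
    """
    lo, hi = block_bounds
    if not (lo <= peak_rank < hi):
        raise ValueError("peak_rank outside its chromosome block")
    if q[peak_rank] > cfg.q_thr:
        raise ValueError("peak marker is not significant")
    l = r = int(peak_rank)
    while l - 1 >= lo and q[l - 1] <= cfg.q_thr and h[l - 1] <= cfg.h_thr:
        l -= 1
    while r + 1 < hi and q[r + 1] <= cfg.q_thr and h[r] <= cfg.h_thr:
        r += 1
    return l, r


class RecurrentAberrationModel:
    """Detector for one binary aberration matrix (one type, one stage).

    Parameters
    ----------
    B : BinaryAberrationMatrix
        Gain or loss indicator matrix with its probe map.
    config : DetectionConfig, optional
        Detection thresholds; defaults follow q_thr=0.10, h_thr=0.12,
        n_perm=10000, max_iterations=10.

    ``fit()`` runs the full significance + homogeneous peel-off loop and
    returns a :class:`RecurrenceResults`.
    """

    def __init__(self, B: BinaryAberrationMatrix, config: DetectionConfig | None = None):
        self.B = B
        self.config = config or DetectionConfig()

    def fit(self) -> "RecurrenceResults":
        cfg = self.config
        B = self.B
        work = B.values.copy()
        bounds = B.probe_map.block_bounds()
        positions = B.probe_map.positions
        chroms = B.probe_map.chroms
        n = B.n_samples

        regions: list[RecurrentRegion] = []
        profiles: list[SignificanceProfile] = []
        for iteration in range(1, cfg.max_iterations + 1):
            current = BinaryAberrationMatrix(
                work, B.aberration_type, list(B.sample_ids), B.probe_map, B.stage
            )
            prof = permutation_pvalues(current, cfg)
            profiles.append(prof)
            if prof.q_values.min() > cfg.q_thr:
                break
            peak = int(np.argmin(prof.q_values))  # ties -> lowest genome rank
            h = h_profile(homogeneity_matrix(work))
            lo, hi = int(bounds[peak, 0]), int(bounds[peak, 1])
            l, r = expand_peak(prof.q_values, h, peak, cfg, (lo, hi))
            regions.append(RecurrentRegion(
                chromosome=str(chroms[peak]),
                l=l, r=r,
                start_bp=int(positions[l]), end_bp=int(positions[r]),
                aberration_type=B.aberration_type,
                peak_q=float(prof.q_values[peak]),
                peak_rank=peak,
                frequency=float(prof.counts[peak]) / n,
                iteration=iteration,
                stage=B.stage,
            ))
            carriers = work[:, peak] == 1
            work[np.ix_(carriers, np.arange(l, r + 1))] = 0
        return RecurrenceResults(self, regions, profiles)


class RecurrenceResults:
    """Regions found by the peel-off loop plus per-iteration significance."""

    def __init__(self, model: RecurrentAberrationModel,
                 regions: list[RecurrentRegion],
                 profiles: list[SignificanceProfile]):
        self.model = model
        self.regions = regions
        self.profiles = profiles

    @property
    def significance(self) -> SignificanceProfile:
        """The first-iteration profile, i.e. of the unpeeled matrix."""
        return self.profiles[0]

    def regions_frame(self) -> pd.DataFrame:
        cols = ["stage", "aberration_type", "chromosome", "l", "r",
                "start_bp", "end_bp", "peak_rank", "peak_q", "frequency", "iteration"]
        rows = [[getattr(reg, c) for c in cols] for reg in self.regions]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        B = self.model.B
        cfg = self.model.config
        lines = [
            "Recurrent aberration detection",
            "==============================",
            f"stage: {B.stage or '-'}   type: {B.aberration_type}",
            f"samples: {B.n_samples}   markers: {B.n_probes}",
            f"q_thr: {cfg.q_thr}   h_thr: {cfg.h_thr}   n_perm: {cfg.n_perm}",
            f"peel-off iterations run: {len(self.profiles)}   regions: {len(self.regions)}",
            "",
        ]
        if self.regions:
            lines.append(self.regions_frame().to_string(index=False,
                                                        float_format=lambda v: f"{v:.4g}"))
        else:
            lines.append("(no significant regions)")
        return "\n".join(lines)


def detect_recurrent_regions(
    B: BinaryAberrationMatrix, cfg: DetectionConfig | None = None,
) -> list[RecurrentRegion]:
    """Functional wrapper over :class:`RecurrentAberrationModel`."""
    return RecurrentAberrationModel(B, cfg).fit().regions


@dataclasses.dataclass(frozen=True)
class SharedRun:
    """A maximal bicluster: a contiguous marker interval and the samples that
    all carry the same non-zero state across it."""

    chromosome: str
    l: int
    r: int
    samples: frozenset
    state: str  # gain|loss


def find_shared_runs(
    A: AberrationCallMatrix, min_samples: int = 2, min_span: int = 1,
) -> list[SharedRun]:
    """All maximal (interval x sample-set) blocks of identical non-zero state.

    A block is maximal when extending the interval one probe left or right
    would shrink its sample set; the sample set is always the full set of
    samples matching the state over the interval, so it cannot be extended.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if min_span < 1:
        raise ValueError("min_span must be >= 1")
    vals = A.values
    ids = np.asarray(A.sample_ids, dtype=object)
    out: list[SharedRun] = []
    for chrom, lo, hi in A.probe_map.chromosome_blocks():
        for state, label in ((1, "gain"), (-1, "loss")):
            match = vals[:, lo:hi] == state  # N x block
            m = hi - lo
            for a in range(m):
                cur = match[:, a].copy()
                if cur.sum() < min_samples:
                    continue
                for b in range(a, m):
                    if b > a:
                        cur &= match[:, b]
                        if cur.sum() < min_samples:
                            break
                    span = b - a + 1
                    left_max = a == 0 or not np.array_equal(cur & match[:, a - 1], cur)
                    right_max = b == m - 1 or not np.array_equal(cur & match[:, b + 1], cur)
                    if span >= min_span and left_max and right_max:
                        out.append(SharedRun(
                            chrom, lo + a, lo + b,
                            frozenset(ids[cur]), label,
                        ))
    return out


def frequency_track(B: BinaryAberrationMatrix) -> pd.DataFrame:
    """Per-marker aberration frequency as a genome track
    (chrom, pos, frequency, type)."""
    counts = marker_counts(B)
    return pd.DataFrame({
        "chrom": B.probe_map.chroms,
        "pos": B.probe_map.positions,
        "frequency": counts / B.n_samples,
        "type": B.aberration_type,
    })


def write_regions_tsv(regions: list[RecurrentRegion], path) -> None:
    cols = ["stage", "aberration_type", "chromosome", "l", "r", "start_bp",
            "end_bp", "peak_rank", "peak_q", "frequency", "iteration"]
    rows = [[getattr(reg, c) for c in cols] for reg in regions]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path) -> list[RecurrentRegion]:
    frame = pd.read_csv(path, sep="\t", dtype={"stage": str, "chromosome": str})
    out = []
    for rec in frame.itertuples(index=False):
        out.append(RecurrentRegion(
            chromosome=str(rec.chromosome), l=int(rec.l), r=int(rec.r),
            start_bp=int(rec.start_bp), end_bp=int(rec.end_bp),
            aberration_type=str(rec.aberration_type), peak_q=float(rec.peak_q),
            peak_rank=int(rec.peak_rank), frequency=float(rec.frequency),
            iteration=int(rec.iteration), stage=str(rec.stage),
        ))
    return out


def write_regions_bed(regions: list[RecurrentRegion], path) -> None:
    """BED export of regions (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for reg in regions:
            name = f"{reg.stage}_{reg.aberration_type}_it{reg.iteration}"
            fh.write(f"{reg.chromosome}\t{reg.start_bp - 1}\t{reg.end_bp}\t{name}\n")


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a frequency track as bedGraph (0-based half-open 1-bp bins)."""
    out = pd.DataFrame({
        "chrom": track["chrom"],
        "start": track["pos"] - 1,
        "end": track["pos"],
        "value": track["frequency"].map(lambda v: f"{v:.6g}"),
    })
    out.to_csv(path, sep="\t", index=False, header=False)
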