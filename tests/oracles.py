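"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: exhaustive
enumeration for the permutation null and the bicluster search, direct
formula evaluation for BH and containment.
"""

from functools import lru_cache
from itertools import combinations, product

import numpy as np


@lru_cache(maxsize=None)
def exact_null_tail(m: int, loads: tuple) -> np.ndarray:
    """P(null count at a marker >= c) for c = 0..len(loads), by enumerating
    every joint arrangement of each row's `load` ones over m markers
    (single chromosome).  By exchangeability every marker has the same tail;
    the tally below averages over markers of the full joint enumeration."""
    n = len(loads)
    row_arrangements = [list(combinations(range(m), k)) for k in loads]
    tail_hits = np.zeros((m, n + 1), dtype=np.int64)
    total = 0
    for arrangement in product(*row_arrangements):
        counts = np.zeros(m, dtype=np.int64)
        for positions in arrangement:
            for j in positions:
                counts[j] += 1
        total += 1
        for j in range(m):
            tail_hits[j, : counts[j] + 1] += 1
    tails = tail_hits / total
    assert np.allclose(tails, tails[0]), "markers must be exchangeable"
    return tails[0]


def exact_pvalues(values: np.ndarray) -> np.ndarray:
    """Exact per-marker p-values P(null >= observed) for a single-chromosome
    binary matrix, via full enumeration."""
    n, m = values.shape
    loads = tuple(int(v) for v in values.sum(axis=1))
    tail = exact_null_tail(m, loads)
    counts = values.sum(axis=0)
    return np.array([tail[c] for c in counts])


def bh_by_hand(p: np.ndarray) -> np.ndarray:
    """q_i = min over k with p_(k) >= p_(i) of m * p_(k) / k, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


def brute_force_containment(regions, genes) -> dict:
    """All-pairs closed-interval containment; returns gene_id -> set of types."""
    out: dict = {}
    for _, g in genes.iterrows():
        for reg in regions:
            if (str(g["chrom"]) == reg.chromosome
                    and reg.start_bp <= g["start"] and g["end"] <= reg.end_bp):
                out.setdefault(g["gene_id"], set()).add(reg.aberration_type)
    return out


def brute_force_biclusters(values, sample_ids, min_samples, min_span):
    """Enumerate every (interval, state) on a single-chromosome ternary
    matrix, take its full sample set, and keep the maximal ones."""
    n, m = values.shape
    found = set()
    for state, label in ((1, "gain"), (-1, "loss")):
        for a in range(m):
            for b in range(a, m):
                rows = frozenset(
                    sample_ids[i] for i in range(n)
                    if all(values[i, j] == state for j in range(a, b + 1))
                )
                if len(rows) < min_samples or b - a + 1 < min_span:
                    continue

                def sset(aa, bb):
                    return frozenset(
                        sample_ids[i] for i in range(n)
                        if all(values[i, j] == state for j in range(aa, bb + 1)))

                if a > 0 and sset(a - 1, b) == rows:
                    continue
                if b < m - 1 and sset(a, b + 1) == rows:
                    continue
                found.add((label, a, b, rows))
    return found
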