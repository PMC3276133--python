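"""Independent brute-force oracles used by the test suite.

Every function here recomputes a pipeline quantity by exhaustive
enumeration or fine-grid evaluation, sharing no code with the
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations, permutations, product

import numpy as np


# ---------------------------------------------------------------------------
# rank product


def _ranks_descending_avg(col: np.ndarray) -> np.ndarray:
    """Descending ranks with average ties, written from the definition."""
    n = len(col)
    order = np.argsort(-col, kind="stable")
    sorted_vals = col[order]
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for m in range(i, j + 1):
            ranks[order[m]] = avg
        i = j + 1
    return ranks


def _ranks_ascending_avg(col: np.ndarray) -> np.ndarray:
    return _ranks_descending_avg(-col)


def rank_product_pfp_oracle(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(RP geometric mean, pfp) by full enumeration of every per-replicate
    rank permutation."""
    n, k = scores.shape
    R = np.column_stack([_ranks_descending_avg(scores[:, j]) for j in range(k)])
    obs = R.prod(axis=1)
    cols = [list(permutations(R[:, j])) for j in range(k)]
    counts = np.zeros(n)
    total = 0
    for combo in product(*cols):
        null = np.prod(np.array(combo).T, axis=1)
        for g in range(n):
            counts[g] += int(np.sum(null <= obs[g] * (1 + 1e-12)))
        total += 1
    c = counts / total
    pfp = c / _ranks_ascending_avg(obs)
    return obs ** (1.0 / k), pfp


# ---------------------------------------------------------------------------
# locus calling


def detect_loci_oracle(
    genes: list[tuple[str, float | None, bool]],
    threshold: float = 1.6,
    min_adjacent: int = 2,
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Loci and singletons on ONE chromosome by enumerating every
    contiguous window.

    ``genes`` is ordered (gene_id, score or None, on_array).  A window is a
    locus iff its endpoints qualify, every on-array member qualifies, it
    has >= min_adjacent qualifying members, and no qualifying gene adjoins
    it across (possibly several) off-array genes.  A qualifying gene whose
    nearest on-array neighbours on both sides fail the threshold is a
    singleton.
    """
    n = len(genes)
    qual = [
        on and s is not None and s >= threshold for _, s, on in genes
    ]
    on_arr = [on for _, _, on in genes]

    def nearest_on_array(i: int, step: int) -> int | None:
        j = i + step
        while 0 <= j < n:
            if on_arr[j]:
                return j
            j += step
        return None

    loci = []
    for i in range(n):
        for j in range(i, n):
            if not (qual[i] and qual[j]):
                continue
            if any(on_arr[m] and not qual[m] for m in range(i, j + 1)):
                continue
            nq = sum(1 for m in range(i, j + 1) if qual[m])
            if nq < min_adjacent:
                continue
            left = nearest_on_array(i, -1)
            right = nearest_on_array(j, +1)
            if left is not None and qual[left]:
                continue
            if right is not None and qual[right]:
                continue
            loci.append(tuple(genes[m][0] for m in range(i, j + 1)))
    singles = []
    for i in range(n):
        if not qual[i]:
            continue
        left = nearest_on_array(i, -1)
        right = nearest_on_array(i, +1)
        if (left is None or not qual[left]) and (right is None or not qual[right]):
            singles.append(genes[i][0])
    return loci, singles


# ---------------------------------------------------------------------------
# growth-curve math


def doubling_time_oracle(
    times: np.ndarray,
    od: np.ndarray,
    min_points: int = 5,
    r2_tolerance: float = 0.005,
) -> float:
    """Exhaustive window search over the OD band [2*first reading, max/2]:
    longest window (earliest on ties) whose log-linear R^2 is within the
    tolerance of the best window's."""
    blank = od[0]
    ok = (od >= 2 * blank) & (od <= od.max() / 2) & (od > 0)
    cands = []
    n = len(od)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            if not ok[i : j + 1].all():
                continue
            t = times[i : j + 1]
            y = np.log(od[i : j + 1])
            slope, intercept = np.polyfit(t, y, 1)
            if slope <= 0:
                continue
            r2 = float(np.corrcoef(t, y)[0, 1] ** 2)
            cands.append((r2, j - i + 1, -i, np.log(2) / slope))
    if not cands:
        raise ValueError("no increasing window")
    r2_best = max(c[0] for c in cands)
    best = max(
        (c for c in cands if c[0] >= r2_best - r2_tolerance),
        key=lambda c: (c[1], c[2]),
    )
    return best[3]


def augc_riemann_oracle(
    times: np.ndarray, od: np.ndarray, window_hours: float = 24.0, n_grid: int = 10_000
) -> float:
    """Midpoint Riemann sum on a fine grid over the linear interpolant."""
    t_end = times[0] + window_hours * 60.0
    edges = np.linspace(times[0], t_end, n_grid + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    vals = np.interp(mids, times, od)
    width = edges[1] - edges[0]
    return float(np.sum(vals * width) / 60.0)


# ---------------------------------------------------------------------------
# clustering


def average_linkage_oracle(dist: np.ndarray) -> list[tuple[frozenset[int], float]]:
    """Naive agglomeration recomputing all inter-cluster average distances
    at every step; returns (merged leaf set, merge height) per step."""
    n = dist.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for a, b in combinations(ids, 2):
            d = float(
                np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[next_id] = merged
        merges.append((merged, d))
        next_id += 1
    return merges


# ---------------------------------------------------------------------------
# hypergeometric


def hypergeom_upper_tail_oracle(
    universe: list[str], term: set[str], hits: set[str]
) -> float:
    """P(overlap >= observed) by enumerating every possible hit set of the
    same size."""
    n = len(hits)
    k_obs = len(hits & term)
    total = 0
    at_least = 0
    for subset in combinations(universe, n):
        total += 1
        if len(set(subset) & term) >= k_obs:
            at_least += 1
    return at_least / total
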