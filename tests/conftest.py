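"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from xlinkval.fixtures import (
    make_homodimer_scenario,
    make_ops_scenario,
    make_predicted_model_scenario,
)
from xlinkval.io import RunConfig


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def homodimer_scenario():
    return make_homodimer_scenario(0)


@pytest.fixture(scope="session")
def ops_scenario():
    return make_ops_scenario(0)


@pytest.fixture(scope="session")
def predicted_scenario():
    return make_predicted_model_scenario(0)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_local_score(query: str, target: str, scheme) -> int:
    """Exhaustive best local alignment score by depth-first enumeration.

    Explores every alignment path (substitution / gap-in-query /
    gap-in-target with affine costs) from every start cell, pruned by the
    optimistic bound of all-matches for the shorter remainder. Exact because
    penalties are non-positive and the bound is admissible. Only feasible for
    short sequences.
    """
    n, m = len(query), len(target)
    match, mismatch = scheme.match, scheme.mismatch
    gap_open, gap_extend = scheme.gap_open, scheme.gap_extend
    best = 0

    def dfs(i: int, j: int, score: int, state: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i >= n or j >= m:
            return
        if score + match * min(n - i, m - j) <= best:
            return
        sub = match if query[i] == target[j] else mismatch
        dfs(i + 1, j + 1, score + sub, "M")
        dfs(i, j + 1, score + (gap_extend if state == "E" else gap_open), "E")
        dfs(i + 1, j, score + (gap_extend if state == "F" else gap_open), "F")

    for i in range(n):
        for j in range(m):
            if best >= match * min(n - i, m - j):
                continue
            sub = match if query[i] == target[j] else mismatch
            dfs(i + 1, j + 1, sub, "M")
    return best


def dijkstra_grid_distance(blocked: np.ndarray, spacing: float, start, goal):
    """Shortest 26-connected path length via scipy's sparse Dijkstra.

    Textbook formulation, fully independent of the package's A* search: free
    voxels become graph nodes, edges connect 26-neighbors with Euclidean step
    weights. Returns None when unreachable.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra

    shape = blocked.shape
    ids = -np.ones(shape, dtype=np.int64)
    free = np.argwhere(~blocked)
    ids[tuple(free.T)] = np.arange(len(free))
    if blocked[tuple(start)] or blocked[tuple(goal)]:
        return None
    rows, cols, weights = [], [], []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                shifted = free + np.array([dx, dy, dz])
                ok = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
                src = free[ok]
                dst = shifted[ok]
                dst_ids = ids[tuple(dst.T)]
                keep = dst_ids >= 0
                rows.append(ids[tuple(src[keep].T)])
                cols.append(dst_ids[keep])
                w = spacing * float(np.sqrt(dx * dx + dy * dy + dz * dz))
                weights.append(np.full(keep.sum(), w))
    graph = csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(free), len(free)),
    )
    src = int(ids[tuple(start)])
    dst = int(ids[tuple(goal)])
    dist = dijkstra(graph, indices=src, min_only=False)[dst]
    return None if np.isinf(dist) else float(dist)
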