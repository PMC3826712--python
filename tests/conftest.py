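"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

from patchconnect.grid import RasterGrid
from patchconnect.patches import patch_from_cells
from patchconnect.surfaces import Surface

NEIGHBOR_FACTORS = [
    (-1, -1, math.sqrt(2)),
    (-1, 0, 1.0),
    (-1, 1, math.sqrt(2)),
    (0, -1, 1.0),
    (0, 1, 1.0),
    (1, -1, math.sqrt(2)),
    (1, 0, 1.0),
    (1, 1, math.sqrt(2)),
]


def make_cost_surface(values, cell_size_m=1.0, barrier=None) -> Surface:
    values = np.asarray(values, dtype=float)
    grid = RasterGrid(values, cell_size_m)
    if barrier is None:
        barrier = np.zeros(values.shape, dtype=bool)
    return Surface(grid, np.asarray(barrier, dtype=bool), "cost")


def make_suitability_surface(values, cell_size_m=250.0, barrier=None) -> Surface:
    values = np.asarray(values, dtype=float)
    grid = RasterGrid(values, cell_size_m)
    if barrier is None:
        barrier = np.zeros(values.shape, dtype=bool)
    return Surface(grid, np.asarray(barrier, dtype=bool), "suitability")


def make_patch(pid, cells, shape, cell_size_m=1.0):
    return patch_from_cells(pid, np.asarray(cells, dtype=int), None, cell_size_m, shape)


def oracle_cost_distance(cost: np.ndarray, open_mask: np.ndarray, source_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Naive O(V^2) multi-source Dijkstra with the same step-cost convention.

    Written independently of the package's heap implementation; node
    selection breaks ties by smallest flat index (np.argmin convention).
    """
    nrows, ncols = cost.shape
    n = nrows * ncols
    flat_cost = cost.ravel()
    flat_open = open_mask.ravel()
    dist = np.full(n, np.inf)
    dist[source_mask.ravel() & flat_open] = 0.0
    visited = np.zeros(n, dtype=bool)
    for _ in range(n):
        cand = np.flatnonzero(~visited & flat_open & np.isfinite(dist))
        if cand.size == 0:
            break
        i = cand[np.argmin(dist[cand])]
        visited[i] = True
        r, c = divmod(int(i), ncols)
        for dr, dc, f in NEIGHBOR_FACTORS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols):
                continue
            j = rr * ncols + cc
            if visited[j] or not flat_open[j]:
                continue
            nd = dist[i] + (flat_cost[i] + flat_cost[j]) * 0.5 * (f * cell_size)
            if nd < dist[j]:
                dist[j] = nd
    return dist.reshape(nrows, ncols)


def oracle_power_iteration(a: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000):
    """Independent power-iteration eigenpair oracle (converged to 1e-12)."""
    n = a.shape[0]
    v = np.ones(n) / n
    for _ in range(max_iter):
        w = a @ v
        w = w / w.sum()
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    lam = float((a @ v).sum())
    return v, lam


@pytest.fixture(scope="session")
def reference_table():
    from patchconnect.network import load_reference_table

    return load_reference_table()


@pytest.fixture(scope="session")
def recovery_run():
    """One full synthetic recovery pipeline run, shared across tests."""
    import patchconnect as pc
    from patchconnect.pipeline import PipelineConfig, build_surfaces

    cfg = pc.recovery_preset(seed=7)
    grids, features, gt = pc.generate_landscape(cfg)
    suit, cost = build_surfaces(PipelineConfig(), grids)
    patches = pc.identify_patches(suit)
    return {"config": cfg, "grids": grids, "gt": gt, "suit": suit, "cost": cost, "patches": patches}
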