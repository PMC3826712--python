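"""Cost-distance fields, least-cost paths and width-constrained corridors.

The movement model is a grid graph: every non-barrier cell of the cost
surface is a node, connected to its 8 neighbors.  Traversing from cell *i*
to adjacent cell *j* costs ``(c_i + c_j) / 2 * d_ij`` where ``c`` is the
cell's resistance score (1-10) and ``d_ij`` is the metric step length —
``cell_size`` orthogonally, ``cell_size * sqrt(2)`` diagonally.  Accumulated
cost therefore carries units of resistance-score x meters.

* ``cost_distance`` runs a multi-source Dijkstra from a patch, yielding the
  accumulated-cost field (0 on the patch, +inf where unreachable).
* ``least_cost_path`` backtracks the single optimal route between two
  patches by steepest admissible descent of the source field.
* ``corridor_surface`` sums the two patches' fields; its minimum equals the
  least-cost path cost, and thresholding it carves corridor slices.
* ``corridor_width_cost`` finds the smallest threshold whose slice links the
  patches while staying at least ``width_km`` wide at its narrowest point
  (measured by Euclidean distance transform against the slice complement).

Determinism: the priority queue breaks cost ties by flat cell index and
backtracking breaks descent ties by fixed row-major neighbor order, so
fields and paths are bit-reproducible.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import RasterGrid
from .patches import STRUCTURE_8, Patch
from .surfaces import Surface

__all__ = [
    "CostDistanceField",
    "LeastCostPath",
    "CorridorSurface",
    "CorridorWidthResult",
    "cost_distance",
    "least_cost_path",
    "corridor_surface",
    "corridor_width_cost",
]

# Fixed row-major neighbor order: (dr, dc) and step-length factor.
_NEIGHBORS = [
    (-1, -1, math.sqrt(2)),
    (-1, 0, 1.0),
    (-1, 1, math.sqrt(2)),
    (0, -1, 1.0),
    (0, 1, 1.0),
    (1, -1, math.sqrt(2)),
    (1, 0, 1.0),
    (1, 1, math.sqrt(2)),
]


@dataclass
class CostDistanceField:
    """Accumulated movement cost from every cell to a source patch."""

    grid: RasterGrid  # +inf = unreachable; nodata mask mirrors the cost surface
    source_patch_id: str
    source_mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class LeastCostPath:
    """The single optimal route between two patches on the cost surface."""

    cells: list[tuple[int, int]]  # ordered from patch a to patch b
    total_cost: float  # resistance-score x meters
    length_km: float  # geometric length of the route
    pair: tuple[str, str]


@dataclass
class CorridorSurface:
    """Pointwise sum of two cost-distance fields; min = the pair's LCP cost."""

    grid: RasterGrid
    pair: tuple[str, str]
    min_value: float
    mask_a: np.ndarray
    mask_b: np.ndarray
    barrier_mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class CorridorWidthResult:
    """Outcome of the width-constrained corridor search.

    ``achieved`` is False when no threshold yields a corridor of the
    requested width (landscape too constricted); then ``threshold_cost`` is
    NaN and ``max_achievable_width_km`` reports the landscape's bottleneck.
    """

    achieved: bool
    threshold_cost: float
    width_km: float
    max_achievable_width_km: float | None = None


def _traversable(cost_surface: Surface) -> np.ndarray:
    return cost_surface.valid_mask & np.isfinite(cost_surface.values)


def cost_distance(cost_surface: Surface, source: Patch) -> CostDistanceField:
    """Multi-source Dijkstra accumulated cost from ``source`` over the surface.

    Barrier and nodata cells are excluded from the graph.  Source cells that
    sit on barrier cells contribute nothing; a source entirely on barriers is
    an error.
    """
    if cost_surface.kind != "cost":
        raise ValueError("cost_distance requires a cost surface")
    if source.n_cells == 0:
        raise ValueError("source patch is empty")
    nrows, ncols = cost_surface.grid.shape
    open_mask = _traversable(cost_surface)
    cost = cost_surface.values
    src_mask = source.mask((nrows, ncols))
    seeds = np.flatnonzero(src_mask.ravel() & open_mask.ravel())
    if seeds.size == 0:
        raise ValueError(f"source patch {source.id} lies entirely on barrier/nodata cells")

    dist = np.full(nrows * ncols, np.inf)
    flat_cost = cost.ravel()
    flat_open = open_mask.ravel()
    s = cost_surface.cell_size_m
    # (step factor already includes sqrt(2) for diagonals)
    offsets = [(dr * ncols + dc, dr, dc, f * s) for dr, dc, f in _NEIGHBORS]

    heap: list[tuple[float, int]] = []
    for i in seeds:
        dist[i] = 0.0
        heap.append((0.0, int(i)))
    heapq.heapify(heap)  # ties broken by flat index via tuple comparison
    done = np.zeros(nrows * ncols, dtype=bool)
    while heap:
        d, i = heapq.heappop(heap)
        if done[i]:
            continue
        done[i] = True
        r, c = divmod(i, ncols)
        ci = flat_cost[i]
        for off, dr, dc, step in offsets:
            rr, cc = r + dr, c + dc
            if rr < 0 or rr >= nrows or cc < 0 or cc >= ncols:
                continue
            j = i + off
            if done[j] or not flat_open[j]:
                continue
            nd = d + (ci + flat_cost[j]) * 0.5 * step
            if nd < dist[j]:
                dist[j] = nd
                heapq.heappush(heap, (nd, j))
    field = dist.reshape(nrows, ncols)
    grid = cost_surface.grid.copy_with(field)
    return CostDistanceField(grid, source.id, src_mask)


def least_cost_path(
    cost_surface: Surface,
    a: Patch,
    b: Patch,
    field_a: CostDistanceField | None = None,
) -> LeastCostPath | None:
    """Backtrack the optimal route from ``b`` down ``a``'s cost field.

    Returns ``None`` when the patches are mutually unreachable (a no-path
    result, not an error).  ``field_a`` may be passed to reuse a previously
    computed field for ``a``.
    """
    if field_a is None:
        field_a = cost_distance(cost_surface, a)
    cd = field_a.values
    nrows, ncols = cd.shape
    b_cells = b.cells
    vals = cd[b_cells[:, 0], b_cells[:, 1]]
    order = np.lexsort((b_cells[:, 1], b_cells[:, 0], vals))  # min cost, tie -> row-major
    best = order[0]
    total = float(vals[best])
    if not np.isfinite(total):
        return None
    a_mask = a.mask((nrows, ncols))
    s = cost_surface.cell_size_m
    r, c = int(b_cells[best, 0]), int(b_cells[best, 1])
    path = [(r, c)]
    length_m = 0.0
    tol = 1e-6 * max(total, 1.0) + 1e-9
    cost = cost_surface.values
    # Steepest admissible descent; at most one step per remaining cost unit.
    for _ in range(nrows * ncols):
        if cd[r, c] <= 0.0 or a_mask[r, c]:
            break
        best_nb = None
        best_val = np.inf
        for dr, dc, f in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if rr < 0 or rr >= nrows or cc < 0 or cc >= ncols:
                continue
            v = cd[rr, cc]
            if not np.isfinite(v):
                continue
            step = (cost[r, c] + cost[rr, cc]) * 0.5 * f * s
            if v + step <= cd[r, c] + tol and v < best_val:
                best_val = v
                best_nb = (rr, cc, f * s)
        if best_nb is None:  # numerically stuck; should not happen on exact fields
            raise RuntimeError(f"backtracking stalled at cell ({r}, {c})")
        rr, cc, step_len = best_nb
        length_m += step_len
        r, c = rr, cc
        path.append((r, c))
    path.reverse()  # orient from a to b
    return LeastCostPath(path, total, length_m / 1000.0, (a.id, b.id))


def corridor_surface(cd_a: CostDistanceField, cd_b: CostDistanceField, barrier_mask: np.ndarray | None = None) -> CorridorSurface:
    """Sum of the two accumulated-cost fields; each cell's value is the cost
    of the best a-to-b route constrained to pass through that cell."""
    if cd_a.grid.shape != cd_b.grid.shape or not cd_a.grid.same_geometry(cd_b.grid):
        raise ValueError("cost-distance fields must share the same grid")
    total = cd_a.values + cd_b.values
    if barrier_mask is None:
        barrier_mask = ~np.isfinite(total)
    finite = total[np.isfinite(total)]
    mn = float(finite.min()) if finite.size else float("inf")
    return CorridorSurface(
        cd_a.grid.copy_with(total),
        (cd_a.source_patch_id, cd_b.source_patch_id),
        mn,
        cd_a.source_mask,
        cd_b.source_mask,
        np.asarray(barrier_mask, dtype=bool),
    )


def _corridor_links(C: CorridorSurface, threshold: float, radius_m: float) -> bool:
    """True iff the slice {C <= threshold} (plus the patches) contains a
    connected region >= 2*radius wide linking the two patches.

    Width is tested by Euclidean distance transform: a cell belongs to the
    eroded core iff its distance to the slice complement is >= radius.  The
    link succeeds when one 8-connected core component comes within radius of
    both patches.
    """
    in_a, in_b = C.mask_a, C.mask_b
    region = (~C.barrier_mask) & (np.nan_to_num(C.values, nan=np.inf) <= threshold)
    region |= in_a | in_b
    if radius_m <= 0:
        core = region
    else:
        edt = ndimage.distance_transform_edt(region, sampling=C.grid.cell_size_m)
        core = edt >= radius_m
        if not core.any():
            return False
    labels, n = ndimage.label(core, structure=STRUCTURE_8)
    if n == 0:
        return False
    if radius_m <= 0:
        near_a, near_b = in_a, in_b
    else:
        near_a = ndimage.distance_transform_edt(~in_a, sampling=C.grid.cell_size_m) <= radius_m
        near_b = ndimage.distance_transform_edt(~in_b, sampling=C.grid.cell_size_m) <= radius_m
    labs_a = np.unique(labels[near_a & (labels > 0)])
    labs_b = np.unique(labels[near_b & (labels > 0)])
    return bool(np.intersect1d(labs_a, labs_b, assume_unique=True).size)


def corridor_width_cost(C: CorridorSurface, width_km: float = 1.0) -> CorridorWidthResult:
    """Smallest corridor-surface threshold whose slice is ``width_km`` wide.

    Found by bisection over the sorted distinct finite values of ``C``; the
    link test is monotone in the threshold, so bisection is exact.  When even
    the full landscape cannot host a corridor of the requested width, a
    bounded-failure result reports the maximum achievable width instead.
    """
    if width_km < 0:
        raise ValueError("width_km must be nonnegative")
    radius_m = width_km * 1000.0 / 2.0
    finite = np.unique(C.values[np.isfinite(C.values)])
    if finite.size == 0:
        return CorridorWidthResult(False, float("nan"), width_km, 0.0)
    if not _corridor_links(C, float(finite[-1]), radius_m):
        return CorridorWidthResult(False, float("nan"), width_km, _max_width(C, float(finite[-1])))
    lo, hi = 0, len(finite) - 1  # invariant: links at hi
    if _corridor_links(C, float(finite[0]), radius_m):
        return CorridorWidthResult(True, float(finite[0]), width_km)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _corridor_links(C, float(finite[mid]), radius_m):
            hi = mid
        else:
            lo = mid
    return CorridorWidthResult(True, float(finite[hi]), width_km)


def _max_width(C: CorridorSurface, threshold: float) -> float:
    """Largest corridor width (km) achievable at ``threshold`` (bisection on radius)."""
    edt = ndimage.distance_transform_edt(
        (~C.barrier_mask) & (np.nan_to_num(C.values, nan=np.inf) <= threshold) | C.mask_a | C.mask_b,
        sampling=C.grid.cell_size_m,
    )
    radii = np.unique(edt[edt > 0])
    lo, hi = 0.0, 0.0
    # binary search over distinct attained radii
    candidates = radii.tolist()
    left, right = 0, len(candidates) - 1
    best = 0.0
    while left <= right:
        mid = (left + right) // 2
        r = float(candidates[mid])
        if _corridor_links(C, threshold, r):
            best = r
            left = mid + 1
        else:
            right = mid - 1
    return best * 2.0 / 1000.0
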