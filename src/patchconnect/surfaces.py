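"""Weighted overlay of score grids into suitability and cost surfaces.

The habitat-suitability surface combines the eight suitability score layers
and the movement-cost surface the seven cost layers, each as a pointwise
convex combination with the expert AHP weights.  Barrier dominance: a cell
flagged BARRIER in any input layer is BARRIER in the combined surface
(absolute avoidance, not weight-discounted); nodata likewise propagates.
Because the weights sum to 1 and scores lie in 1-10, surface values lie in
[1, 10] on valid cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .ahp import WeightSet
from .classification import COST_VARIABLES, SUITABILITY_VARIABLES, ScoreGrid
from .grid import RasterGrid

__all__ = ["Surface", "weighted_overlay", "resample_to"]

_KIND_VARIABLES = {"suitability": frozenset(SUITABILITY_VARIABLES), "cost": frozenset(COST_VARIABLES)}


@dataclass
class Surface:
    """A combined landscape surface (kind 'suitability' or 'cost')."""

    grid: RasterGrid
    barrier_mask: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("suitability", "cost"):
            raise ValueError(f"surface kind must be 'suitability' or 'cost', got {self.kind!r}")
        self.barrier_mask = np.asarray(self.barrier_mask, dtype=bool)
        if self.barrier_mask.shape != self.grid.shape:
            raise ValueError("barrier_mask shape does not match grid")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def cell_size_m(self) -> float:
        return self.grid.cell_size_m

    @property
    def valid_mask(self) -> np.ndarray:
        return ~(self.barrier_mask | self.grid.nodata_mask)


def weighted_overlay(score_grids: Mapping[str, ScoreGrid], weights: WeightSet, kind: str) -> Surface:
    """Combine score layers into one surface by a weighted pointwise sum.

    Layer names must exactly match the weight names and be the canonical
    variable set for ``kind`` (mixing suitability-only and cost-only variables
    is rejected).  Any barrier or nodata cell in an input makes the output
    cell barrier / nodata respectively.
    """
    expected = _KIND_VARIABLES[kind] if kind in _KIND_VARIABLES else None
    names = set(score_grids)
    if names != set(weights.names):
        raise KeyError(f"layer names {sorted(names)} do not match weight names {sorted(weights.names)}")
    if expected is not None and names != expected:
        raise ValueError(
            f"{kind} surface requires exactly the variables {sorted(expected)}; got {sorted(names)}"
        )
    total = sum(weights.weights.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1 (got {total})")

    grids = list(score_grids.values())
    ref = grids[0].grid
    for sg in grids[1:]:
        if not sg.grid.same_geometry(ref):
            raise ValueError("all score grids must share shape, cell size and origin (resample first)")

    acc = np.zeros(ref.shape)
    barrier = np.zeros(ref.shape, dtype=bool)
    nodata = np.zeros(ref.shape, dtype=bool)
    for name, sg in score_grids.items():
        w = weights.weights[name]
        barrier |= sg.barrier_mask
        nodata |= sg.nodata_mask
        acc += w * np.nan_to_num(sg.values, nan=0.0)
    invalid = barrier | nodata
    acc[invalid] = np.nan
    out = ref.copy_with(acc, nodata_mask=nodata)
    return Surface(out, barrier, kind)


def resample_to(
    grid: RasterGrid,
    target_cell_size_m: float,
    target_shape: tuple[int, int] | None = None,
    target_origin: tuple[float, float] | None = None,
) -> RasterGrid:
    """Nearest-neighbor resample onto an aligned target grid.

    Each target cell takes the value of the source cell containing its
    center; masks travel identically.  Nearest-neighbor is used so integer
    scores survive resampling unchanged.  The target extent must fall within
    the source extent.
    """
    if target_origin is None:
        target_origin = grid.origin
    if target_shape is None:
        # Cover the same extent as closely as an integer cell count allows.
        h = grid.nrows * grid.cell_size_m
        w = grid.ncols * grid.cell_size_m
        target_shape = (int(round(h / target_cell_size_m)), int(round(w / target_cell_size_m)))
    tr, tc = target_shape
    x0s, y0s = grid.origin
    x0t, y0t = target_origin
    # Target cell centers in map coordinates.
    xs = x0t + (np.arange(tc) + 0.5) * target_cell_size_m
    ys = y0t + (tr - np.arange(tr) - 0.5) * target_cell_size_m
    src_col = np.floor((xs - x0s) / grid.cell_size_m).astype(int)
    src_row = (grid.nrows - 1 - np.floor((ys - y0s) / grid.cell_size_m)).astype(int)
    if src_col.min() < 0 or src_col.max() >= grid.ncols or src_row.min() < 0 or src_row.max() >= grid.nrows:
        raise ValueError("target extent exceeds source extent")
    values = grid.values[np.ix_(src_row, src_col)]
    mask = grid.nodata_mask[np.ix_(src_row, src_col)]
    return RasterGrid(values, target_cell_size_m, target_origin, mask, grid.crs)
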