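"""Habitat patch identification and patch geometry statistics.

Candidate patches are 8-connected components of suitability cells strictly
above a score threshold (default 9.50), kept when their area exceeds a
minimum (default 60 km^2) — deliberately strict criteria that select only
high-quality, conservation-priority habitat.  Patches are sorted by area
descending and given deterministic ids.  Inter-patch separation is measured
edge-to-edge: the minimum distance between boundary-cell centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import RasterGrid
from .surfaces import Surface

__all__ = [
    "Patch",
    "identify_patches",
    "patch_mean_suitability",
    "euclidean_patch_distance",
    "load_extant_patches",
    "patch_from_cells",
]

# 8-connectivity structuring element shared with the movement graph.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class Patch:
    """An 8-connected set of grid cells forming one habitat patch."""

    id: str
    cells: np.ndarray  # (n, 2) int array of (row, col)
    area_km2: float
    mean_suitability: float
    boundary_cells: np.ndarray  # (m, 2) subset of cells on the patch edge
    label: str = "potential"  # 'extant' or 'potential'
    grid_shape: tuple[int, int] | None = None

    def mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or self.grid_shape
        if shape is None:
            raise ValueError("patch carries no grid shape; pass one explicitly")
        m = np.zeros(shape, dtype=bool)
        m[self.cells[:, 0], self.cells[:, 1]] = True
        return m

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _boundary_of(mask: np.ndarray) -> np.ndarray:
    """Cells of ``mask`` with at least one 8-neighbor outside the patch."""
    interior = ndimage.binary_erosion(mask, structure=STRUCTURE_8, border_value=0)
    return np.argwhere(mask & ~interior)


def patch_from_cells(
    pid: str,
    cells: np.ndarray,
    surface: Surface | None,
    cell_size_m: float,
    grid_shape: tuple[int, int],
    label: str = "potential",
) -> Patch:
    """Assemble a :class:`Patch` (area, mean suitability, boundary) from cells."""
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        raise ValueError(f"patch {pid}: empty cell set")
    m = np.zeros(grid_shape, dtype=bool)
    m[cells[:, 0], cells[:, 1]] = True
    area = len(cells) * cell_size_m**2 / 1e6
    if surface is not None:
        mean_suit = float(np.nanmean(surface.values[cells[:, 0], cells[:, 1]]))
    else:
        mean_suit = float("nan")
    return Patch(pid, cells, area, mean_suit, _boundary_of(m), label, grid_shape)


def identify_patches(
    surface: Surface,
    score_threshold: float = 9.50,
    min_area_km2: float = 60.0,
    smoothing_window: int | None = None,
) -> list[Patch]:
    """Potential habitat patches on a suitability surface.

    Cells with value strictly above ``score_threshold`` (non-barrier,
    non-nodata) are grouped into 8-connected components; components whose
    area strictly exceeds ``min_area_km2`` are returned sorted by area
    descending with ids ``P1, P2, ...``.  ``smoothing_window`` optionally
    applies a moving-window mean to the surface before thresholding
    (default off: per-cell thresholding).
    """
    if surface.kind != "suitability":
        raise ValueError("patch identification requires a suitability surface")
    vals = surface.values
    if smoothing_window is not None and smoothing_window > 1:
        filled = np.where(surface.valid_mask, vals, 0.0)
        counts = ndimage.uniform_filter(surface.valid_mask.astype(float), smoothing_window, mode="constant")
        sums = ndimage.uniform_filter(filled, smoothing_window, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(counts > 0, sums / counts, np.nan)
    above = surface.valid_mask & (np.nan_to_num(vals, nan=-np.inf) > score_threshold)
    labels, n = ndimage.label(above, structure=STRUCTURE_8)
    cell_area_km2 = surface.cell_size_m**2 / 1e6
    comps = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        area = len(cells) * cell_area_km2
        if area > min_area_km2:
            comps.append((area, cells))
    # Deterministic order: area descending, then first-cell row-major index.
    comps.sort(key=lambda t: (-t[0], t[1][0, 0] * surface.grid.ncols + t[1][0, 1]))
    return [
        patch_from_cells(f"P{i + 1}", cells, surface, surface.cell_size_m, surface.grid.shape)
        for i, (_, cells) in enumerate(comps)
    ]


def patch_mean_suitability(patch: Patch, surface: Surface) -> float:
    """Arithmetic mean of the suitability surface over the patch's cells."""
    r, c = patch.cells[:, 0], patch.cells[:, 1]
    if r.max() >= surface.grid.nrows or c.max() >= surface.grid.ncols:
        raise ValueError("patch cells fall outside the surface")
    return float(np.nanmean(surface.values[r, c]))


def euclidean_patch_distance(a: Patch, b: Patch, cell_size_m: float) -> float:
    """Edge-to-edge separation in km: min distance over boundary-cell centers.

    Patches must be disjoint; overlap raises an error.
    """
    sa = {tuple(x) for x in a.cells}
    if any(tuple(x) in sa for x in b.cells):
        raise ValueError(f"patches {a.id} and {b.id} overlap")
    pa = a.boundary_cells.astype(float)
    pb = b.boundary_cells.astype(float)
    tree = cKDTree(pa)
    d, _ = tree.query(pb, k=1)
    return float(d.min()) * cell_size_m / 1000.0


def load_extant_patches(
    vector_file: str | Path | dict,
    template: RasterGrid,
    surface: Surface | None = None,
) -> list[Patch]:
    """Rasterize extant-range polygons (GeoJSON) onto ``template``'s grid.

    A cell belongs to a patch iff its center lies inside the polygon.
    Feature property ``name`` (or ``id``) provides the patch id.  Invalid or
    self-intersecting polygons raise; a polygon containing no cell center
    raises a degenerate-geometry error.
    """
    import shapely
    from shapely.geometry import shape as shp_shape

    if isinstance(vector_file, (str, Path)):
        obj = json.loads(Path(vector_file).read_text())
    else:
        obj = vector_file
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    X, Y = template.cell_centers()
    pts_x, pts_y = X.ravel(), Y.ravel()
    out: list[Patch] = []
    for i, feat in enumerate(feats):
        geom = shp_shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"feature {i}: invalid geometry ({shapely.is_valid_reason(geom)})")
        inside = shapely.contains_xy(geom, pts_x, pts_y).reshape(template.shape)
        cells = np.argwhere(inside)
        pid = str(feat.get("properties", {}).get("name", feat.get("properties", {}).get("id", f"E{i + 1}")))
        if cells.size == 0:
            raise ValueError(f"patch {pid}: polygon contains no cell center (smaller than one cell?)")
        out.append(
            patch_from_cells(pid, cells, surface, template.cell_size_m, template.shape, label="extant")
        )
    return out
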