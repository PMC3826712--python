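"""Synthetic study-region generator with planted ground truth.

Emulates the ten landscape layers the connectivity model consumes —
elevation, slope, NDVI, human density, and distances to rivers, highways,
railways, farmland, settlements and individual houses — on a seeded random
landscape, so the full pipeline (reclassify -> overlay -> patches ->
network) is testable without any real GIS data.

Background terrain is a Gaussian-smoothed random field scaled to the
configured elevation range (default 2500-5200 m, the plateau basin-to-summit
span of the gazelle's region); slope is the gradient magnitude of that
terrain in degrees; NDVI and human density are independent smoothed fields.
Vector features are sampled at random and turned into distance rasters by
exact Euclidean distance from cell centers to the feature geometry.

Planted ground truth: patch discs locally override the raw layers so the
reclassified, weighted suitability hits a target score above the patch
threshold; corridor routes override the cost-relevant layers so the route is
strictly cheaper than the surrounding matrix.  The emitted
:class:`GroundTruth` records the planted footprints and routes for
parameter-recovery tests.  All randomness flows from a single integer seed
through one generator instance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, mapping

from .classification import (
    COST_VARIABLES,
    SUITABILITY_VARIABLES,
    RuleTable,
    default_cost_weights,
    default_suitability_weights,
    load_rule_tables,
)
from .grid import RasterGrid

__all__ = [
    "PlantedPatch",
    "PlantedCorridor",
    "SyntheticConfig",
    "GroundTruth",
    "generate_landscape",
    "distance_raster",
    "recovery_preset",
    "LAYER_NAMES",
]

LAYER_NAMES = (
    "elevation",
    "slope",
    "ndvi",
    "human_density",
    "dist_river",
    "dist_highway",
    "dist_railway",
    "dist_farmland",
    "dist_settlement",
    "dist_house",
)

_FEATURE_LAYER = {
    "river": "dist_river",
    "highway": "dist_highway",
    "railway": "dist_railway",
    "farmland": "dist_farmland",
    "settlement": "dist_settlement",
    "house": "dist_house",
}


@dataclass(frozen=True)
class PlantedPatch:
    center_km: tuple[float, float]  # map (x, y) from the grid origin, in km
    radius_km: float
    target_suitability: float = 9.8


@dataclass(frozen=True)
class PlantedCorridor:
    patch_pair: tuple[int, int]  # indices into planted_patches
    waypoints_km: tuple[tuple[float, float], ...]  # interior route points (x, y) km
    target_cost: float = 1.0
    half_width_cells: int = 2


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic landscape.

    The default window is 200x200 cells at 250 m (a 50 x 50 km, 2500 km^2
    region) so the full pipeline runs in seconds; ``study_scale_config``
    below provides a window matching the real analysis area's extent.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size_m: float = 250.0
    seed: int = 0
    elevation_range: tuple[float, float] = (2500.0, 5200.0)
    terrain_sigma_cells: float = 5.0  # autocorrelation length of the terrain field
    field_sigma_cells: float = 10.0  # NDVI / human-density smoothing
    n_settlements: int = 5
    n_houses: int = 40
    n_farmland_polygons: int = 4
    n_rivers: int = 2
    n_highways: int = 1
    n_railways: int = 1
    planted_patches: tuple[PlantedPatch, ...] = ()
    planted_corridors: tuple[PlantedCorridor, ...] = ()

    @property
    def extent_km(self) -> tuple[float, float]:
        return (self.shape[1] * self.cell_size_m / 1000.0, self.shape[0] * self.cell_size_m / 1000.0)

    def validate(self) -> None:
        w, h = self.extent_km
        for p in self.planted_patches:
            x, y = p.center_km
            if not (p.radius_km < x < w - p.radius_km and p.radius_km < y < h - p.radius_km):
                raise ValueError(f"planted patch at {p.center_km} km (r={p.radius_km}) overlaps the grid border")
        for c in self.planted_corridors:
            for x, y in c.waypoints_km:
                if not (0 < x < w and 0 < y < h):
                    raise ValueError(f"corridor waypoint ({x}, {y}) km outside the grid")
            for i in c.patch_pair:
                if not 0 <= i < len(self.planted_patches):
                    raise ValueError(f"corridor references missing planted patch index {i}")


@dataclass
class GroundTruth:
    """Planted footprints and routes, consistent with the emitted layers."""

    patch_masks: list[np.ndarray]
    patch_specs: list[PlantedPatch]
    corridor_routes: list[np.ndarray]  # (n, 2) arrays of route (row, col) cells
    corridor_specs: list[PlantedCorridor]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "patches": [
                {
                    "center_km": list(s.center_km),
                    "radius_km": s.radius_km,
                    "target_suitability": s.target_suitability,
                    "cells": np.argwhere(m).tolist(),
                }
                for s, m in zip(self.patch_specs, self.patch_masks)
            ],
            "corridors": [
                {
                    "patch_pair": list(s.patch_pair),
                    "target_cost": s.target_cost,
                    "route_cells": r.tolist(),
                }
                for s, r in zip(self.corridor_specs, self.corridor_routes)
            ],
        }
        Path(path).write_text(json.dumps(obj))


# -- random fields ---------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float, lo: float, hi: float) -> np.ndarray:
    """Seeded Gaussian-smoothed white noise rescaled to [lo, hi]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    if hi == lo:
        return np.full(shape, float(lo))
    fmin, fmax = f.min(), f.max()
    if fmax == fmin:
        return np.full(shape, (lo + hi) / 2.0)
    return lo + (f - fmin) * (hi - lo) / (fmax - fmin)


def _slope_degrees(elevation: np.ndarray, cell_size_m: float) -> np.ndarray:
    gy, gx = np.gradient(elevation, cell_size_m)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


# -- vector features -------------------------------------------------------


def _random_points(rng: np.random.Generator, n: int, w_km: float, h_km: float) -> list[Point]:
    return [Point(rng.uniform(0, w_km) * 1000, rng.uniform(0, h_km) * 1000) for _ in range(n)]


def _random_polyline(rng: np.random.Generator, w_km: float, h_km: float) -> LineString:
    """A line crossing the window between two random opposite-ish edge points."""
    if rng.random() < 0.5:  # west-east
        p0 = (0.0, rng.uniform(0, h_km))
        p1 = (w_km, rng.uniform(0, h_km))
    else:  # south-north
        p0 = (rng.uniform(0, w_km), 0.0)
        p1 = (rng.uniform(0, w_km), h_km)
    mids = []
    for t in (0.33, 0.66):
        mx = p0[0] + t * (p1[0] - p0[0]) + rng.normal(0, 0.08 * w_km)
        my = p0[1] + t * (p1[1] - p0[1]) + rng.normal(0, 0.08 * h_km)
        mids.append((mx, my))
    pts = [p0, *mids, p1]
    return LineString([(x * 1000, y * 1000) for x, y in pts])


def _random_polygon(rng: np.random.Generator, w_km: float, h_km: float):
    cx, cy = rng.uniform(0.1 * w_km, 0.9 * w_km), rng.uniform(0.1 * h_km, 0.9 * h_km)
    r = rng.uniform(0.5, 2.0)
    return Point(cx * 1000, cy * 1000).buffer(r * 1000, quad_segs=8)


def distance_raster(features: list, template: RasterGrid) -> RasterGrid:
    """Per-cell Euclidean distance (m) from cell centers to the nearest feature.

    Empty feature sets yield an all-infinite grid (with a warning).
    """
    X, Y = template.cell_centers()
    if not features:
        warnings.warn("empty feature set: distance raster is infinite everywhere", stacklevel=2)
        return template.copy_with(np.full(template.shape, np.inf))
    union = shapely.union_all(list(features))
    pts = shapely.points(X.ravel(), Y.ravel())
    d = shapely.distance(pts, union).reshape(template.shape)
    return template.copy_with(d)


# -- planting --------------------------------------------------------------


def _suitability_plan(target: float, tables: dict[str, dict[str, RuleTable]]) -> dict[str, int]:
    """Per-variable integer scores whose weighted sum is closest to ``target``.

    All variables start at score 10; at most one variable is lowered to an
    achievable score, chosen to minimize the miss.
    """
    w = default_suitability_weights().weights
    best = {v: 10 for v in SUITABILITY_VARIABLES}
    best_err = abs(10.0 - target)
    for v in SUITABILITY_VARIABLES:
        for s in tables[v]["suitability"].achievable_scores():
            val = 10.0 - w[v] * (10 - s)
            if abs(val - target) < best_err:
                best_err = abs(val - target)
                best = {u: 10 for u in SUITABILITY_VARIABLES}
                best[v] = s
    return best


def _cost_plan(target: float, tables: dict[str, dict[str, RuleTable]]) -> dict[str, int]:
    """Per-variable cost scores each as close to ``target`` as achievable
    (ties resolved toward the cheaper score)."""
    plan = {}
    for v in COST_VARIABLES:
        scores = tables[v]["cost"].achievable_scores()
        plan[v] = min(scores, key=lambda s: (abs(s - target), s))
    return plan


def _disc_mask(template: RasterGrid, center_km: tuple[float, float], radius_km: float) -> np.ndarray:
    X, Y = template.cell_centers()
    cx, cy = center_km[0] * 1000, center_km[1] * 1000
    return (X - cx) ** 2 + (Y - cy) ** 2 <= (radius_km * 1000) ** 2


def _route_line(config: SyntheticConfig, corridor: PlantedCorridor) -> LineString:
    a = config.planted_patches[corridor.patch_pair[0]].center_km
    b = config.planted_patches[corridor.patch_pair[1]].center_km
    pts = [a, *corridor.waypoints_km, b]
    return LineString([(x * 1000, y * 1000) for x, y in pts])


def _route_cells(line: LineString, template: RasterGrid) -> np.ndarray:
    """Cells traversed by the route centerline (sampled at quarter-cell steps)."""
    step = template.cell_size_m / 4.0
    n = max(int(line.length / step), 1)
    seen = []
    seen_set = set()
    for i in range(n + 1):
        p = line.interpolate(i * line.length / n)
        try:
            rc = template.index_of(p.x, p.y)
        except IndexError:
            continue
        if rc not in seen_set:
            seen_set.add(rc)
            seen.append(rc)
    return np.array(seen, dtype=int)


# -- generator -------------------------------------------------------------


def generate_landscape(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[dict[str, RasterGrid], dict[str, list], GroundTruth]:
    """Generate raw layers, vector features and ground truth for one region.

    Deterministic for a fixed seed (``seed`` overrides ``config.seed``).
    Planting order: features and distance rasters first, then corridor
    overrides, then patch overrides (patch footprints win where they meet a
    corridor end).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nrows, ncols = config.shape
    template = RasterGrid(np.zeros(config.shape), config.cell_size_m)
    w_km, h_km = config.extent_km
    tables = load_rule_tables()

    lo, hi = config.elevation_range
    elevation = _smooth_field(rng, config.shape, config.terrain_sigma_cells, lo, hi)
    ndvi = _smooth_field(rng, config.shape, config.field_sigma_cells, 0.0, 1.0)
    human_density = _smooth_field(rng, config.shape, config.field_sigma_cells, 0.0, 60.0)

    features: dict[str, list] = {
        "river": [_random_polyline(rng, w_km, h_km) for _ in range(config.n_rivers)],
        "highway": [_random_polyline(rng, w_km, h_km) for _ in range(config.n_highways)],
        "railway": [_random_polyline(rng, w_km, h_km) for _ in range(config.n_railways)],
        "farmland": [_random_polygon(rng, w_km, h_km) for _ in range(config.n_farmland_polygons)],
        "settlement": _random_points(rng, config.n_settlements, w_km, h_km),
        "house": _random_points(rng, config.n_houses, w_km, h_km),
    }

    layers: dict[str, np.ndarray] = {
        "elevation": elevation,
        "ndvi": ndvi,
        "human_density": human_density,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty feature classes are a valid config
        for fname, lname in _FEATURE_LAYER.items():
            layers[lname] = distance_raster(features[fname], template).values

    # Corridor overrides: route buffer gets cost-plan raw values.
    routes = []
    corridor_masks = []
    X, Y = template.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    for cor in config.planted_corridors:
        line = _route_line(config, cor)
        near = shapely.distance(pts, line).reshape(config.shape) <= cor.half_width_cells * config.cell_size_m
        plan = _cost_plan(cor.target_cost, tables)
        for v, s in plan.items():
            if v != "slope":  # slope is re-derived below, then overridden
                layers[v][near] = tables[v]["cost"].representative_value(s)
        routes.append(_route_cells(line, template))
        corridor_masks.append(near)

    # Patch overrides: disc footprint gets suitability-plan raw values plus
    # safe (non-barrier, low-resistance) settlement/house distances.
    patch_masks = []
    patch_plans = []
    for p in config.planted_patches:
        m = _disc_mask(template, p.center_km, p.radius_km)
        plan = _suitability_plan(p.target_suitability, tables)
        for v, s in plan.items():
            if v != "slope":  # slope is re-derived below, then overridden
                layers[v][m] = tables[v]["suitability"].representative_value(s)
        layers["dist_settlement"][m] = tables["dist_settlement"]["cost"].representative_value(1)
        layers["dist_house"][m] = tables["dist_house"]["cost"].representative_value(1)
        patch_masks.append(m)
        patch_plans.append(plan)

    # Slope derives from the final elevation layer; planted footprints are
    # then re-flattened because gradients at disc/buffer rims would leak
    # terrain steps into the edge cells of the override regions.
    layers["slope"] = _slope_degrees(layers["elevation"], config.cell_size_m)
    for cor, mask in zip(config.planted_corridors, corridor_masks):
        plan = _cost_plan(cor.target_cost, tables)
        layers["slope"][mask] = tables["slope"]["cost"].representative_value(plan["slope"])
    for plan, m in zip(patch_plans, patch_masks):
        layers["slope"][m] = tables["slope"]["suitability"].representative_value(plan["slope"])

    grids = {name: template.copy_with(layers[name]) for name in LAYER_NAMES}
    gt = GroundTruth(patch_masks, list(config.planted_patches), routes, list(config.planted_corridors))
    return grids, features, gt


def recovery_preset(seed: int = 0) -> SyntheticConfig:
    """Three planted patches and one planted corridor on the default window.

    Patch discs (radius 5 km, ~78.5 km^2) clear the 60 km^2 area criterion;
    all three pairs fall inside the 25 km Euclidean gate; the planted
    corridor (A-B, one waypoint bending the route) is strictly cheaper than
    the matrix, so its pair must attain the network's minimum movement cost.
    """
    return SyntheticConfig(
        seed=seed,
        planted_patches=(
            PlantedPatch(center_km=(12.0, 12.0), radius_km=5.0, target_suitability=9.8),
            PlantedPatch(center_km=(12.0, 38.0), radius_km=5.0, target_suitability=9.8),
            PlantedPatch(center_km=(38.0, 25.0), radius_km=5.0, target_suitability=9.8),
        ),
        planted_corridors=(PlantedCorridor(patch_pair=(0, 1), waypoints_km=((8.0, 25.0),), target_cost=1.0),),
    )


def study_scale_config(seed: int = 0) -> SyntheticConfig:
    """A window matching the real analysis area's extent (~58,600 km^2)."""
    return SyntheticConfig(shape=(970, 970), cell_size_m=250.0, seed=seed)


def write_features_geojson(features: dict[str, list], path: str | Path) -> None:
    feats = []
    for cls, geoms in features.items():
        for g in geoms:
            feats.append({"type": "Feature", "properties": {"class": cls}, "geometry": mapping(g)})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
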