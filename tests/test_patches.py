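"""Patch identification, geometry statistics and polygon rasterization."""

import numpy as np
import pytest

from patchconnect.patches import (
    euclidean_patch_distance,
    identify_patches,
    load_extant_patches,
    patch_from_cells,
    patch_mean_suitability,
)
from patchconnect.grid import RasterGrid

from .conftest import make_patch, make_suitability_surface


def flood_fill_components(mask):
    """Independent 8-connected component oracle (BFS flood fill)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0, c0 in np.argwhere(mask):
        if seen[r0, c0]:
            continue
        stack, comp = [(r0, c0)], []
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        comps.append(sorted(comp))
    return comps


def test_uniform_high_surface_is_one_patch():
    surf = make_suitability_surface(np.full((40, 40), 10.0), cell_size_m=250.0)
    found = identify_patches(surf)
    assert len(found) == 1
    assert found[0].area_km2 == pytest.approx(100.0)
    assert found[0].id == "P1"
    assert identify_patches(make_suitability_surface(np.full((40, 40), 5.0))) == []


def test_area_filter_drops_small_blob_and_matches_flood_fill():
    vals = np.full((60, 60), 5.0)
    vals[2:30, 2:42] = 9.8  # 28 x 40 = 1120 cells = 70 km^2 at 250 m
    vals[42:58, 8:58] = 9.8  # 16 x 50 = 800 cells = 50 km^2 (filtered)
    surf = make_suitability_surface(vals, cell_size_m=250.0)
    found = identify_patches(surf, 9.50, 60.0)
    above = vals > 9.50
    comps = flood_fill_components(above)
    big = [c for c in comps if len(c) * 0.0625 > 60.0]
    assert len(found) == len(big) == 1
    assert sorted(map(tuple, found[0].cells)) == big[0]
    # raising thresholds never increases the patch count (monotonicity)
    for thr, area in [(9.9, 60.0), (9.5, 80.0), (9.9, 80.0)]:
        assert len(identify_patches(surf, thr, area)) <= len(found)


def test_patch_identification_translation_and_rotation_invariant():
    rng = np.random.default_rng(5)
    vals = np.full((30, 30), 5.0)
    vals[3:12, 4:20] = 9.9
    surf = make_suitability_surface(vals, cell_size_m=1000.0)
    base = identify_patches(surf, 9.5, 10.0)
    rolled = make_suitability_surface(np.roll(vals, (6, 3), axis=(0, 1)), cell_size_m=1000.0)
    rot = make_suitability_surface(np.rot90(vals), cell_size_m=1000.0)
    for other in (rolled, rot):
        found = identify_patches(other, 9.5, 10.0)
        assert len(found) == len(base) == 1
        assert found[0].n_cells == base[0].n_cells


def test_mean_suitability_is_arithmetic_mean():
    vals = np.full((6, 6), 5.0)
    vals[0, 0], vals[0, 1] = 8.0, 10.0
    surf = make_suitability_surface(vals, cell_size_m=250.0)
    p = make_patch("A", [(0, 0), (0, 1)], (6, 6), 250.0)
    assert patch_mean_suitability(p, surf) == pytest.approx(9.0)
    rng = np.random.default_rng(11)
    block = rng.uniform(1, 10, size=(5, 5))
    vals2 = np.full((8, 8), 5.0)
    vals2[1:6, 2:7] = block
    surf2 = make_suitability_surface(vals2)
    cells = [(r, c) for r in range(1, 6) for c in range(2, 7)]
    p2 = make_patch("B", cells, (8, 8), 250.0)
    assert patch_mean_suitability(p2, surf2) == pytest.approx(block.sum() / 25.0)


def test_euclidean_distance_closed_forms():
    shape = (20, 20)
    a = make_patch("A", [(5, 2)], shape, 250.0)
    b = make_patch("B", [(5, 12)], shape, 250.0)
    assert euclidean_patch_distance(a, b, 250.0) == pytest.approx(2.5)
    c = make_patch("C", [(8, 6)], shape, 1000.0)  # offset (3, 4): 3-4-5 triangle
    assert euclidean_patch_distance(a, c, 1000.0) == pytest.approx(5.0)


def test_euclidean_distance_matches_boundary_pair_oracle():
    rng = np.random.default_rng(9)
    shape = (30, 30)
    cells_a = [(r, c) for r in range(3, 9) for c in range(3, 9) if rng.random() < 0.8 or (r, c) == (3, 3)]
    cells_b = [(r, c) for r in range(18, 26) for c in range(15, 24) if rng.random() < 0.8 or (r, c) == (18, 15)]
    a = make_patch("A", cells_a, shape, 500.0)
    b = make_patch("B", cells_b, shape, 500.0)
    got = euclidean_patch_distance(a, b, 500.0)
    brute = min(
        np.hypot(r1 - r2, c1 - c2) for r1, c1 in map(tuple, a.boundary_cells) for r2, c2 in map(tuple, b.boundary_cells)
    )
    assert got == pytest.approx(brute * 500.0 / 1000.0)
    with pytest.raises(ValueError, match="overlap"):
        euclidean_patch_distance(a, make_patch("C", cells_a[:3], shape, 500.0), 500.0)


def test_extant_polygon_rasterization():
    template = RasterGrid(np.zeros((10, 10)), 100.0, origin=(0.0, 0.0))
    # axis-aligned square covering exactly the 4x4 block of cell centers
    # x in [200, 600], y in [200, 600] -> cols 2..5, rows 4..7
    poly = {
        "type": "Feature",
        "properties": {"name": "HD"},
        "geometry": {
            "type": "Polygon",
            "coordinates": [[[200, 200], [600, 200], [600, 600], [200, 600], [200, 200]]],
        },
    }
    got = load_extant_patches({"type": "FeatureCollection", "features": [poly]}, template)
    assert len(got) == 1 and got[0].id == "HD" and got[0].label == "extant"
    assert got[0].n_cells == 16
    tiny = dict(poly)
    tiny["geometry"] = {"type": "Polygon", "coordinates": [[[210, 210], [220, 210], [220, 220], [210, 210]]]}
    with pytest.raises(ValueError, match="no cell center"):
        load_extant_patches({"type": "FeatureCollection", "features": [tiny]}, template)


def test_convex_polygon_matches_half_plane_oracle():
    rng = np.random.default_rng(21)
    template = RasterGrid(np.zeros((25, 25)), 40.0, origin=(0.0, 0.0))
    pts = rng.uniform(100, 900, size=(8, 2))
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    ring = pts[hull.vertices]
    feat = {
        "type": "Feature",
        "properties": {"name": "X"},
        "geometry": {"type": "Polygon", "coordinates": [ring.tolist() + [ring[0].tolist()]]},
    }
    got = load_extant_patches({"type": "FeatureCollection", "features": [feat]}, template)

    def inside(px, py):
        # ccw hull: point is inside iff left of every edge
        n = len(ring)
        for i in range(n):
            x1, y1 = ring[i]
            x2, y2 = ring[(i + 1) % n]
            if (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1) < 0:
                return False
        return True

    expect = {
        (r, c)
        for r in range(25)
        for c in range(25)
        if inside(*template.cell_center(r, c))
    }
    assert {tuple(x) for x in got[0].cells} == expect
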