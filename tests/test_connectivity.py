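"""Cost-distance fields, least-cost paths and corridor extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchconnect.connectivity import (
    corridor_surface,
    corridor_width_cost,
    cost_distance,
    least_cost_path,
)

from .conftest import make_cost_surface, make_patch, oracle_cost_distance

SQRT2 = math.sqrt(2)


def test_unit_cost_closed_form_neighbors():
    surf = make_cost_surface(np.ones((5, 5)), cell_size_m=1.0)
    src = make_patch("A", [(2, 2)], (5, 5))
    cd = cost_distance(surf, src)
    assert cd.values[2, 2] == 0.0
    assert cd.values[2, 3] == pytest.approx(1.0)
    assert cd.values[1, 1] == pytest.approx(SQRT2)
    assert cd.values[2, 4] == pytest.approx(2.0)


def test_barrier_ring_isolates_source():
    barrier = np.zeros((7, 7), dtype=bool)
    barrier[1:6, 1] = barrier[1:6, 5] = barrier[1, 1:6] = barrier[5, 1:6] = True
    surf = make_cost_surface(np.ones((7, 7)), barrier=barrier)
    cd = cost_distance(surf, make_patch("A", [(3, 3)], (7, 7)))
    outside = np.ones((7, 7), dtype=bool)
    outside[1:6, 1:6] = False
    assert np.all(np.isinf(cd.values[outside]))
    assert np.isfinite(cd.values[3, 2])
    # a source entirely on barrier cells is an error
    with pytest.raises(ValueError, match="barrier"):
        cost_distance(surf, make_patch("B", [(1, 1)], (7, 7)))


@pytest.mark.parametrize("seed", range(25))
def test_field_matches_bruteforce_oracle_bitwise(seed):
    rng = np.random.default_rng(seed)
    shape = rng.integers(5, 13, size=2)
    cost = rng.integers(1, 11, size=shape).astype(float)
    barrier = rng.random(shape) < 0.15
    src = tuple(rng.integers(0, shape))
    barrier[src] = False
    surf = make_cost_surface(cost, cell_size_m=float(rng.choice([1.0, 30.0, 250.0])), barrier=barrier)
    cd = cost_distance(surf, make_patch("A", [src], tuple(shape)))
    oracle = oracle_cost_distance(cost, ~barrier, _mask(shape, [src]), surf.cell_size_m)
    assert np.array_equal(cd.values, oracle)  # bit-for-bit


def test_field_matches_scipy_csgraph():
    # independent cross-check through scipy's Dijkstra on the same graph
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra as scipy_dijkstra

    rng = np.random.default_rng(99)
    shape = (10, 10)
    cost = rng.integers(1, 11, size=shape).astype(float)
    surf = make_cost_surface(cost, cell_size_m=30.0)
    cd = cost_distance(surf, make_patch("A", [(0, 0)], shape))
    n = 100
    g = lil_matrix((n, n))
    for r in range(10):
        for c in range(10):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (dr or dc) and 0 <= rr < 10 and 0 <= cc < 10:
                        d = 30.0 * (SQRT2 if dr and dc else 1.0)
                        g[r * 10 + c, rr * 10 + cc] = (cost[r, c] + cost[rr, cc]) / 2.0 * d
    ref = scipy_dijkstra(g.tocsr(), indices=[0]).reshape(shape)
    assert np.allclose(cd.values, ref)


def _mask(shape, cells):
    m = np.zeros(tuple(shape), dtype=bool)
    for r, c in cells:
        m[r, c] = True
    return m


def test_monotonicity_under_cost_increase_and_barriers():
    rng = np.random.default_rng(4)
    cost = rng.integers(1, 10, size=(9, 9)).astype(float)
    src = make_patch("A", [(0, 0)], (9, 9))
    base = cost_distance(make_cost_surface(cost), src).values
    higher = cost.copy()
    higher[4, 4] += 5
    up = cost_distance(make_cost_surface(higher), src).values
    assert np.all(up >= base - 1e-12)
    barrier = np.zeros((9, 9), dtype=bool)
    barrier[4, :5] = True
    blocked = cost_distance(make_cost_surface(cost, barrier=barrier), src).values
    ok = np.isfinite(blocked)
    assert np.all(blocked[ok] >= base[ok] - 1e-12)


def test_symmetry_of_pair_cost():
    rng = np.random.default_rng(12)
    cost = rng.integers(1, 11, size=(12, 12)).astype(float)
    surf = make_cost_surface(cost, cell_size_m=100.0)
    a = make_patch("A", [(1, 1), (1, 2), (2, 1)], (12, 12))
    b = make_patch("B", [(9, 10), (10, 10)], (12, 12))
    cd_a = cost_distance(surf, a)
    cd_b = cost_distance(surf, b)
    cost_ab = cd_a.values[b.cells[:, 0], b.cells[:, 1]].min()
    cost_ba = cd_b.values[a.cells[:, 0], a.cells[:, 1]].min()
    assert cost_ab == pytest.approx(cost_ba, rel=1e-12)


def test_lcp_uniform_cost_closed_form():
    c0, k, s = 3.0, 6, 25.0
    surf = make_cost_surface(np.full((4, 10), c0), cell_size_m=s)
    a = make_patch("A", [(2, 1)], (4, 10), s)
    b = make_patch("B", [(2, 1 + k)], (4, 10), s)
    path = least_cost_path(surf, a, b)
    assert path.total_cost == pytest.approx(c0 * k * s)
    assert path.length_km == pytest.approx(k * s / 1000.0)
    assert path.cells[0] == (2, 1) and path.cells[-1] == (2, 7)


def test_lcp_routes_through_barrier_gap():
    cost = np.ones((11, 11))
    barrier = np.zeros((11, 11), dtype=bool)
    barrier[:, 5] = True
    barrier[8, 5] = False  # the gap
    surf = make_cost_surface(cost, barrier=barrier)
    a = make_patch("A", [(2, 1)], (11, 11))
    b = make_patch("B", [(2, 9)], (11, 11))
    path = least_cost_path(surf, a, b)
    assert (8, 5) in path.cells
    oracle = oracle_cost_distance(cost, ~barrier, _mask((11, 11), [(2, 1)]), 1.0)
    assert path.total_cost == pytest.approx(oracle[2, 9])
    # fully blocked -> no-path result, not an error
    barrier[8, 5] = True
    none = least_cost_path(make_cost_surface(cost, barrier=barrier), a, b)
    assert none is None


def test_adjacent_patches_degenerate_path():
    surf = make_cost_surface(np.full((3, 3), 4.0), cell_size_m=10.0)
    a = make_patch("A", [(1, 1)], (3, 3), 10.0)
    b = make_patch("B", [(1, 2)], (3, 3), 10.0)
    path = least_cost_path(surf, a, b)
    assert path.total_cost == pytest.approx(4.0 * 10.0)  # one orthogonal step
    assert len(path.cells) == 2


def test_lcp_length_at_least_euclidean():
    from patchconnect.patches import euclidean_patch_distance

    rng = np.random.default_rng(8)
    for _ in range(5):
        cost = rng.integers(1, 11, size=(15, 15)).astype(float)
        surf = make_cost_surface(cost, cell_size_m=100.0)
        a = make_patch("A", [(2, 2)], (15, 15), 100.0)
        b = make_patch("B", [(12, 11)], (15, 15), 100.0)
        path = least_cost_path(surf, a, b)
        eps = 100.0 * SQRT2 / 1000.0
        assert path.length_km >= euclidean_patch_distance(a, b, 100.0) - eps


def test_corridor_minimum_equals_lcp_cost():
    rng = np.random.default_rng(17)
    cost = rng.integers(1, 11, size=(12, 12)).astype(float)
    surf = make_cost_surface(cost, cell_size_m=50.0)
    a = make_patch("A", [(1, 1)], (12, 12), 50.0)
    b = make_patch("B", [(10, 9)], (12, 12), 50.0)
    cd_a, cd_b = cost_distance(surf, a), cost_distance(surf, b)
    C = corridor_surface(cd_a, cd_b)
    path = least_cost_path(surf, a, b, field_a=cd_a)
    assert C.min_value == pytest.approx(path.total_cost, rel=1e-12)
    # oracle: sum of two independently brute-forced fields
    oa = oracle_cost_distance(cost, np.ones((12, 12), bool), _mask((12, 12), [(1, 1)]), 50.0)
    ob = oracle_cost_distance(cost, np.ones((12, 12), bool), _mask((12, 12), [(10, 9)]), 50.0)
    assert np.allclose(C.values, oa + ob)
    # the backtracked path stays within one maximal step cost of the optimum
    max_step = 10.0 * 50.0 * SQRT2
    on_path = np.array([C.values[r, c] for r, c in path.cells])
    assert np.all(on_path <= C.min_value + max_step + 1e-9)


def _simple_corridor_setup(width_cells=20, cell=100.0):
    shape = (width_cells, 30)
    surf = make_cost_surface(np.ones(shape), cell_size_m=cell)
    a = make_patch("A", [(width_cells // 2, 2)], shape, cell)
    b = make_patch("B", [(width_cells // 2, 27)], shape, cell)
    cd_a, cd_b = cost_distance(surf, a), cost_distance(surf, b)
    return corridor_surface(cd_a, cd_b), surf, a, b


def test_zero_width_threshold_is_corridor_minimum():
    C, *_ = _simple_corridor_setup()
    res = corridor_width_cost(C, width_km=0.0)
    assert res.achieved
    assert res.threshold_cost == pytest.approx(C.min_value)


def test_width_cost_matches_exhaustive_sweep_oracle():
    from patchconnect.connectivity import _corridor_links

    C, *_ = _simple_corridor_setup(width_cells=14, cell=100.0)
    for width_km in (0.4, 0.8):
        res = corridor_width_cost(C, width_km=width_km)
        finite = np.unique(C.values[np.isfinite(C.values)])
        oracle = next(t for t in finite if _corridor_links(C, float(t), width_km * 500.0))
        assert res.achieved and res.threshold_cost == pytest.approx(float(oracle))


def test_width_cost_nondecreasing_in_width():
    C, *_ = _simple_corridor_setup()
    prev = -np.inf
    for w in (0.0, 0.2, 0.5, 1.0):
        res = corridor_width_cost(C, width_km=w)
        assert res.achieved
        assert res.threshold_cost >= prev - 1e-9
        prev = res.threshold_cost


def test_unachievable_width_reports_bounded_failure():
    cost = np.ones((15, 15))
    barrier = np.zeros((15, 15), dtype=bool)
    barrier[:, 7] = True
    barrier[7, 7] = False  # one-cell gap, far narrower than the request
    surf = make_cost_surface(cost, cell_size_m=100.0, barrier=barrier)
    a = make_patch("A", [(7, 1)], (15, 15), 100.0)
    b = make_patch("B", [(7, 13)], (15, 15), 100.0)
    C = corridor_surface(cost_distance(surf, a), cost_distance(surf, b), barrier_mask=barrier)
    res = corridor_width_cost(C, width_km=1.0)
    assert not res.achieved
    assert np.isnan(res.threshold_cost)
    assert res.max_achievable_width_km is not None and res.max_achievable_width_km < 1.0
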