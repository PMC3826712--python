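"""Weighted overlay and resampling behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchconnect.ahp import WeightSet
from patchconnect.classification import (
    COST_VARIABLES,
    SUITABILITY_VARIABLES,
    ScoreGrid,
    default_suitability_weights,
)
from patchconnect.grid import RasterGrid
from patchconnect.surfaces import resample_to, weighted_overlay


def _score_grids(arrays, cell=250.0, barriers=None):
    out = {}
    for i, (name, arr) in enumerate(arrays.items()):
        g = RasterGrid(np.asarray(arr, dtype=float), cell)
        b = None if barriers is None else barriers.get(name)
        out[name] = ScoreGrid(g, b)
    return out


def _uniform_layers(names, value, shape=(4, 4)):
    return {n: np.full(shape, float(value)) for n in names}


def test_constant_layers_give_constant_surface():
    grids = _score_grids(_uniform_layers(SUITABILITY_VARIABLES, 10))
    surf = weighted_overlay(grids, default_suitability_weights(), "suitability")
    assert np.allclose(surf.values, 10.0)


def test_two_level_weighted_arithmetic():
    # scores 5 on slope (weight 0.3891), 10 elsewhere -> 10 - 0.3891 * 5
    layers = _uniform_layers(SUITABILITY_VARIABLES, 10)
    layers["slope"][:] = 5.0
    grids = _score_grids(layers)
    surf = weighted_overlay(grids, default_suitability_weights(), "suitability")
    assert np.allclose(surf.values, 10.0 - 0.3891 * 5.0)


def test_barrier_dominates_any_weight():
    layers = _uniform_layers(SUITABILITY_VARIABLES, 10)
    barriers = {"elevation": np.zeros((4, 4), dtype=bool)}
    barriers["elevation"][1, 2] = True
    grids = _score_grids(layers, barriers=barriers)
    surf = weighted_overlay(grids, default_suitability_weights(), "suitability")
    assert bool(surf.barrier_mask[1, 2])
    assert np.isnan(surf.values[1, 2])
    assert not surf.barrier_mask[0, 0]


def test_weight_and_name_validation():
    layers = _uniform_layers(SUITABILITY_VARIABLES, 10)
    grids = _score_grids(layers)
    bad = {k: v for k, v in default_suitability_weights().weights.items()}
    bad.pop("slope")
    with pytest.raises(KeyError):
        weighted_overlay(grids, WeightSet.from_weights(bad), "suitability")
    # cost-only variables cannot enter a suitability overlay
    wrong = _score_grids(_uniform_layers(COST_VARIABLES, 5))
    w = WeightSet.from_weights({n: 1 / len(COST_VARIABLES) for n in COST_VARIABLES})
    with pytest.raises(ValueError, match="requires exactly"):
        weighted_overlay(wrong, w, "suitability")


def test_mismatched_geometry_rejected():
    grids = _score_grids(_uniform_layers(SUITABILITY_VARIABLES, 10))
    grids["ndvi"] = ScoreGrid(RasterGrid(np.full((4, 4), 10.0), 30.0))  # different cell size
    with pytest.raises(ValueError, match="share"):
        weighted_overlay(grids, default_suitability_weights(), "suitability")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0.0, 1.0))
def test_overlay_linear_in_weights_and_bounded(seed, alpha):
    rng = np.random.default_rng(seed)
    layers = {n: rng.integers(1, 11, size=(5, 5)).astype(float) for n in SUITABILITY_VARIABLES}
    grids = _score_grids(layers)

    def rand_weights():
        w = rng.uniform(0.05, 1.0, size=len(SUITABILITY_VARIABLES))
        w /= w.sum()
        return WeightSet.from_weights(dict(zip(SUITABILITY_VARIABLES, w)))

    w1, w2 = rand_weights(), rand_weights()
    mix = WeightSet.from_weights(
        {n: alpha * w1.weights[n] + (1 - alpha) * w2.weights[n] for n in SUITABILITY_VARIABLES}
    )
    s1 = weighted_overlay(grids, w1, "suitability").values
    s2 = weighted_overlay(grids, w2, "suitability").values
    sm = weighted_overlay(grids, mix, "suitability").values
    assert np.allclose(sm, alpha * s1 + (1 - alpha) * s2, atol=1e-9)
    for s in (s1, s2, sm):
        assert np.all(s >= 1.0 - 1e-9) and np.all(s <= 10.0 + 1e-9)


def test_resample_identity_and_constant():
    g = RasterGrid(np.arange(16, dtype=float).reshape(4, 4), 250.0, origin=(10.0, 20.0))
    same = resample_to(g, 250.0, (4, 4), (10.0, 20.0))
    assert np.array_equal(same.values, g.values)
    const = resample_to(RasterGrid(np.full((4, 4), 7.0), 250.0), 50.0)
    assert const.shape == (20, 20)
    assert np.all(const.values == 7.0)


def test_resample_checkerboard_against_index_oracle():
    src = RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 250.0)
    out = resample_to(src, 125.0)
    assert out.shape == (4, 4)
    # oracle: target cell (r, c) maps to source cell (r // 2, c // 2)
    expect = np.array([[src.values[r // 2, c // 2] for c in range(4)] for r in range(4)])
    assert np.array_equal(out.values, expect)


def test_resample_extent_error():
    g = RasterGrid(np.zeros((4, 4)), 250.0)
    with pytest.raises(ValueError, match="extent"):
        resample_to(g, 250.0, (5, 5), (0.0, 0.0))
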