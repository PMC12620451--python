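"""Vegetation-index formulas: oracle equivalence, bounds, masking."""

import math

import numpy as np
import pytest

from cropnpp.errors import MissingBandError, UnknownIndexError
from cropnpp.grids import ReflectanceStack
from cropnpp.indices import (INDEX_NAMES, IndexParams, compute_all,
                             compute_index)

from conftest import make_stack

A, S, X, L = 0.08, 1.2, 0.08, 0.5  # default soil-line / calibration constants

# Independent scalar re-implementation of every formula, written directly
# from the definitions; used as the oracle against the vectorized module.
ORACLE = {
    "NDVI": lambda b: (b["B8"] - b["B4"]) / (b["B8"] + b["B4"]),
    "DVI": lambda b: b["B8"] - b["B4"],
    "RVI": lambda b: b["B8"] / b["B4"],
    "EVI": lambda b: 2.5 * (b["B8"] - b["B4"]) / (b["B8"] + 6 * b["B4"] - 7.5 * b["B2"] + 1),
    "ARVI": lambda b: (b["B8"] - (2 * b["B4"] - b["B2"])) / (b["B8"] + (2 * b["B4"] - b["B2"])),
    "GNDVI": lambda b: (b["B7"] - b["B3"]) / (b["B7"] + b["B3"]),
    "NDI45": lambda b: (b["B5"] - b["B4"]) / (b["B5"] + b["B4"]),
    "MSAVI": lambda b: (2 * b["B8"] + 1 - math.sqrt((2 * b["B8"] + 1) ** 2 - 8 * (b["B8"] - b["B4"]))) / 2,
    "GEMI": lambda b: (lambda n: n * (1 - 0.25 * n) - (b["B4"] - 0.125) / (1 - b["B4"]))(
        (2 * (b["B8A"] ** 2 - b["B4"] ** 2) + 1.5 * b["B8A"] + 0.5 * b["B4"]) / (b["B8A"] + b["B4"] + 0.5)),
    "REIP": lambda b: 705 + 35 * ((b["B4"] + b["B7"]) / 2 - b["B5"]) / (b["B6"] - b["B5"]),
    "SAVI": lambda b: (1 + L) * (b["B8"] - b["B4"]) / (b["B8"] + b["B4"] + L),
    "TNDVI": lambda b: (math.sqrt((b["B8"] - b["B4"]) / (b["B8"] + b["B4"]) + 0.5)
                        if (b["B8"] - b["B4"]) / (b["B8"] + b["B4"]) + 0.5 >= 0
                        else math.nan),
    "PVI": lambda b: (b["B8"] - S * b["B4"] - A) / math.sqrt(S ** 2 + 1),
    "WDVI": lambda b: b["B8"] - S * b["B4"],
    "TSAVI": lambda b: S * (b["B8"] - S * b["B4"] - A) / (A * b["B8"] + b["B4"] - A * S + X * (1 + S ** 2)),
}


def test_oracle_equivalence_random_band_vectors(rng):
    """All 15 indices match an independent scalar evaluator to <=1e-10."""
    n = 200
    vecs = [{bn: float(rng.uniform(0.02, 0.6)) for bn in
             ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A")} for _ in range(n)]
    for name in INDEX_NAMES:
        stack = make_stack({}, shape=(1, n))
        for bn in stack.bands:
            stack.bands[bn][0, :] = [v[bn] for v in vecs]
        out = compute_index(stack, name)
        got = out.values[0]
        want = np.array([ORACLE[name](v) for v in vecs])
        valid = out.valid[0]
        np.testing.assert_array_equal(valid, np.isfinite(want), err_msg=name)
        assert np.max(np.abs(got[valid] - want[valid])) <= 1e-10, name


@pytest.mark.parametrize("name,bands,expected", [
    ("NDVI", {"B8": 0.40, "B4": 0.08}, 2 / 3),
    ("NDVI", {"B8": 0.30, "B4": 0.30}, 0.0),
    ("RVI", {"B8": 0.40, "B4": 0.10}, 4.0),
    ("REIP", {"B4": 0.05, "B5": 0.10, "B6": 0.20, "B7": 0.25}, 722.5),
    ("DVI", {"B8": 0.45, "B4": 0.20}, 0.25),
])
def test_hand_computed_values(name, bands, expected):
    g = compute_index(make_stack(bands), name)
    assert g.values == pytest.approx(expected, abs=1e-6)


def test_savi_reduces_to_ndvi_at_zero_L(rng):
    stack = make_stack({bn: rng.uniform(0.05, 0.5) for bn in ("B4", "B8")})
    savi = compute_index(stack, "SAVI", IndexParams(savi_L=0.0))
    ndvi = compute_index(stack, "NDVI")
    np.testing.assert_allclose(savi.values, ndvi.values, atol=1e-12)


def test_normalized_difference_bounds(rng):
    stack = make_stack({}, shape=(8, 8))
    for bn in stack.bands:
        stack.bands[bn][:] = rng.uniform(0.01, 1.0, size=(8, 8))
    for name in ("NDVI", "GNDVI", "NDI45"):
        g = compute_index(stack, name)
        v = g.valid_values()
        assert (v >= -1).all() and (v <= 1).all()


def test_ndvi_strictly_increasing_in_nir():
    b8 = np.linspace(0.05, 0.9, 30)
    stack = make_stack({"B4": 0.2}, shape=(1, 30))
    stack.bands["B8"][0, :] = b8
    v = compute_index(stack, "NDVI").values[0]
    assert (np.diff(v) > 0).all()


def test_uniform_stack_gives_constant_layers(small_scene):
    stack = make_stack({bn: 0.1 + i * 0.03 for i, bn in
                        enumerate(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A"))})
    cube = compute_all(stack)
    for name in INDEX_NAMES:
        v = cube[name].valid_values()
        assert np.ptp(v) < 1e-12, name


def test_mask_propagates_to_all_layers():
    mask = np.zeros((4, 4), bool)
    mask[1, 2] = True
    cube = compute_all(make_stack({"B8": 0.4, "B4": 0.1}, mask=mask))
    for name in INDEX_NAMES:
        assert cube[name].mask[1, 2]
        assert cube[name].valid.sum() <= 15  # mask conservation


def test_zero_denominator_masks_not_inf():
    # B6 == B5 makes the red-edge interpolation denominator vanish
    g = compute_index(make_stack({"B5": 0.2, "B6": 0.2, "B4": 0.1, "B7": 0.3}), "REIP")
    assert g.mask.all()
    assert not np.isinf(g.values[np.isfinite(g.values)]).any()


def test_tndvi_masked_where_radicand_negative():
    # NDVI = -0.6 -> radicand -0.1 < 0
    g = compute_index(make_stack({"B8": 0.1, "B4": 0.4}), "TNDVI")
    assert g.mask.all()


def test_unknown_index_and_missing_band_errors():
    stack = make_stack({"B8": 0.4, "B4": 0.1})
    with pytest.raises(UnknownIndexError):
        compute_index(stack, "NOPE")
    del stack.bands["B2"]
    with pytest.raises(MissingBandError, match="B2"):
        compute_index(stack, "EVI")


def test_all_masked_warns_but_returns():
    mask = np.ones((4, 4), bool)
    with pytest.warns(UserWarning, match="all pixels masked"):
        g = compute_index(make_stack({"B8": 0.4, "B4": 0.1}, mask=mask), "NDVI")
    assert g.mask.all()


def test_reflectance_clamping_and_invalid_masking():
    vals = np.full((2, 2), 0.3)
    vals[0, 0] = -0.005  # clamped to 0
    vals[0, 1] = 1.5  # invalid -> masked
    stack = make_stack({"B4": vals, "B8": 0.4}, shape=(2, 2))
    assert stack.bands["B4"][0, 0] == 0.0
    assert stack.mask[0, 1]
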