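"""Discretization and first-order intensity features."""

import numpy as np
import pytest

from ctphantom.radiomics import discretize, first_order_features


def test_floor_discretization_example():
    vals = np.array([0.0, 24.0, 25.0, 49.0]).reshape(4, 1, 1)
    mask = np.ones((4, 1, 1), dtype=bool)
    d = discretize(vals, mask, bin_width=25.0)
    assert d.levels.ravel().tolist() == [1, 1, 2, 2]
    assert d.n_levels == 2


def test_constant_region_single_level_flagged():
    vals = np.full((3, 3, 3), 7.0)
    with pytest.warns(UserWarning):
        d = discretize(vals, np.ones((3, 3, 3), bool), 25.0)
    assert d.n_levels == 1 and d.degenerate
    assert np.all(d.levels == 1)


def test_level_count_matches_bruteforce_recount(rng):
    vals = rng.normal(-600, 120, (9, 8, 7))
    mask = rng.random((9, 8, 7)) > 0.3
    d = discretize(vals, mask, 25.0)
    vmin = vals[mask].min()
    expected = {
        int(np.floor((vals[idx] - vmin) / 25.0)) + 1
        for idx in zip(*np.nonzero(mask))
    }
    assert d.n_levels == max(expected)
    for idx in zip(*np.nonzero(mask)):
        assert d.levels[idx] == int(np.floor((vals[idx] - vmin) / 25.0)) + 1


def test_shift_moves_anchor_not_levels(rng):
    vals = rng.normal(0, 50, (6, 6, 6))
    mask = np.ones((6, 6, 6), bool)
    a = discretize(vals, mask, 25.0)
    b = discretize(vals + 100.0, mask, 25.0)
    assert np.array_equal(a.levels, b.levels)


def test_first_order_constant_cube():
    vals = np.full((2, 2, 2), 5.0)
    mask = np.ones((2, 2, 2), bool)
    f = first_order_features(vals, mask, voxel_volume=1.0)
    assert f["Mean"] == 5.0
    assert f["Variance"] == 0.0
    assert f["Energy"] == 200.0
    assert f["TotalEnergy"] == 200.0
    assert f["Range"] == 0.0
    assert f["Uniformity"] == 1.0
    assert f["Entropy"] == 0.0


def test_first_order_small_example():
    vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
    mask = np.ones((4, 1, 1), bool)
    f = first_order_features(vals, mask)
    assert f["Mean"] == 2.5
    assert f["Median"] == 2.5
    assert f["Range"] == 3.0
    assert f["Minimum"] == 1.0 and f["Maximum"] == 4.0
    assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30.0 / 4.0))


def test_first_order_matches_streaming_oracle(rng):
    """All 18 statistics agree with an independent per-voxel recomputation."""
    vals = rng.normal(-500, 80, (10, 9, 8))
    mask = rng.random((10, 9, 8)) > 0.4
    vv = 0.5 * 0.5 * 1.0
    f = first_order_features(vals, mask, voxel_volume=vv, bin_width=25.0)

    x = sorted(float(vals[i]) for i in zip(*np.nonzero(mask)))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    hist = {}
    for v in x:
        hist[int((v - x[0]) // 25.0)] = hist.get(int((v - x[0]) // 25.0), 0) + 1
    probs = [c / n for c in hist.values()]
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    expected = {
        "Energy": sum(v**2 for v in x),
        "TotalEnergy": vv * sum(v**2 for v in x),
        "Entropy": -sum(p * np.log2(p) for p in probs),
        "Minimum": x[0],
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust)
        / len(robust),
        "RootMeanSquared": (sum(v**2 for v in x) / n) ** 0.5,
        "Skewness": (sum((v - mean) ** 3 for v in x) / n) / var**1.5,
        "Kurtosis": (sum((v - mean) ** 4 for v in x) / n) / var**2,
        "Variance": var,
        "Uniformity": sum(p**2 for p in probs),
    }
    assert set(f) == set(expected)
    for k, v in expected.items():
        assert f[k] == pytest.approx(v, rel=1e-9), k
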