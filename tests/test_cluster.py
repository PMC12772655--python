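"""PCA embedding and cluster consistency/separability statistics."""

import numpy as np
import pytest

from ctphantom.cluster import (
    fit_pca,
    nearest_centroid_accuracy,
    project,
    separability,
    within_cluster_distance,
)
from _oracles import separability_bruteforce, within_cluster_bruteforce


def test_rank_one_data_needs_one_component(rng):
    t = rng.normal(size=200)
    X = np.outer(t, [1.0, -2.0, 0.5]) + 3.0
    space = fit_pca(X)
    assert space.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
    assert space.n_retained == 1


def test_isotropic_gaussian_splits_evenly(rng):
    X = rng.normal(size=(4000, 2))
    space = fit_pca(X)
    assert space.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.03)
    assert space.explained_variance_ratio[1] == pytest.approx(0.5, abs=0.03)


def test_retained_count_is_minimal(rng):
    X = rng.normal(size=(60, 10)) * np.linspace(3, 0.2, 10)
    space = fit_pca(X)
    cum = np.cumsum(space.explained_variance_ratio)
    m = space.n_retained
    assert cum[m - 1] >= 0.95
    if m > 1:
        assert cum[m - 2] < 0.95
    # variance fractions non-increasing and sum to <= 1
    evr = space.explained_variance_ratio
    assert np.all(np.diff(evr) <= 1e-12)
    assert evr.sum() <= 1.0 + 1e-9


def test_full_rank_projection_preserves_geometry(rng):
    X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6)) + rng.normal(size=6)
    space = fit_pca(X)
    full = project(X, space, n_components=len(space.feature_names))
    # orthogonal reconstruction of the standardized data
    Z = space.standardize(X)
    np.testing.assert_allclose(full @ space.components, Z, atol=1e-8)
    # centroid at the origin
    np.testing.assert_allclose(full.mean(axis=0), 0.0, atol=1e-9)
    # pairwise distances preserved at full rank
    from scipy.spatial.distance import pdist

    np.testing.assert_allclose(pdist(full), pdist(Z), atol=1e-8)


def test_constant_feature_dropped_with_warning(rng):
    X = rng.normal(size=(30, 4))
    X[:, 2] = 7.0
    with pytest.warns(UserWarning):
        space = fit_pca(X)
    assert len(space.feature_names) == 3
    assert space.dropped == ("f2",)


def test_projection_name_mismatch_rejected(rng):
    import pandas as pd

    df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
    space = fit_pca(df)
    with pytest.raises(ValueError):
        project(df.rename(columns={"c": "z"}), space)


def test_deterministic_sign_convention(rng):
    X = rng.normal(size=(50, 5))
    s1, s2 = fit_pca(X), fit_pca(X.copy())
    np.testing.assert_array_equal(s1.components, s2.components)
    for row in s1.components:
        assert row[np.argmax(np.abs(row))] > 0


def test_within_cluster_hand_examples():
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [5.0, 5.0]])
    labels = ["a", "a", "b"]
    out = within_cluster_distance(pts, labels)
    assert out["a"] == (pytest.approx(1.0), pytest.approx(0.0))
    assert out["b"] == (0.0, 0.0)  # singleton cluster


def test_within_cluster_matches_bruteforce(rng):
    pts = rng.normal(size=(50, 4))
    labels = rng.choice(["x", "y", "z"], size=50).tolist()
    ours = within_cluster_distance(pts, labels)
    expected = within_cluster_bruteforce(pts, labels)
    for lab in expected:
        assert ours[lab][0] == pytest.approx(expected[lab][0], rel=1e-12)
        assert ours[lab][1] == pytest.approx(expected[lab][1], rel=1e-12)


def test_separability_hand_example():
    pts = np.array(
        [[-2.0, 1.0], [-2.0, -1.0], [2.0, 1.0], [2.0, -1.0]]
    )
    labels = ["a", "a", "b", "b"]
    assert separability(pts, labels) == pytest.approx(4.0)


def test_separability_matches_bruteforce(rng):
    pts = rng.normal(size=(60, 3)) + np.repeat(
        rng.normal(scale=5, size=(3, 3)), 20, axis=0
    )
    labels = np.repeat(["a", "b", "c"], 20)
    assert separability(pts, labels) == pytest.approx(
        separability_bruteforce(pts, list(labels)), rel=1e-12
    )


def test_separability_scaling_properties(rng):
    pts = rng.normal(size=(90, 3)) + np.repeat(
        rng.normal(scale=4, size=(3, 3)), 30, axis=0
    )
    labels = np.repeat(["a", "b", "c"], 30)
    base = separability(pts, labels)
    # shrinking every cluster toward its centroid by 2 doubles separability
    shrunk = pts.copy()
    for lab in "abc":
        sel = labels == lab
        cen = pts[sel].mean(axis=0)
        shrunk[sel] = cen + (pts[sel] - cen) / 2.0
    assert separability(shrunk, labels) == pytest.approx(2.0 * base, rel=1e-9)
    # invariant under rotation, translation and uniform scaling
    theta = 0.7
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0],
         [np.sin(theta), np.cos(theta), 0],
         [0, 0, 1.0]]
    )
    moved = (pts @ R.T) * 3.0 + np.array([5.0, -2.0, 1.0])
    assert separability(moved, labels) == pytest.approx(base, rel=1e-9)


def test_simulated_gaussian_clusters_match_expectation(rng):
    """Three spherical Gaussian clusters with known centroids: separability
    approaches (mean centroid distance) / E||x - centroid|| at large n."""
    dim, n, sd = 3, 4000, 1.0
    cents = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
    pts = np.concatenate(
        [c + rng.normal(scale=sd, size=(n, dim)) for c in cents]
    )
    labels = np.repeat(["a", "b", "c"], n)
    # E||N(0, I_3)|| = sd * sqrt(2) * Gamma(2) / Gamma(1.5)
    expected_within = sd * np.sqrt(2) * 1.0 / (np.sqrt(np.pi) / 2)
    d = np.mean([10.0, 10.0, np.sqrt(200.0)])
    assert separability(pts, labels) == pytest.approx(
        d / expected_within, rel=0.03
    )
    assert nearest_centroid_accuracy(pts, labels) > 0.99


def test_empty_cluster_rejected():
    with pytest.raises(ValueError):
        separability(np.zeros((2, 2)), ["a", "a"])
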