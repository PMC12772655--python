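"""Texture matrices vs exhaustive brute-force enumeration, plus matrix
conservation laws and degenerate cases."""

import numpy as np
import pytest

from ctphantom.radiomics.discretize import discretize
from ctphantom.radiomics.features import (
    glcm_features,
    ngtdm_features,
)
from ctphantom.radiomics.matrices import (
    DIRECTIONS_13,
    gldm_matrix,
    glcm_matrices,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)
from _oracles import (
    gldm_bruteforce,
    glcm_bruteforce,
    glrlm_bruteforce,
    glszm_bruteforce,
    ngtdm_bruteforce,
)


def random_levels(rng, max_side=8, n_levels=4, hole_p=0.25):
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    levels[rng.random(shape) < hole_p] = 0
    if not (levels > 0).any():
        levels[0, 0, 0] = 1
    return levels


def assert_all_matrices_match(levels, n_levels=4):
    glcm = glcm_matrices(levels, n_levels)
    for k, d in enumerate(DIRECTIONS_13):
        np.testing.assert_array_equal(glcm[k], glcm_bruteforce(levels, n_levels, d))

    rlm = glrlm_matrices(levels, n_levels)
    for mat, d in zip(rlm, DIRECTIONS_13):
        expected = glrlm_bruteforce(levels, n_levels, d)
        got = {
            (g + 1, r + 1): int(mat[g, r])
            for g in range(mat.shape[0])
            for r in range(mat.shape[1])
            if mat[g, r]
        }
        assert got == expected

    szm = glszm_matrix(levels, n_levels)
    got = {
        (g + 1, s + 1): int(szm[g, s])
        for g in range(szm.shape[0])
        for s in range(szm.shape[1])
        if szm[g, s]
    }
    assert got == glszm_bruteforce(levels, n_levels)

    np.testing.assert_array_equal(
        gldm_matrix(levels, n_levels), gldm_bruteforce(levels, n_levels)
    )

    n_i, p_i, s_i = ngtdm_table(levels, n_levels)
    en, ep, es = ngtdm_bruteforce(levels, n_levels)
    np.testing.assert_allclose(n_i, en)
    np.testing.assert_allclose(p_i, ep)
    np.testing.assert_allclose(s_i, es, atol=1e-10)


@pytest.mark.parametrize("trial", range(20))
def test_matrices_equal_bruteforce_random_grids(trial):
    rng = np.random.default_rng(1000 + trial)
    assert_all_matrices_match(random_levels(rng))


def test_matrix_conservation_laws(rng):
    levels = random_levels(rng, max_side=8, n_levels=5)
    n_vox = int((levels > 0).sum())
    for mat in glrlm_matrices(levels, 5):
        r = np.arange(1, mat.shape[1] + 1)
        assert int((mat * r[None, :]).sum()) == n_vox
    szm = glszm_matrix(levels, 5)
    s = np.arange(1, szm.shape[1] + 1)
    assert int((szm * s[None, :]).sum()) == n_vox
    assert int(gldm_matrix(levels, 5).sum()) == n_vox
    glcm = glcm_matrices(levels, 5)
    for m in glcm:
        np.testing.assert_array_equal(m, m.T)  # symmetrized
        assert (m >= 0).all()


def test_checkerboard_contrast_one_along_axes():
    """3D two-level checkerboard: every axis-aligned neighbor pair differs
    by exactly one level, so per-direction GLCM contrast is exactly 1; along
    face diagonals parity matches and contrast is 0."""
    idx = np.indices((6, 6, 6)).sum(axis=0)
    levels = (idx % 2 + 1).astype(np.int32)
    mats = glcm_matrices(levels, 2)
    for k, d in enumerate(DIRECTIONS_13):
        p = mats[k] / mats[k].sum()
        i = np.arange(1, 3)
        contrast = float((p * (i[:, None] - i[None, :]) ** 2).sum())
        n_odd = sum(abs(c) for c in d) % 2
        assert contrast == (1.0 if n_odd else 0.0)


def test_single_level_degenerate_features():
    vals = np.zeros((4, 4, 4))
    mask = np.ones((4, 4, 4), bool)
    with pytest.warns(UserWarning):
        d = discretize(vals, mask, 25.0)
    g = glcm_features(d)
    assert g["JointEntropy"] == 0.0
    assert g["MaximumProbability"] == 1.0
    n = ngtdm_features(d)
    assert n["Coarseness"] == 1e6  # capped maximum for flat texture
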