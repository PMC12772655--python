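"""Gray-level texture matrix construction on discretized 3D ROIs.

All matrices use distance-1 neighborhoods: the 13 unique 3D direction
offsets (26-connectivity half-space) for GLCM and GLRLM, and the full
26-neighborhood for GLSZM zones, GLDM dependence counts and NGTDM
neighborhood averages.  Level 0 marks out-of-mask voxels throughout.

Everything here is counting; the implementations are vectorized but each is
verified in the test suite against exhaustive pure-Python enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import label as cc_label

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]


def _half_space_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0):
                    dirs.append((dx, dy, dz))
    return tuple(dirs)


#: The 13 unique distance-1 direction offsets (one per +/- pair).
DIRECTIONS_13 = _half_space_directions()


def _shift_slices(shape, offset):
    """Slice pairs (a, b) so that arr[a] and arr[b] pair each voxel v with
    its neighbor v + offset."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        if d == 0:
            sa.append(slice(None))
            sb.append(slice(None))
        elif d > 0:
            sa.append(slice(0, n - d))
            sb.append(slice(d, n))
        else:
            sa.append(slice(-d, n))
            sb.append(slice(0, n + d))
    return tuple(sa), tuple(sb)


def glcm_matrices(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence count matrices, shape (13, Ng, Ng)."""
    L = np.asarray(levels)
    Ng = int(n_levels)
    out = np.zeros((len(DIRECTIONS_13), Ng, Ng), dtype=np.int64)
    for k, off in enumerate(DIRECTIONS_13):
        sa, sb = _shift_slices(L.shape, off)
        a, b = L[sa], L[sb]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pair = (a[valid].astype(np.int64) - 1) * Ng + (b[valid] - 1)
        counts = np.bincount(pair, minlength=Ng * Ng).reshape(Ng, Ng)
        out[k] = counts + counts.T
    return out


def _plane(arr: np.ndarray, axis: int, index: int):
    sl = [slice(None)] * arr.ndim
    sl[axis] = index
    return arr[tuple(sl)]


def glrlm_matrices(levels: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Run-length count matrices P(gray level, run length), one per direction.

    Per direction the weighted sum ``sum_i sum_r P[i, r] * r`` equals the
    in-mask voxel count.
    """
    L = np.asarray(levels)
    Ng = int(n_levels)
    n_vox = int((L > 0).sum())
    out = []
    for off in DIRECTIONS_13:
        # Dynamic program: R[v] = run length of the maximal run starting at v
        # toward +off.  Process planes so v + off is ready before v.
        R = (L > 0).astype(np.int64)
        ax = next(i for i in range(3) if off[i] != 0)
        step = off[ax]
        rest = tuple(d for i, d in enumerate(off) if i != ax)
        planes = range(L.shape[ax] - 2, -1, -1) if step > 0 else range(1, L.shape[ax])
        for i in planes:
            cur, nxt = _plane(L, ax, i), _plane(L, ax, i + step)
            rcur, rnxt = _plane(R, ax, i), _plane(R, ax, i + step)
            sa, sb = _shift_slices(cur.shape, rest)
            eq = (cur[sa] == nxt[sb]) & (cur[sa] > 0)
            view = rcur[sa]
            view[eq] = 1 + rnxt[sb][eq]
        # Run starts: in-mask voxels whose -off predecessor differs.
        sa, sb = _shift_slices(L.shape, off)  # arr[sa] has neighbor arr[sb]
        starts = L > 0
        interior = np.zeros(L.shape, dtype=bool)
        interior[sb] = (L[sa] == L[sb]) & (L[sa] > 0)
        starts &= ~interior
        lv = L[starts].astype(np.int64)
        rl = R[starts]
        max_r = int(rl.max()) if rl.size else 1
        mat = np.bincount(
            (lv - 1) * max_r + (rl - 1), minlength=Ng * max_r
        ).reshape(Ng, max_r)
        assert int((mat * np.arange(1, max_r + 1)).sum()) == n_vox
        out.append(mat)
    return out


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix P(gray level, zone size), 26-connected zones."""
    L = np.asarray(levels)
    Ng = int(n_levels)
    structure = np.ones((3, 3, 3), dtype=int)
    pairs = []
    for g in range(1, Ng + 1):
        binary = L == g
        if not binary.any():
            continue
        lab, nz = cc_label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        pairs.append((g, sizes))
    max_s = max((int(s.max()) for _, s in pairs), default=1)
    mat = np.zeros((Ng, max_s), dtype=np.int64)
    for g, sizes in pairs:
        mat[g - 1] += np.bincount(sizes - 1, minlength=max_s)
    return mat


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P(gray level, dependence size).

    A 26-neighbor is dependent when |level difference| <= alpha; the
    dependence size is the dependent-neighbor count plus one (the center),
    so sizes span 1..27 and every in-mask voxel contributes one count.
    """
    L = np.asarray(levels).astype(np.int64)
    Ng = int(n_levels)
    dep = np.zeros(L.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        for o in (off, tuple(-d for d in off)):
            sa, sb = _shift_slices(L.shape, o)
            good = (L[sb] > 0) & (np.abs(L[sa] - L[sb]) <= alpha) & (L[sa] > 0)
            view = dep[sa]
            view[good] += 1
    inmask = L > 0
    j = dep[inmask] + 1
    lv = L[inmask]
    mat = np.bincount((lv - 1) * 27 + (j - 1), minlength=Ng * 27).reshape(Ng, 27)
    return mat


def ngtdm_table(levels: np.ndarray, n_levels: int):
    """Neighborhood gray-tone difference table.

    Returns ``(n_i, p_i, s_i)`` arrays over levels 1..Ng: counts and
    probabilities of valid voxels per level, and the summed absolute
    difference between each voxel's level and its 26-neighborhood average.
    Voxels without any in-mask neighbor are excluded.
    """
    L = np.asarray(levels).astype(np.float64)
    Ng = int(n_levels)
    inmask = L > 0
    nb_sum = np.zeros(L.shape)
    nb_cnt = np.zeros(L.shape)
    for off in DIRECTIONS_13:
        for o in (off, tuple(-d for d in off)):
            sa, sb = _shift_slices(L.shape, o)
            contrib = np.where(inmask[sb], L[sb], 0.0)
            nb_sum[sa] += contrib
            nb_cnt[sa] += inmask[sb]
    valid = inmask & (nb_cnt > 0)
    n_valid = int(valid.sum())
    n_i = np.zeros(Ng)
    s_i = np.zeros(Ng)
    if n_valid:
        lv = L[valid].astype(np.int64)
        diff = np.abs(L[valid] - nb_sum[valid] / nb_cnt[valid])
        n_i = np.bincount(lv - 1, minlength=Ng).astype(float)
        s_i = np.bincount(lv - 1, weights=diff, minlength=Ng)
    p_i = n_i / n_valid if n_valid else n_i
    return n_i, p_i, s_i
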