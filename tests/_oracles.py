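"""Independent brute-force oracles: naive pure-Python/numpy recomputations
of the quantities the package computes with vectorized code.  Deliberately
slow and literal; used on small instances only."""

from __future__ import annotations

import itertools
import math

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def glcm_bruteforce(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric co-occurrence counts by enumerating every voxel pair."""
    mat = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for v in itertools.product(*(range(n) for n in shape)):
        a = levels[v]
        if a == 0:
            continue
        w = tuple(v[i] + direction[i] for i in range(3))
        if _inside(shape, w) and levels[w] > 0:
            b = levels[w]
            mat[a - 1, b - 1] += 1
            mat[b - 1, a - 1] += 1
    return mat


def glrlm_bruteforce(levels: np.ndarray, n_levels: int, direction) -> dict:
    """(gray level, run length) -> count, by walking every maximal run."""
    counts: dict[tuple[int, int], int] = {}
    shape = levels.shape
    for v in itertools.product(*(range(n) for n in shape)):
        g = levels[v]
        if g == 0:
            continue
        prev = tuple(v[i] - direction[i] for i in range(3))
        if _inside(shape, prev) and levels[prev] == g:
            continue  # not a run start
        length = 1
        w = tuple(v[i] + direction[i] for i in range(3))
        while _inside(shape, w) and levels[w] == g:
            length += 1
            w = tuple(w[i] + direction[i] for i in range(3))
        counts[(g, length)] = counts.get((g, length), 0) + 1
    return counts


def glszm_bruteforce(levels: np.ndarray, n_levels: int) -> dict:
    """(gray level, zone size) -> count via BFS over 26-connected zones."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    for v in itertools.product(*(range(n) for n in shape)):
        g = levels[v]
        if g == 0 or seen[v]:
            continue
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = tuple(u[i] + d[i] for i in range(3))
                if _inside(shape, w) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        counts[(int(g), size)] = counts.get((int(g), size), 0) + 1
    return counts


def gldm_bruteforce(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix (Ng x 27): per voxel, count 26-neighbors within
    alpha of its level; dependence size = count + 1."""
    mat = np.zeros((n_levels, 27), dtype=np.int64)
    shape = levels.shape
    for v in itertools.product(*(range(n) for n in shape)):
        g = levels[v]
        if g == 0:
            continue
        dep = 0
        for d in NEIGHBORS_26:
            w = tuple(v[i] + d[i] for i in range(3))
            if _inside(shape, w) and levels[w] > 0 and abs(int(levels[w]) - int(g)) <= alpha:
                dep += 1
        mat[g - 1, dep] += 1
    return mat


def ngtdm_bruteforce(levels: np.ndarray, n_levels: int):
    shape = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for v in itertools.product(*(range(n) for n in shape)):
        g = levels[v]
        if g == 0:
            continue
        nb = []
        for d in NEIGHBORS_26:
            w = tuple(v[i] + d[i] for i in range(3))
            if _inside(shape, w) and levels[w] > 0:
                nb.append(int(levels[w]))
        if not nb:
            continue
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(nb) / len(nb))
    total = n_i.sum()
    p_i = n_i / total if total else n_i
    return n_i, p_i, s_i


def anova_f_bruteforce(groups) -> float:
    """Between/within mean-square ratio from the definition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(groups).mean()
    k = len(groups)
    n = sum(g.size for g in groups)
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def lilliefors_stat_bruteforce(x) -> float:
    """Sup-distance between the empirical CDF and the fitted normal CDF,
    evaluated on a fine grid plus at the jump points."""
    from scipy.stats import norm

    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    mu, sd = x.mean(), x.std(ddof=1)
    best = 0.0
    for i, xi in enumerate(x):
        f = norm.cdf((xi - mu) / sd)
        best = max(best, abs((i + 1) / n - f), abs(i / n - f))
    return best


def within_cluster_bruteforce(points, labels):
    points = np.asarray(points, dtype=float)
    out = {}
    for lab in dict.fromkeys(list(labels)):
        sub = points[[i for i, l in enumerate(labels) if l == lab]]
        cen = sub.mean(axis=0)
        d = [math.dist(p, cen) for p in sub]
        mean = sum(d) / len(d)
        sd = math.sqrt(sum((di - mean) ** 2 for di in d) / len(d))
        out[lab] = (mean, sd)
    return out


def separability_bruteforce(points, labels) -> float:
    points = np.asarray(points, dtype=float)
    uniq = list(dict.fromkeys(list(labels)))
    cents = {
        lab: points[[i for i, l in enumerate(labels) if l == lab]].mean(axis=0)
        for lab in uniq
    }
    between = [
        math.dist(cents[a], cents[b])
        for i, a in enumerate(uniq)
        for b in uniq[i + 1 :]
    ]
    within = within_cluster_bruteforce(points, labels)
    return (sum(between) / len(between)) / (
        sum(w[0] for w in within.values()) / len(within)
    )


def roi_stats_bruteforce(volume, origin, spacing, center_xy, z, radius):
    """Per-voxel loop over the disc: (mean, sample SD, n)."""
    vals = []
    nx, ny = volume.shape[:2]
    for i in range(nx):
        for j in range(ny):
            x = origin[0] + spacing[0] * i
            y = origin[1] + spacing[1] * j
            if (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius**2:
                vals.append(float(volume[i, j, z]))
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1)) if n > 1 else 0.0
    return mean, sd, n
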