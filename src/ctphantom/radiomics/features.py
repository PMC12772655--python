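"""Texture feature formulas for the five matrix families.

Formulas follow the harmonized definitions in common use (the de facto
standard extractor conventions): gray levels are 1-based bin labels,
directional families (GLCM, GLRLM) are averaged at the feature level over
the 13 distance-1 directions, and degenerate single-level regions take
their defined limits.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRoi
from .matrices import (
    gldm_matrix,
    glcm_matrices,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_EPS = np.spacing(1.0)

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "MCC",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

#: Cap applied to NGTDM coarseness when the denominator vanishes.
COARSENESS_MAX = 1e6


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    Ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        return dict.fromkeys(GLCM_NAMES, np.nan)
    p = counts / total
    i = np.arange(1, Ng + 1, dtype=float)
    I = i[:, None] * np.ones((1, Ng))
    J = np.ones((Ng, 1)) * i[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((px * i).sum())
    uy = float((py * i).sum())
    sx = float(np.sqrt((px * (i - ux) ** 2).sum()))
    sy = float(np.sqrt((py * (i - uy) ** 2).sum()))

    k_sum = np.arange(2, 2 * Ng + 1, dtype=float)
    p_sum = np.zeros(k_sum.size)
    k_diff = np.arange(0, Ng, dtype=float)
    p_diff = np.zeros(k_diff.size)
    sums = (I + J).astype(int)
    diffs = np.abs(I - J).astype(int)
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())
    np.add.at(p_diff, diffs.ravel(), p.ravel())

    contrast = float((p * (I - J) ** 2).sum())
    joint_entropy = _entropy2(p.ravel())
    hx, hy = _entropy2(px), _entropy2(py)
    pxy = px[:, None] * py[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxy[nz] + _EPS)).sum())
    nzq = pxy > 0
    hxy2 = float(-(pxy[nzq] * np.log2(pxy[nzq])).sum())
    imc1 = (joint_entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    if sx > 0 and sy > 0:
        correlation = float(((p * I * J).sum() - ux * uy) / (sx * sy))
        # Marginal-correlation matrix: second largest eigenvalue's sqrt.
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / px[:, None]) @ (p / py[:, None]).T
        q = np.nan_to_num(q)
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(np.clip(ev[-2], 0.0, 1.0))) if ev.size > 1 else 1.0
    else:
        correlation = 1.0
        mcc = 1.0

    da = float((k_diff * p_diff).sum())
    off = ~np.eye(Ng, dtype=bool)
    inv_var = float((p[off] / (I[off] - J[off]) ** 2).sum())
    return {
        "Autocorrelation": float((p * I * J).sum()),
        "ClusterProminence": float((p * (I + J - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (I + J - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (I + J - ux - uy) ** 2).sum()),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) / Ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / Ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": joint_entropy,
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float((p * (I - ux) ** 2).sum()),
    }


def glcm_features(d: DiscretizedRoi) -> dict[str, float]:
    mats = glcm_matrices(d.levels, d.n_levels)
    per_dir = [_glcm_features_single(m) for m in mats if m.sum() > 0]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


def _rlm_features_single(counts: np.ndarray, n_vox: int) -> dict[str, float]:
    Ng, Nr = counts.shape
    total = counts.sum()
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    r = np.arange(1, Nr + 1, dtype=float)[None, :]
    P = counts.astype(float)
    p = P / total
    ri = P.sum(axis=1)  # per gray level
    rj = P.sum(axis=0)  # per run length
    mu_i = float((p * i).sum())
    mu_r = float((p * r).sum())
    return {
        "GrayLevelNonUniformity": float((ri**2).sum() / total),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / total**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum() / total),
        "LongRunEmphasis": float((P * r**2).sum() / total),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * r**2).sum() / total),
        "LongRunLowGrayLevelEmphasis": float((P * r**2 / i**2).sum() / total),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum() / total),
        "RunEntropy": _entropy2(p.ravel()),
        "RunLengthNonUniformity": float((rj**2).sum() / total),
        "RunLengthNonUniformityNormalized": float((rj**2).sum() / total**2),
        "RunPercentage": float(total / n_vox),
        "RunVariance": float((p * (r - mu_r) ** 2).sum()),
        "ShortRunEmphasis": float((P / r**2).sum() / total),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / r**2).sum() / total),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * r**2)).sum() / total),
    }


def glrlm_features(d: DiscretizedRoi) -> dict[str, float]:
    mats = glrlm_matrices(d.levels, d.n_levels)
    n_vox = d.n_voxels
    per_dir = [_rlm_features_single(m, n_vox) for m in mats if m.sum() > 0]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def glszm_features(d: DiscretizedRoi) -> dict[str, float]:
    counts = glszm_matrix(d.levels, d.n_levels)
    Ng, Ns = counts.shape
    total = counts.sum()
    n_vox = d.n_voxels
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    s = np.arange(1, Ns + 1, dtype=float)[None, :]
    P = counts.astype(float)
    p = P / total
    zi = P.sum(axis=1)
    zs = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    return {
        "GrayLevelNonUniformity": float((zi**2).sum() / total),
        "GrayLevelNonUniformityNormalized": float((zi**2).sum() / total**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / total),
        "LargeAreaEmphasis": float((P * s**2).sum() / total),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / total),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / total),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / total),
        "SizeZoneNonUniformity": float((zs**2).sum() / total),
        "SizeZoneNonUniformityNormalized": float((zs**2).sum() / total**2),
        "SmallAreaEmphasis": float((P / s**2).sum() / total),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / total),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / total),
        "ZoneEntropy": _entropy2(p.ravel()),
        "ZonePercentage": float(total / n_vox),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
    }


def gldm_features(d: DiscretizedRoi) -> dict[str, float]:
    counts = gldm_matrix(d.levels, d.n_levels)
    Ng, Nd = counts.shape
    total = counts.sum()
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    j = np.arange(1, Nd + 1, dtype=float)[None, :]
    P = counts.astype(float)
    p = P / total
    gi = P.sum(axis=1)
    dj = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "DependenceEntropy": _entropy2(p.ravel()),
        "DependenceNonUniformity": float((dj**2).sum() / total),
        "DependenceNonUniformityNormalized": float((dj**2).sum() / total**2),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((gi**2).sum() / total),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / total),
        "LargeDependenceEmphasis": float((P * j**2).sum() / total),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / total),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / total),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / total),
        "SmallDependenceEmphasis": float((P / j**2).sum() / total),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / total),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / total),
    }


def ngtdm_features(d: DiscretizedRoi) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(d.levels, d.n_levels)
    Np = n_i.sum()
    present = p_i > 0
    Ngp = int(present.sum())
    i = np.arange(1, d.n_levels + 1, dtype=float)

    denom_coarse = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_MAX
    coarseness = min(coarseness, COARSENESS_MAX)

    if Ngp > 1 and Np > 0:
        pi_, pj_ = p_i[present][:, None], p_i[present][None, :]
        ii, jj = i[present][:, None], i[present][None, :]
        contrast = float(
            (pi_ * pj_ * (ii - jj) ** 2).sum()
            / (Ngp * (Ngp - 1))
            * (s_i.sum() / Np)
        )
        denom_busy = float(np.abs(ii * pi_ - jj * pj_).sum())
        busyness = denom_coarse / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            (np.abs(ii - jj) * (pi_ * s_i[present][:, None] + pj_ * s_i[present][None, :])
             / (pi_ + pj_)).sum() / Np
        )
        s_total = float(s_i.sum())
        strength = (
            float(((pi_ + pj_) * (ii - jj) ** 2).sum()) / s_total if s_total > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
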