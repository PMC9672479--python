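"""Intensity and texture feature definitions.

The bank follows the IBSI-style definitions used throughout the
radiomics literature: 18 first-order statistics plus five gray-level
matrix families — co-occurrence (GLCM, 24), run length (GLRLM, 16),
size zone (GLSZM, 16), neighboring gray tone difference (NGTDM, 5) and
dependence (GLDM, 14).  Gray levels are discretized with a fixed bin
width starting at the ROI minimum; matrix families pool counts over the
13 unique 3D directions (GLCM symmetrized), and all computations are
fully deterministic.

Each family function takes a discretized label volume ``lab`` (int,
level 0 outside the ROI, levels 1..Ng inside) and returns an ordered
``{base_name: value}`` dict.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "discretize", "first_order_features", "glcm_features", "glrlm_features",
    "glszm_features", "ngtdm_features", "gldm_features",
    "FAMILY_SIZES", "DIRECTIONS_13",
]

_EPS = np.finfo(float).eps

FAMILY_SIZES = {
    "shape": 14, "firstorder": 18, "glcm": 24, "glrlm": 16,
    "glszm": 16, "ngtdm": 5, "gldm": 14,
}

#: The 13 unique direction vectors of a 26-connected 3D neighborhood
#: (one per +/- pair), ordered (dz, dy, dx).
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
)


def discretize(image: np.ndarray, mask: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization to integer levels 1..Ng (0 outside)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lab = np.zeros(image.shape, dtype=np.int32)
    lab[mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int32) + 1
    return lab


# --------------------------------------------------------------------------
# first order

def first_order_features(
    image: np.ndarray, mask: np.ndarray, bin_width: float, voxel_volume: float
) -> dict[str, float]:
    x = image[mask].astype(float)
    n = x.size
    lab = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(lab) / n
    p = p[p > 0]
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    skew = 0.0 if sd == 0 else float(np.mean((x - mean) ** 3) / sd**3)
    kurt = 0.0 if sd == 0 else float(np.mean((x - mean) ** 4) / var**2)
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,  # non-excess (Pearson) kurtosis
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


# --------------------------------------------------------------------------
# helpers

def _shift(lab: np.ndarray, d: tuple[int, int, int], fill: int = 0) -> np.ndarray:
    """Return array whose value at v is lab[v - d] (``fill`` outside)."""
    out = np.full_like(lab, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, delta in enumerate(d):
        if delta > 0:
            dst[ax], src[ax] = slice(delta, None), slice(None, -delta)
        elif delta < 0:
            dst[ax], src[ax] = slice(None, delta), slice(-delta, None)
    out[tuple(dst)] = lab[tuple(src)]
    return out


def _neighbor_pairs(lab: np.ndarray, d: tuple[int, int, int]):
    """Gray-level pairs (a, b) for all in-ROI voxel pairs at offset d."""
    shifted = _shift(lab, d)
    both = (lab > 0) & (shifted > 0)
    return lab[both], shifted[both]


# --------------------------------------------------------------------------
# GLCM

def glcm_features(lab: np.ndarray, Ng: int) -> dict[str, float]:
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _neighbor_pairs(lab, d)
        np.add.at(counts, (a - 1, b - 1), 1)
    counts = counts + counts.T  # symmetric co-occurrence
    total = counts.sum()
    if total == 0:
        raise ValueError("GLCM: no voxel pairs in ROI")
    P = counts / total
    i = np.arange(1, Ng + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = np.sqrt(np.sum((i - ux) ** 2 * px))
    sy = np.sqrt(np.sum((i - uy) ** 2 * py))

    ks = np.arange(2, 2 * Ng + 1, dtype=float)
    pxy_sum = np.zeros(ks.size)
    np.add.at(pxy_sum, (I + J).astype(int).ravel() - 2, P.ravel())
    kd = np.arange(0, Ng, dtype=float)
    pxy_diff = np.zeros(kd.size)
    np.add.at(pxy_diff, np.abs(I - J).astype(int).ravel(), P.ravel())

    HX = -np.sum(px[px > 0] * np.log2(px[px > 0]))
    HY = -np.sum(py[py > 0] * np.log2(py[py > 0]))
    HXY = -np.sum(P[P > 0] * np.log2(P[P > 0]))
    pxpy = np.outer(px, py)
    nz = (pxpy > 0)
    HXY1 = -np.sum(P[nz] * np.log2(pxpy[nz] + _EPS))
    HXY2 = -np.sum(pxpy[nz] * np.log2(pxpy[nz] + _EPS))

    imc1 = 0.0 if max(HX, HY) == 0 else (HXY - HXY1) / max(HX, HY)
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (HXY2 - HXY))))

    # MCC: second largest eigenvalue of Q
    if Ng > 1:
        valid = px > 0
        Pv = P[np.ix_(valid, valid)]
        pxv = px[valid]
        pyv = py[valid]
        Q = (Pv / pxv[:, None]) @ (Pv / pyv[:, None]).T
        eig = np.sort(np.linalg.eigvals(Q).real)
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if eig.size > 1 else 1.0
    else:
        mcc = 1.0

    da = float(np.sum(kd * pxy_diff))
    corr = 1.0 if sx * sy == 0 else float(
        (np.sum(I * J * P) - ux * uy) / (sx * sy)
    )
    return {
        "Autocorrelation": float(np.sum(I * J * P)),
        "ClusterProminence": float(np.sum((I + J - ux - uy) ** 4 * P)),
        "ClusterShade": float(np.sum((I + J - ux - uy) ** 3 * P)),
        "ClusterTendency": float(np.sum((I + J - ux - uy) ** 2 * P)),
        "Contrast": float(np.sum((I - J) ** 2 * P)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -np.sum(pxy_diff[pxy_diff > 0] * np.log2(pxy_diff[pxy_diff > 0]))
        ),
        "DifferenceVariance": float(np.sum((kd - da) ** 2 * pxy_diff)),
        "Id": float(np.sum(P / (1 + np.abs(I - J)))),
        "Idm": float(np.sum(P / (1 + (I - J) ** 2))),
        "Idmn": float(np.sum(P / (1 + ((I - J) / Ng) ** 2))),
        "Idn": float(np.sum(P / (1 + np.abs(I - J) / Ng))),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "InverseVariance": float(np.sum(P[I != J] / (I - J)[I != J] ** 2)),
        "JointAverage": ux,
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": float(HXY),
        "MaximumProbability": float(P.max()),
        "MCC": mcc,
        "SumAverage": float(np.sum(ks * pxy_sum)),
        "SumEntropy": float(
            -np.sum(pxy_sum[pxy_sum > 0] * np.log2(pxy_sum[pxy_sum > 0]))
        ),
        "SumSquares": float(np.sum((I - ux) ** 2 * P)),
    }


# --------------------------------------------------------------------------
# GLRLM

def _runs_one_direction(lab: np.ndarray, d: tuple[int, int, int]):
    """(gray level, run length) of every maximal run along direction d."""
    Z, H, W = lab.shape
    pred = _shift(lab, d, fill=-1)
    starts = (lab > 0) & (pred != lab)
    coords = np.argwhere(starts)
    vals = lab[starts]
    n = vals.size
    lengths = np.ones(n, dtype=np.int64)
    pos = coords.copy()
    idx = np.arange(n)
    dvec = np.array(d)
    while idx.size:
        pos = pos + dvec
        inb = (
            (pos[:, 0] >= 0) & (pos[:, 0] < Z)
            & (pos[:, 1] >= 0) & (pos[:, 1] < H)
            & (pos[:, 2] >= 0) & (pos[:, 2] < W)
        )
        pos, idx = pos[inb], idx[inb]
        if not idx.size:
            break
        same = lab[pos[:, 0], pos[:, 1], pos[:, 2]] == vals[idx]
        idx = idx[same]
        pos = pos[same]
        lengths[idx] += 1
    return vals, lengths


def glrlm_features(lab: np.ndarray, Ng: int) -> dict[str, float]:
    Np = int((lab > 0).sum())
    max_len = max(lab.shape)
    P = np.zeros((Ng, max_len), dtype=np.int64)
    for d in DIRECTIONS_13:
        vals, lengths = _runs_one_direction(lab, d)
        np.add.at(P, (vals - 1, lengths - 1), 1)
    P = P[:, : max(1, int(np.max(np.nonzero(P.any(axis=0))[0])) + 1) if P.any() else 1]
    Nr = P.sum()
    if Nr == 0:
        raise ValueError("GLRLM: empty run-length matrix")
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    p = P / Nr
    pg = p.sum(axis=1)  # per gray level
    pr = p.sum(axis=0)  # per run length
    mu_i = float(np.sum(i * pg))
    mu_j = float(np.sum(j * pr))
    return {
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / Nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * pg)),
        "HighGrayLevelRunEmphasis": float(np.sum(i**2 * pg)),
        "LongRunEmphasis": float(np.sum(j**2 * pr)),
        "LongRunHighGrayLevelEmphasis": float(np.sum(p * np.outer(i**2, j**2))),
        "LongRunLowGrayLevelEmphasis": float(np.sum(p * np.outer(1 / i**2, j**2))),
        "LowGrayLevelRunEmphasis": float(np.sum(pg / i**2)),
        "RunEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "RunLengthNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / Nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pr**2)),
        "RunPercentage": float(Nr / (Np * len(DIRECTIONS_13))),
        "RunVariance": float(np.sum((j - mu_j) ** 2 * pr)),
        "ShortRunEmphasis": float(np.sum(pr / j**2)),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(p * np.outer(i**2, 1 / j**2))),
        "ShortRunLowGrayLevelEmphasis": float(
            np.sum(p * np.outer(1 / i**2, 1 / j**2))
        ),
    }


# --------------------------------------------------------------------------
# GLSZM

def glszm_features(lab: np.ndarray, Ng: int) -> dict[str, float]:
    Np = int((lab > 0).sum())
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connected zones
    zone_counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for level in range(1, Ng + 1):
        binary = lab == level
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zone_counts[(level, int(s))] = zone_counts.get((level, int(s)), 0) + 1
            max_size = max(max_size, int(s))
    P = np.zeros((Ng, max_size), dtype=np.int64)
    for (level, size), c in zone_counts.items():
        P[level - 1, size - 1] = c
    Nz = P.sum()
    if Nz == 0:
        raise ValueError("GLSZM: no zones in ROI")
    i = np.arange(1, Ng + 1, dtype=float)
    j = np.arange(1, max_size + 1, dtype=float)
    p = P / Nz
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float(np.sum(i * pg))
    mu_j = float(np.sum(j * ps))
    return {
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / Nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * pg)),
        "HighGrayLevelZoneEmphasis": float(np.sum(i**2 * pg)),
        "LargeAreaEmphasis": float(np.sum(j**2 * ps)),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(p * np.outer(i**2, j**2))),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(p * np.outer(1 / i**2, j**2))),
        "LowGrayLevelZoneEmphasis": float(np.sum(pg / i**2)),
        "SizeZoneNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / Nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2)),
        "SmallAreaEmphasis": float(np.sum(ps / j**2)),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(p * np.outer(i**2, 1 / j**2))),
        "SmallAreaLowGrayLevelEmphasis": float(
            np.sum(p * np.outer(1 / i**2, 1 / j**2))
        ),
        "ZoneEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "ZonePercentage": float(Nz / Np),
        "ZoneVariance": float(np.sum((j - mu_j) ** 2 * ps)),
    }


# --------------------------------------------------------------------------
# NGTDM

def ngtdm_features(lab: np.ndarray, Ng: int) -> dict[str, float]:
    mask = lab > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nbr_sum = ndimage.convolve(lab.astype(float), kernel, mode="constant")
    nbr_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    valid = mask & (nbr_cnt > 0)
    levels = lab[valid].astype(float)
    abar = nbr_sum[valid] / nbr_cnt[valid]
    N = levels.size
    if N == 0:
        raise ValueError("NGTDM: no voxels with in-ROI neighbors")
    s = np.zeros(Ng)
    n = np.zeros(Ng)
    np.add.at(s, levels.astype(int) - 1, np.abs(levels - abar))
    np.add.at(n, levels.astype(int) - 1, 1)
    p = n / N
    present = p > 0
    ivals = np.arange(1, Ng + 1, dtype=float)
    Ngp = int(present.sum())
    ip, pp, sp = ivals[present], p[present], s[present]

    coarse_den = float(np.sum(pp * sp))
    coarseness = 1e6 if coarse_den == 0 else 1.0 / coarse_den
    if Ngp > 1:
        ii, jj = np.meshgrid(ip, ip, indexing="ij")
        pi, pj = np.meshgrid(pp, pp, indexing="ij")
        si, sj = np.meshgrid(sp, sp, indexing="ij")
        contrast = (
            np.sum(pi * pj * (ii - jj) ** 2) / (Ngp * (Ngp - 1))
        ) * (np.sum(sp) / N)
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = 0.0 if busy_den == 0 else coarse_den / busy_den
        complexity = float(
            np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)) / N
        )
        strength = 0.0 if np.sum(sp) == 0 else float(
            np.sum((pi + pj) * (ii - jj) ** 2) / np.sum(sp)
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }


# --------------------------------------------------------------------------
# GLDM

_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def gldm_features(lab: np.ndarray, Ng: int, alpha: int = 0) -> dict[str, float]:
    mask = lab > 0
    dep = np.zeros(lab.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        shifted = _shift(lab, d)
        dep += (mask & (shifted > 0) & (np.abs(shifted - lab) <= alpha)).astype(
            np.int64
        )
    dvals = dep[mask] + 1  # the center voxel always depends on itself
    levels = lab[mask]
    Nd = int(dvals.max())
    P = np.zeros((Ng, Nd), dtype=np.int64)
    np.add.at(P, (levels - 1, dvals - 1), 1)
    Nz = P.sum()
    i = np.arange(1, Ng + 1, dtype=float)
    j = np.arange(1, Nd + 1, dtype=float)
    p = P / Nz
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float(np.sum(i * pg))
    mu_j = float(np.sum(j * pd))
    return {
        "DependenceEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "DependenceNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / Nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2)),
        "DependenceVariance": float(np.sum((j - mu_j) ** 2 * pd)),
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / Nz),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * pg)),
        "HighGrayLevelEmphasis": float(np.sum(i**2 * pg)),
        "LargeDependenceEmphasis": float(np.sum(j**2 * pd)),
        "LargeDependenceHighGrayLevelEmphasis": float(
            np.sum(p * np.outer(i**2, j**2))
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            np.sum(p * np.outer(1 / i**2, j**2))
        ),
        "LowGrayLevelEmphasis": float(np.sum(pg / i**2)),
        "SmallDependenceEmphasis": float(np.sum(pd / j**2)),
        "SmallDependenceHighGrayLevelEmphasis": float(
            np.sum(p * np.outer(i**2, 1 / j**2))
        ),
        "SmallDependenceLowGrayLevelEmphasis": float(
            np.sum(p * np.outer(1 / i**2, 1 / j**2))
        ),
    }
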