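"""Radiomics feature extraction on 2D flow parameter maps.

Normalized parameter maps are discretized with a fixed bin width of 25
(anchored at the ROI minimum) and summarized by six feature families:
first-order statistics and the GLCM, GLRLM, GLSZM, GLDM and NGTDM texture
matrices, all computed in 2D with distance-1 / 8-connected neighborhoods
following the IBSI definitions. Together with 16 shape-and-motion contour
descriptors, the default catalogue yields 79 features per parameter map and
411 features per plane per timeframe (5 x 79 + 16).

The full six-family set has 93 members (18 + 24 + 16 + 16 + 14 + 5); the
default catalogue excludes 14 redundant or derived variants (e.g. the
normalized duplicates of the non-uniformity features, GLCM sum-statistics
that are linear functions of retained features) to arrive at the 79-feature
per-map signature. The catalogue is configurable; the 79/16/411 counts are
enforced for the shipped default.

Texture matrix conventions:

* GLCM: distance 1, the four unique 2D directions, symmetrized; features
  computed per direction, then averaged.
* GLRLM: run-length matrices of the four directions are summed before
  feature computation.
* GLSZM: zones are 8-connected components of constant gray level.
* GLDM: dependence = number of 8-neighbors equal to the center (tolerance
  alpha = 0); the matrix is indexed by (gray level, dependence + 1).
* NGTDM: difference of each pixel from the mean of its valid 8-neighbors.

Degenerate denominators follow the IBSI conventions (documented constants),
never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .maps import ParameterMap

__all__ = [
    "DiscretizedMap",
    "FeatureCatalogue",
    "FeatureVector",
    "DEFAULT_BIN_WIDTH",
    "FAMILY_FEATURES",
    "DEFAULT_EXCLUSIONS",
    "SHAPE_FEATURES",
    "discretize",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "shape2d_features",
    "extract_signature",
]

DEFAULT_BIN_WIDTH = 25.0

#: Value returned for NGTDM Coarseness when its denominator is zero.
COARSENESS_MAX = 1e6

_EPS = np.spacing(1.0)

_DIRECTIONS_2D = ((0, 1), (1, 0), (1, 1), (1, -1))
_STRUCT8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedMap:
    """Integer gray levels (1-based) on the ROI; 0 outside the mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float


def discretize(pmap: ParameterMap, bin_width: float = DEFAULT_BIN_WIDTH,
               mask: np.ndarray | None = None) -> DiscretizedMap:
    """Fixed-bin-width gray-level discretization anchored at the ROI minimum.

    ``level = floor((value - min_ROI) / bin_width) + 1``.
    """
    if mask is None:
        mask = pmap.mask
    if mask is None or not np.any(mask):
        raise ValueError("discretize requires a non-empty ROI mask")
    vals = pmap.values
    mn = vals[mask].min()
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[mask] = np.floor((vals[mask] - mn) / bin_width).astype(np.int64) + 1
    return DiscretizedMap(levels=levels, mask=np.asarray(mask, dtype=bool),
                          n_levels=int(levels[mask].max()),
                          bin_width=bin_width)


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def first_order_features(values: np.ndarray, levels: np.ndarray,
                         pixel_area: float = 1.0) -> dict[str, float]:
    """First-order statistics of the ROI intensities.

    ``values`` are the (normalized) map values inside the ROI; ``levels``
    the corresponding discretized gray levels, used for Entropy and
    Uniformity. Skewness and kurtosis use population moments and are 0 by
    convention for constant input; kurtosis is not excess-corrected.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    mean = v.mean()
    m2 = ((v - mean) ** 2).mean()
    m3 = ((v - mean) ** 3).mean()
    m4 = ((v - mean) ** 4).mean()
    p10, p90 = np.percentile(v, [10, 90])
    robust = v[(v >= p10) & (v <= p90)]
    rmad = np.abs(robust - robust.mean()).mean() if robust.size else 0.0
    _, counts = np.unique(np.asarray(levels).ravel(), return_counts=True)
    p = counts / counts.sum()
    return {
        "Energy": float((v**2).sum()),
        "TotalEnergy": float(pixel_area * (v**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(v.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(np.median(v)),
        "InterquartileRange": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(d: DiscretizedMap, direction: tuple[int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one distance-1 direction."""
    lv, mask = d.levels, d.mask
    ng = d.n_levels
    dy, dx = direction
    h, w = lv.shape
    ys = slice(max(0, dy), h + min(0, dy))
    xs = slice(max(0, dx), w + min(0, dx))
    ys0 = slice(max(0, -dy), h - max(0, dy))
    xs0 = slice(max(0, -dx), w - max(0, dx))
    a = lv[ys0, xs0]
    b = lv[ys, xs]
    ok = mask[ys0, xs0] & mask[ys, xs]
    P = np.zeros((ng, ng))
    np.add.at(P, (a[ok] - 1, b[ok] - 1), 1.0)
    return P + P.T


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    tot = P.sum()
    if tot == 0:
        raise ValueError("GLCM has no co-occurring pixel pairs (ROI too small)")
    p = P / tot
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = (px * i).sum()
    muy = (py * i).sum()
    sigx = np.sqrt((px * (i - mux) ** 2).sum())
    sigy = np.sqrt((py * (i - muy) ** 2).sum())

    k_diff = np.arange(0, ng)           # |i-j|
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)    # i+j
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J).ravel() - 2, p.ravel())

    diff_avg = (k_diff * p_diff).sum()
    nz = p > 0
    joint_entropy = -(p[nz] * np.log2(p[nz])).sum()
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log2(py[py > 0])).sum()
    pxy = np.outer(px, py)
    m = nz & (pxy > 0)
    hxy1 = -(p[m] * np.log2(pxy[m])).sum()
    hxy2 = -(pxy[pxy > 0] * np.log2(pxy[pxy > 0])).sum()

    if sigx > 0 and sigy > 0:
        correlation = ((p * I * J).sum() - mux * muy) / (sigx * sigy)
    else:
        correlation = 1.0

    offdiag = I != J
    inv_var = (p[offdiag] / (I[offdiag] - J[offdiag]) ** 2).sum()

    # MCC: second largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px_i py_k)
    keep = px > 0
    if keep.sum() > 1:
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        pys = py[keep]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px_i py_k)
        Q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0))) if eig.size > 1 else 1.0
    else:
        mcc = 1.0

    imc_den = max(hx, hy)
    imc1 = (joint_entropy - hxy1) / imc_den if imc_den > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    return {
        "Autocorrelation": float((p * I * J).sum()),
        "JointAverage": float(mux),
        "ClusterProminence": float((p * (I + J - mux - muy) ** 4).sum()),
        "ClusterShade": float((p * (I + J - mux - muy) ** 3).sum()),
        "ClusterTendency": float((p * (I + J - mux - muy) ** 2).sum()),
        "Contrast": float((p * (I - J) ** 2).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": float(diff_avg),
        "DifferenceEntropy": float(
            -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
        ),
        "DifferenceVariance": float((p_diff * (k_diff - diff_avg) ** 2).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(inv_var),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": float(joint_entropy),
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(
            -(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()
        ),
        "SumSquares": float((p * (I - mux) ** 2).sum()),
    }


def glcm_features(d: DiscretizedMap) -> dict[str, float]:
    """Distance-1 GLCM features, averaged over the four 2D directions."""
    if d.mask.sum() < 2:
        raise ValueError("GLCM requires at least 2 ROI pixels")
    per_dir = []
    for direction in _DIRECTIONS_2D:
        P = _glcm_matrix(d, direction)
        if P.sum() > 0:
            per_dir.append(_glcm_features_single(P))
    if not per_dir:
        raise ValueError("no co-occurring ROI pixel pairs in any direction")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _lines(shape: tuple[int, int], direction: tuple[int, int]):
    """Index lists of all maximal lattice lines along one direction."""
    h, w = shape
    dy, dx = direction
    if (dy, dx) == (0, 1):
        for y in range(h):
            yield [(y, x) for x in range(w)]
    elif (dy, dx) == (1, 0):
        for x in range(w):
            yield [(y, x) for y in range(h)]
    elif (dy, dx) == (1, 1):
        for s in range(-(h - 1), w):
            line = [(y, y + s) for y in range(h) if 0 <= y + s < w]
            if line:
                yield line
    else:  # (1, -1)
        for s in range(h + w - 1):
            line = [(y, s - y) for y in range(h) if 0 <= s - y < w]
            if line:
                yield line


def _glrlm_matrix(d: DiscretizedMap) -> np.ndarray:
    """Run-length counts summed over the four 2D directions."""
    lv, mask = d.levels, d.mask
    ng = d.n_levels
    max_run = max(lv.shape)
    R = np.zeros((ng, max_run))
    for direction in _DIRECTIONS_2D:
        for line in _lines(lv.shape, direction):
            run_level, run_len = None, 0
            for (y, x) in line + [(-1, -1)]:
                inside = y >= 0 and mask[y, x]
                lvl = lv[y, x] if inside else None
                if lvl == run_level and lvl is not None:
                    run_len += 1
                else:
                    if run_level is not None:
                        R[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lvl, 1 if inside else 0
    return R


def _level_length_features(M: np.ndarray, n_pixels: int,
                           names: dict[str, str]) -> dict[str, float]:
    """Shared feature formulas for level x size matrices (GLRLM/GLSZM)."""
    N = M.sum()
    if N == 0:
        raise ValueError("empty texture matrix")
    ng, nl = M.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nl + 1)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = M / N
    mu_i = (p * I).sum()
    mu_j = (p * J).sum()
    nz = p > 0
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    return {
        names["SE"]: float((M / J**2).sum() / N),
        names["LE"]: float((M * J**2).sum() / N),
        names["GLN"]: float((row**2).sum() / N),
        names["GLNN"]: float((row**2).sum() / N**2),
        names["SN"]: float((col**2).sum() / N),
        names["SNN"]: float((col**2).sum() / N**2),
        names["PCT"]: float(N / n_pixels),
        names["GLV"]: float((p * (I - mu_i) ** 2).sum()),
        names["SV"]: float((p * (J - mu_j) ** 2).sum()),
        names["ENT"]: float(-(p[nz] * np.log2(p[nz])).sum()),
        names["LGL"]: float((M / I**2).sum() / N),
        names["HGL"]: float((M * I**2).sum() / N),
        names["SLGL"]: float((M / (I**2 * J**2)).sum() / N),
        names["SHGL"]: float((M * I**2 / J**2).sum() / N),
        names["LLGL"]: float((M * J**2 / I**2).sum() / N),
        names["LHGL"]: float((M * I**2 * J**2).sum() / N),
    }


_GLRLM_NAMES = {
    "SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "RunLengthNonUniformity", "SNN": "RunLengthNonUniformityNormalized",
    "PCT": "RunPercentage", "GLV": "GrayLevelVariance", "SV": "RunVariance",
    "ENT": "RunEntropy", "LGL": "LowGrayLevelRunEmphasis",
    "HGL": "HighGrayLevelRunEmphasis",
    "SLGL": "ShortRunLowGrayLevelEmphasis",
    "SHGL": "ShortRunHighGrayLevelEmphasis",
    "LLGL": "LongRunLowGrayLevelEmphasis",
    "LHGL": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "SizeZoneNonUniformity", "SNN": "SizeZoneNonUniformityNormalized",
    "PCT": "ZonePercentage", "GLV": "GrayLevelVariance", "SV": "ZoneVariance",
    "ENT": "ZoneEntropy", "LGL": "LowGrayLevelZoneEmphasis",
    "HGL": "HighGrayLevelZoneEmphasis",
    "SLGL": "SmallAreaLowGrayLevelEmphasis",
    "SHGL": "SmallAreaHighGrayLevelEmphasis",
    "LLGL": "LargeAreaLowGrayLevelEmphasis",
    "LHGL": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(d: DiscretizedMap) -> dict[str, float]:
    """Run-length features; the matrices of the four directions are summed.

    RunPercentage uses the pooled denominator ``4 * N_pixels`` (one
    potential run per pixel per direction) so it stays in (0, 1].
    """
    n_pixels = int(d.mask.sum())
    R = _glrlm_matrix(d)
    feats = _level_length_features(R, 4 * n_pixels, _GLRLM_NAMES)
    return feats


def glszm_features(d: DiscretizedMap) -> dict[str, float]:
    """Size-zone features; zones are 8-connected equal-level components."""
    lv, mask = d.levels, d.mask
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI")
    max_zone = n_pixels
    Z = np.zeros((d.n_levels, max_zone))
    for lvl in np.unique(lv[mask]):
        lab, n = ndimage.label((lv == lvl) & mask, structure=_STRUCT8)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        for s in sizes.astype(int):
            Z[lvl - 1, s - 1] += 1
    return _level_length_features(Z, n_pixels, _GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def _neighbor_stacks(lv: np.ndarray, mask: np.ndarray):
    """For each pixel: per-8-neighbor (level, validity) stacks."""
    h, w = lv.shape
    vals = []
    oks = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            v = np.zeros_like(lv)
            ok = np.zeros_like(mask)
            ys = slice(max(0, dy), h + min(0, dy))
            xs = slice(max(0, dx), w + min(0, dx))
            ys0 = slice(max(0, -dy), h - max(0, dy))
            xs0 = slice(max(0, -dx), w - max(0, dx))
            v[ys0, xs0] = lv[ys, xs]
            ok[ys0, xs0] = mask[ys, xs]
            vals.append(v)
            oks.append(ok)
    return np.stack(vals), np.stack(oks)


def gldm_features(d: DiscretizedMap, alpha: int = 0) -> dict[str, float]:
    """Gray-level dependence features (8-neighborhood, tolerance alpha)."""
    lv, mask = d.levels, d.mask
    if not mask.any():
        raise ValueError("empty ROI")
    nbv, nbok = _neighbor_stacks(lv, mask)
    dep = ((np.abs(nbv - lv[None]) <= alpha) & nbok).sum(axis=0)
    levels_roi = lv[mask]
    dep_roi = dep[mask]
    D = np.zeros((d.n_levels, 9))   # dependence 0..8 -> column index dep
    np.add.at(D, (levels_roi - 1, dep_roi), 1.0)
    # matrix indexed by (level, dependence + 1): size index j = dep + 1
    N = D.sum()
    ng = d.n_levels
    i = np.arange(1, ng + 1)
    j = np.arange(1, 10)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = D / N
    mu_i = (p * I).sum()
    mu_j = (p * J).sum()
    nz = p > 0
    row = D.sum(axis=1)
    col = D.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float((D / J**2).sum() / N),
        "LargeDependenceEmphasis": float((D * J**2).sum() / N),
        "GrayLevelNonUniformity": float((row**2).sum() / N),
        "DependenceNonUniformity": float((col**2).sum() / N),
        "DependenceNonUniformityNormalized": float((col**2).sum() / N**2),
        "GrayLevelVariance": float((p * (I - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (J - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((D / I**2).sum() / N),
        "HighGrayLevelEmphasis": float((D * I**2).sum() / N),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (D / (I**2 * J**2)).sum() / N
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (D * I**2 / J**2).sum() / N
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (D * J**2 / I**2).sum() / N
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (D * I**2 * J**2).sum() / N
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(d: DiscretizedMap) -> dict[str, float]:
    """Neighboring gray-tone difference features (8-neighborhood)."""
    lv, mask = d.levels, d.mask
    if not mask.any():
        raise ValueError("empty ROI")
    nbv, nbok = _neighbor_stacks(lv, mask)
    cnt = nbok.sum(axis=0)
    tot = (nbv * nbok).sum(axis=0)
    has_nb = mask & (cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.abs(lv - tot / np.where(cnt > 0, cnt, 1))
    ng = d.n_levels
    s = np.zeros(ng)
    n = np.zeros(ng)
    np.add.at(s, lv[has_nb] - 1, diff[has_nb])
    np.add.at(n, lv[has_nb] - 1, 1.0)
    Nvp = n.sum()
    p = n / Nvp
    i = np.arange(1, ng + 1)
    present = p > 0
    ngp = int(present.sum())

    denom_coarse = (p * s).sum()
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_MAX

    if ngp > 1:
        Pi, Pj = np.meshgrid(p[present], p[present], indexing="ij")
        Ii, Ij = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = (
            (Pi * Pj * (Ii - Ij) ** 2).sum() / (ngp * (ngp - 1))
        ) * (s.sum() / Nvp)
        busy_den = np.abs(Ii * Pi - Ij * Pj).sum()
        busyness = (p * s).sum() / busy_den if busy_den > 0 else 0.0
        Si = np.meshgrid(s[present], s[present], indexing="ij")
        complexity = (
            np.abs(Ii - Ij) * (Pi * Si[0] + Pj * Si[1]) / (Pi + Pj)
        ).sum() / Nvp
        s_sum = s.sum()
        strength = (
            ((Pi + Pj) * (Ii - Ij) ** 2).sum() / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# 2D shape
# ---------------------------------------------------------------------------

SHAPE_FEATURES = (
    "PixelArea",
    "MeshArea",
    "Perimeter",
    "PerimeterToAreaRatio",
    "MaximumDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Elongation",
    "Eccentricity",
    "Circularity",
    "Compactness",
    "Extent",
    "Solidity",
    "EquivalentDiameter",
    "CentroidDrift",
    "AreaFractionChange",
)


def _contours(mask: np.ndarray):
    padded = np.pad(mask.astype(float), 1)
    return [c - 1.0 for c in measure.find_contours(padded, 0.5)]


def _shoelace(contour: np.ndarray) -> float:
    x, y = contour[:, 1], contour[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def shape2d_features(mask: np.ndarray, pixel_size_mm: float = 1.0,
                     reference_mask: np.ndarray | None = None) -> dict[str, float]:
    """16 contour shape-and-motion descriptors of a 2D ROI.

    Lengths are mm, areas mm^2. ``CentroidDrift`` and ``AreaFractionChange``
    compare against the reference-timeframe mask (0 when the mask is its
    own reference).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if reference_mask is None:
        reference_mask = mask
    s = float(pixel_size_mm)

    n = int(mask.sum())
    pixel_area = n * s * s
    contours = _contours(mask)
    mesh_area = abs(sum(_shoelace(c) for c in contours)) * s * s
    # Crofton (intercept-count) perimeter: unbiased for smooth contours,
    # unlike the staircase length of the marching-squares polyline
    perimeter = float(measure.perimeter_crofton(mask, directions=4)) * s

    # max pairwise distance over the corner points of boundary pixels
    eroded = ndimage.binary_erosion(mask)
    byy, bxx = np.nonzero(mask & ~eroded)
    corners = np.concatenate([
        np.stack([byy + oy, bxx + ox], axis=1)
        for oy in (-0.5, 0.5) for ox in (-0.5, 0.5)
    ]) * s
    from scipy.spatial.distance import pdist

    max_diam = float(pdist(corners).max()) if len(corners) > 1 else float(s)

    yy, xx = np.nonzero(mask)
    coords = np.stack([yy, xx], axis=1) * s
    centroid = coords.mean(axis=0)
    if n > 1:
        cov = np.cov(coords.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.maximum(eig, 0.0)
    else:
        eig = np.zeros(2)
    major = 4.0 * np.sqrt(eig[0])
    minor = 4.0 * np.sqrt(eig[1])
    elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    ecc = float(np.sqrt(1.0 - eig[1] / eig[0])) if eig[0] > 0 else 0.0

    bbox_area = (np.ptp(yy) + 1) * (np.ptp(xx) + 1) * s * s
    hull = morphology.convex_hull_image(mask)
    solidity = n / int(hull.sum())

    circ = 2.0 * np.sqrt(np.pi * mesh_area) / perimeter if perimeter > 0 else 0.0
    comp = 4.0 * np.pi * mesh_area / perimeter**2 if perimeter > 0 else 0.0

    ref_yy, ref_xx = np.nonzero(reference_mask)
    ref_centroid = np.stack([ref_yy, ref_xx], axis=1).mean(axis=0) * s
    ref_area = int(np.asarray(reference_mask, dtype=bool).sum()) * s * s

    return {
        "PixelArea": float(pixel_area),
        "MeshArea": float(mesh_area),
        "Perimeter": float(perimeter),
        "PerimeterToAreaRatio": float(perimeter / mesh_area) if mesh_area else 0.0,
        "MaximumDiameter": max_diam,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": elong,
        "Eccentricity": ecc,
        "Circularity": float(circ),
        "Compactness": float(comp),
        "Extent": float(pixel_area / bbox_area),
        "Solidity": float(solidity),
        "EquivalentDiameter": float(2.0 * np.sqrt(pixel_area / np.pi)),
        "CentroidDrift": float(np.linalg.norm(centroid - ref_centroid)),
        "AreaFractionChange": float((pixel_area - ref_area) / ref_area),
    }


# ---------------------------------------------------------------------------
# catalogue and signature
# ---------------------------------------------------------------------------

_FAMILY_FUNCS = {
    "firstorder": None,   # handled separately (needs raw values)
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
        "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    ),
    "glcm": (
        "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
        "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy",
        "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
    ),
    "glrlm": tuple(_GLRLM_NAMES[k] for k in (
        "SE", "LE", "GLN", "GLNN", "SN", "SNN", "PCT", "GLV", "SV", "ENT",
        "LGL", "HGL", "SLGL", "SHGL", "LLGL", "LHGL",
    )),
    "glszm": tuple(_GLSZM_NAMES[k] for k in (
        "SE", "LE", "GLN", "GLNN", "SN", "SNN", "PCT", "GLV", "SV", "ENT",
        "LGL", "HGL", "SLGL", "SHGL", "LLGL", "LHGL",
    )),
    "gldm": (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelNonUniformity", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "GrayLevelVariance",
        "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    ),
    "ngtdm": ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"),
}

#: Redundant or derived variants excluded from the default 79-feature
#: per-map catalogue (14 in total): normalized duplicates of non-uniformity
#: features, GLCM sum statistics expressible through retained features, the
#: information-correlation and eigenvalue variants kept as options, and the
#: GLDM gray-level emphases that duplicate their GLRLM counterparts.
DEFAULT_EXCLUSIONS: frozenset[tuple[str, str]] = frozenset({
    ("firstorder", "TotalEnergy"),
    ("firstorder", "Range"),
    ("glcm", "SumAverage"),
    ("glcm", "SumSquares"),
    ("glcm", "MCC"),
    ("glcm", "Imc1"),
    ("glcm", "Idmn"),
    ("glrlm", "GrayLevelNonUniformityNormalized"),
    ("glrlm", "RunLengthNonUniformityNormalized"),
    ("glszm", "GrayLevelNonUniformityNormalized"),
    ("glszm", "SizeZoneNonUniformityNormalized"),
    ("gldm", "DependenceNonUniformityNormalized"),
    ("gldm", "LowGrayLevelEmphasis"),
    ("gldm", "HighGrayLevelEmphasis"),
})


@dataclass
class FeatureCatalogue:
    """Ordered feature names per family defining the signature layout."""

    families: dict[str, tuple[str, ...]] = field(default_factory=dict)
    shape: tuple[str, ...] = SHAPE_FEATURES

    @classmethod
    def default(cls) -> "FeatureCatalogue":
        fams = {
            fam: tuple(
                n for n in names if (fam, n) not in DEFAULT_EXCLUSIONS
            )
            for fam, names in FAMILY_FEATURES.items()
        }
        return cls(families=fams)

    @property
    def per_map_total(self) -> int:
        return sum(len(v) for v in self.families.values())

    @property
    def shape_total(self) -> int:
        return len(self.shape)

    @property
    def grand_total(self) -> int:
        from .maps import MAP_KINDS

        return len(MAP_KINDS) * self.per_map_total + self.shape_total

    def feature_names(self) -> list[str]:
        """All signature column names in deterministic order."""
        from .maps import MAP_KINDS

        names = []
        for kind in MAP_KINDS:
            for fam, feats in self.families.items():
                names.extend(f"{kind}__{fam}__{n}" for n in feats)
        names.extend(f"shape__{n}" for n in self.shape)
        return names

    def to_dict(self) -> dict:
        return {"families": {k: list(v) for k, v in self.families.items()},
                "shape": list(self.shape)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureCatalogue":
        return cls(
            families={k: tuple(v) for k, v in d["families"].items()},
            shape=tuple(d["shape"]),
        )


@dataclass
class FeatureVector:
    """Named radiomics features of one plane at one timeframe."""

    values: dict[str, float]
    plane_label: str = ""
    timeframe: int = 0
    subject_id: str = ""
    scanner_id: str = ""
    observer_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


def extract_signature(maps: dict[str, ParameterMap], mask: np.ndarray,
                      reference_mask: np.ndarray | None = None,
                      catalogue: FeatureCatalogue | None = None,
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      pixel_size_mm: float = 1.0) -> FeatureVector:
    """The full radiomics signature of one plane at one timeframe.

    ``maps`` holds the five normalized parameter maps; all must share the
    plane grid. Returns exactly ``catalogue.grand_total`` named values
    (411 for the default catalogue).
    """
    from .maps import MAP_KINDS

    if catalogue is None:
        catalogue = FeatureCatalogue.default()
    missing = [k for k in MAP_KINDS if k not in maps]
    if missing:
        raise ValueError(f"missing parameter maps: {missing}")
    mask = np.asarray(mask, dtype=bool)

    out: dict[str, float] = {}
    for kind in MAP_KINDS:
        pmap = maps[kind]
        if not pmap.normalized:
            raise ValueError(f"{kind} map must be normalized before extraction")
        try:
            d = discretize(pmap, bin_width=bin_width, mask=mask)
            fam_values = {
                "firstorder": first_order_features(
                    pmap.values[mask], d.levels[mask],
                    pixel_area=pixel_size_mm**2,
                ),
            }
            for fam, func in _FAMILY_FUNCS.items():
                if func is not None:
                    fam_values[fam] = func(d)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed on map {kind!r}: {exc}"
            ) from exc
        for fam, names in catalogue.families.items():
            vals = fam_values[fam]
            for n in names:
                out[f"{kind}__{fam}__{n}"] = vals[n]

    try:
        shp = shape2d_features(mask, pixel_size_mm, reference_mask)
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed on family 'shape': "
                           f"{exc}") from exc
    for n in catalogue.shape:
        out[f"shape__{n}"] = shp[n]

    first = next(iter(maps.values()))
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite feature values: {bad[:5]}")
    return FeatureVector(values=out, plane_label=first.plane_label,
                         timeframe=first.timeframe)
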