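"""Independent brute-force oracles for the texture feature families.

Everything here is written from the matrix definitions with explicit
Python loops and no shared code with the package: pixel-pair enumeration
for the GLCM, line scanning for the GLRLM, breadth-first flood fill for the
GLSZM, per-pixel neighbor counting for the GLDM/NGTDM, and naive formula
transcriptions for the features. Intended only for small maps.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _inside(mask, y, x):
    return 0 <= y < mask.shape[0] and 0 <= x < mask.shape[1] and mask[y, x]


def _log2(x):
    return math.log2(x)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(levels, mask, dy, dx, ng):
    P = np.zeros((ng, ng))
    for y in range(levels.shape[0]):
        for x in range(levels.shape[1]):
            if not mask[y, x]:
                continue
            for sy, sx in ((dy, dx), (-dy, -dx)):
                yy, xx = y + sy, x + sx
                if _inside(mask, yy, xx):
                    P[levels[y, x] - 1, levels[yy, xx] - 1] += 1
    return P


def _glcm_features_one(P):
    ng = P.shape[0]
    p = P / P.sum()
    i_vals = list(range(1, ng + 1))
    px = [sum(p[i - 1][j - 1] for j in i_vals) for i in i_vals]
    py = [sum(p[i - 1][j - 1] for i in i_vals) for j in i_vals]
    mux = sum(px[i - 1] * i for i in i_vals)
    muy = sum(py[j - 1] * j for j in i_vals)
    sigx = math.sqrt(sum(px[i - 1] * (i - mux) ** 2 for i in i_vals))
    sigy = math.sqrt(sum(py[j - 1] * (j - muy) ** 2 for j in i_vals))

    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng - 1)
    for i in i_vals:
        for j in i_vals:
            pdiff[abs(i - j)] += p[i - 1][j - 1]
            psum[i + j - 2] += p[i - 1][j - 1]

    f = {}
    f["Autocorrelation"] = sum(p[i - 1][j - 1] * i * j
                               for i in i_vals for j in i_vals)
    f["JointAverage"] = mux
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3),
                        ("ClusterTendency", 2)):
        f[name] = sum(p[i - 1][j - 1] * (i + j - mux - muy) ** power
                      for i in i_vals for j in i_vals)
    f["Contrast"] = sum(p[i - 1][j - 1] * (i - j) ** 2
                        for i in i_vals for j in i_vals)
    if sigx > 0 and sigy > 0:
        f["Correlation"] = (f["Autocorrelation"] - mux * muy) / (sigx * sigy)
    else:
        f["Correlation"] = 1.0
    da = sum(k * pdiff[k] for k in range(ng))
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(q * _log2(q) for q in pdiff if q > 0)
    f["DifferenceVariance"] = sum(pdiff[k] * (k - da) ** 2 for k in range(ng))
    f["Id"] = sum(p[i - 1][j - 1] / (1 + abs(i - j))
                  for i in i_vals for j in i_vals)
    f["Idm"] = sum(p[i - 1][j - 1] / (1 + (i - j) ** 2)
                   for i in i_vals for j in i_vals)
    f["Idmn"] = sum(p[i - 1][j - 1] / (1 + ((i - j) / ng) ** 2)
                    for i in i_vals for j in i_vals)
    f["Idn"] = sum(p[i - 1][j - 1] / (1 + abs(i - j) / ng)
                   for i in i_vals for j in i_vals)
    hxy = -sum(p[i - 1][j - 1] * _log2(p[i - 1][j - 1])
               for i in i_vals for j in i_vals if p[i - 1][j - 1] > 0)
    hx = -sum(q * _log2(q) for q in px if q > 0)
    hy = -sum(q * _log2(q) for q in py if q > 0)
    hxy1 = -sum(p[i - 1][j - 1] * _log2(px[i - 1] * py[j - 1])
                for i in i_vals for j in i_vals
                if p[i - 1][j - 1] > 0 and px[i - 1] * py[j - 1] > 0)
    hxy2 = -sum(px[i - 1] * py[j - 1] * _log2(px[i - 1] * py[j - 1])
                for i in i_vals for j in i_vals
                if px[i - 1] * py[j - 1] > 0)
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(p[i - 1][j - 1] / (i - j) ** 2
                               for i in i_vals for j in i_vals if i != j)
    f["JointEnergy"] = sum(p[i - 1][j - 1] ** 2
                           for i in i_vals for j in i_vals)
    f["JointEntropy"] = hxy
    f["MaximumProbability"] = max(p[i - 1][j - 1]
                                  for i in i_vals for j in i_vals)
    keep = [i for i in i_vals if px[i - 1] > 0]
    if len(keep) > 1:
        Q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a, b] = sum(
                    p[i - 1][k - 1] * p[j - 1][k - 1] / (px[i - 1] * py[k - 1])
                    for k in i_vals if py[k - 1] > 0
                )
        eig = sorted(abs(v) for v in np.linalg.eigvals(Q))
        f["MCC"] = math.sqrt(max(eig[-2], 0.0))
    else:
        f["MCC"] = 1.0
    f["SumAverage"] = sum((k + 2) * psum[k] for k in range(2 * ng - 1))
    f["SumEntropy"] = -sum(q * _log2(q) for q in psum if q > 0)
    f["SumSquares"] = sum(p[i - 1][j - 1] * (i - mux) ** 2
                          for i in i_vals for j in i_vals)
    return f


def oracle_glcm(levels, mask):
    ng = int(levels[mask].max())
    per_dir = []
    for dy, dx in DIRECTIONS:
        P = _glcm_matrix(levels, mask, dy, dx, ng)
        if P.sum() > 0:
            per_dir.append(_glcm_features_one(P))
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def oracle_glrlm_matrix(levels, mask):
    ng = int(levels[mask].max())
    h, w = levels.shape
    R = np.zeros((ng, max(h, w)))

    def walk(y, x, dy, dx):
        run_level, run_len = None, 0
        while 0 <= y < h and 0 <= x < w:
            if mask[y, x]:
                lvl = levels[y, x]
                if lvl == run_level:
                    run_len += 1
                else:
                    if run_level is not None:
                        R[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lvl, 1
            else:
                if run_level is not None:
                    R[run_level - 1, run_len - 1] += 1
                run_level, run_len = None, 0
            y, x = y + dy, x + dx
        if run_level is not None:
            R[run_level - 1, run_len - 1] += 1

    for y in range(h):
        walk(y, 0, 0, 1)
    for x in range(w):
        walk(0, x, 1, 0)
    for x in range(w):
        walk(0, x, 1, 1)
    for y in range(1, h):
        walk(y, 0, 1, 1)
    for x in range(w):
        walk(0, x, 1, -1)
    for y in range(1, h):
        walk(y, w - 1, 1, -1)
    return R


def _level_size_features(M, n_pixels, names):
    N = M.sum()
    ng, nl = M.shape
    f = {}
    row = [M[i].sum() for i in range(ng)]
    col = [M[:, j].sum() for j in range(nl)]
    f[names[0]] = sum(M[i, j] / (j + 1) ** 2 for i in range(ng)
                      for j in range(nl)) / N
    f[names[1]] = sum(M[i, j] * (j + 1) ** 2 for i in range(ng)
                      for j in range(nl)) / N
    f[names[2]] = sum(r**2 for r in row) / N
    f[names[3]] = sum(r**2 for r in row) / N**2
    f[names[4]] = sum(c**2 for c in col) / N
    f[names[5]] = sum(c**2 for c in col) / N**2
    f[names[6]] = N / n_pixels
    mu_i = sum(M[i, j] / N * (i + 1) for i in range(ng) for j in range(nl))
    mu_j = sum(M[i, j] / N * (j + 1) for i in range(ng) for j in range(nl))
    f[names[7]] = sum(M[i, j] / N * (i + 1 - mu_i) ** 2
                      for i in range(ng) for j in range(nl))
    f[names[8]] = sum(M[i, j] / N * (j + 1 - mu_j) ** 2
                      for i in range(ng) for j in range(nl))
    f[names[9]] = -sum(M[i, j] / N * _log2(M[i, j] / N)
                       for i in range(ng) for j in range(nl) if M[i, j] > 0)
    f[names[10]] = sum(M[i, j] / (i + 1) ** 2 for i in range(ng)
                       for j in range(nl)) / N
    f[names[11]] = sum(M[i, j] * (i + 1) ** 2 for i in range(ng)
                       for j in range(nl)) / N
    f[names[12]] = sum(M[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                       for i in range(ng) for j in range(nl)) / N
    f[names[13]] = sum(M[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                       for i in range(ng) for j in range(nl)) / N
    f[names[14]] = sum(M[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                       for i in range(ng) for j in range(nl)) / N
    f[names[15]] = sum(M[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                       for i in range(ng) for j in range(nl)) / N
    return f


GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]


def oracle_glrlm(levels, mask):
    R = oracle_glrlm_matrix(levels, mask)
    return _level_size_features(R, 4 * int(mask.sum()), GLRLM_NAMES)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def oracle_glszm(levels, mask):
    ng = int(levels[mask].max())
    n_pixels = int(mask.sum())
    Z = np.zeros((ng, n_pixels))
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            lvl = levels[y0, x0]
            stack = [(y0, x0)]
            seen[y0, x0] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if (_inside(mask, yy, xx) and not seen[yy, xx]
                                and levels[yy, xx] == lvl):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            Z[lvl - 1, size - 1] += 1
    return _level_size_features(Z, n_pixels, GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def oracle_gldm(levels, mask, alpha=0):
    ng = int(levels[mask].max())
    D = np.zeros((ng, 9))
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            dep = 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if (_inside(mask, yy, xx)
                            and abs(int(levels[yy, xx]) - int(levels[y, x]))
                            <= alpha):
                        dep += 1
            D[levels[y, x] - 1, dep] += 1
    N = D.sum()
    f = {}
    names = [
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelNonUniformity", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "GrayLevelVariance",
        "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    ]
    nl = 9
    row = [D[i].sum() for i in range(ng)]
    col = [D[:, j].sum() for j in range(nl)]
    f[names[0]] = sum(D[i, j] / (j + 1) ** 2 for i in range(ng)
                      for j in range(nl)) / N
    f[names[1]] = sum(D[i, j] * (j + 1) ** 2 for i in range(ng)
                      for j in range(nl)) / N
    f[names[2]] = sum(r**2 for r in row) / N
    f[names[3]] = sum(c**2 for c in col) / N
    f[names[4]] = sum(c**2 for c in col) / N**2
    mu_i = sum(D[i, j] / N * (i + 1) for i in range(ng) for j in range(nl))
    mu_j = sum(D[i, j] / N * (j + 1) for i in range(ng) for j in range(nl))
    f[names[5]] = sum(D[i, j] / N * (i + 1 - mu_i) ** 2
                      for i in range(ng) for j in range(nl))
    f[names[6]] = sum(D[i, j] / N * (j + 1 - mu_j) ** 2
                      for i in range(ng) for j in range(nl))
    f[names[7]] = -sum(D[i, j] / N * _log2(D[i, j] / N)
                       for i in range(ng) for j in range(nl) if D[i, j] > 0)
    f[names[8]] = sum(D[i, j] / (i + 1) ** 2 for i in range(ng)
                      for j in range(nl)) / N
    f[names[9]] = sum(D[i, j] * (i + 1) ** 2 for i in range(ng)
                      for j in range(nl)) / N
    f[names[10]] = sum(D[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                       for i in range(ng) for j in range(nl)) / N
    f[names[11]] = sum(D[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                       for i in range(ng) for j in range(nl)) / N
    f[names[12]] = sum(D[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                       for i in range(ng) for j in range(nl)) / N
    f[names[13]] = sum(D[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                       for i in range(ng) for j in range(nl)) / N
    return f


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def oracle_ngtdm(levels, mask, coarseness_max=1e6):
    ng = int(levels[mask].max())
    s = [0.0] * ng
    n = [0.0] * ng
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            nb = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    if _inside(mask, y + dy, x + dx):
                        nb.append(int(levels[y + dy, x + dx]))
            if nb:
                i = int(levels[y, x])
                s[i - 1] += abs(i - sum(nb) / len(nb))
                n[i - 1] += 1
    Nvp = sum(n)
    p = [ni / Nvp for ni in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)

    denom = sum(p[i] * s[i] for i in range(ng))
    coarse = 1.0 / denom if denom > 0 else coarseness_max
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (sum(s) / Nvp)
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                       for i in present for j in present)
        busy = denom / busy_den if busy_den > 0 else 0.0
        cmplx = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / Nvp
        s_sum = sum(s)
        strength = (sum((p[i] + p[j]) * (i - j) ** 2
                        for i in present for j in present) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = busy = cmplx = strength = 0.0
    return {
        "Coarseness": coarse,
        "Contrast": contrast,
        "Busyness": busy,
        "Complexity": cmplx,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def oracle_first_order(values, levels, pixel_area=1.0):
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    p10, p90 = np.percentile(v, [10, 90])
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust)
    counts = {}
    for lvl in levels:
        counts[int(lvl)] = counts.get(int(lvl), 0) + 1
    probs = [c / n for c in counts.values()]
    return {
        "Energy": sum(x**2 for x in v),
        "TotalEnergy": pixel_area * sum(x**2 for x in v),
        "Entropy": -sum(p * _log2(p) for p in probs),
        "Minimum": v[0],
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": v[-1],
        "Mean": mean,
        "Median": float(np.median(v)),
        "InterquartileRange": float(np.percentile(v, 75)
                                    - np.percentile(v, 25)),
        "Range": v[-1] - v[0],
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(x - rmean)
                                           for x in robust) / len(robust),
        "RootMeanSquared": math.sqrt(sum(x**2 for x in v) / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p**2 for p in probs),
    }
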