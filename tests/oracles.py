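"""Naive brute-force references for the texture-matrix families.

Everything here is written as explicit per-voxel / per-entry Python
loops, independent of the vectorized implementations in
``angiokin.radiomics``: pair counting for GLCM, run walking for GLRLM,
flood fill for GLSZM, neighbor counting for GLDM/NGTDM, and scalar
double loops for every feature formula. Shared conventions (13
directions, eps guards, log2, degenerate cases) are restated from the
documented definitions, not imported.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-16

DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
NEIGHBORS_26 = [
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _inside(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


def naive_glcm(levels, mask, ng, distance=1):
    shape = levels.shape
    out = np.zeros((len(DIRECTIONS), ng, ng))
    for d, off in enumerate(DIRECTIONS):
        off = tuple(o * distance for o in off)
        for p in np.ndindex(shape):
            if not mask[p]:
                continue
            for sgn in (1, -1):
                q = tuple(c + sgn * o for c, o in zip(p, off))
                if _inside(q, shape) and mask[q]:
                    out[d, levels[p] - 1, levels[q] - 1] += 1
    return out


def naive_glrlm(levels, mask, ng):
    shape = levels.shape
    mats = []
    max_len = 1
    for off in DIRECTIONS:
        runs = {}
        for p in np.ndindex(shape):
            if not mask[p]:
                continue
            prev = tuple(c - o for c, o in zip(p, off))
            if _inside(prev, shape) and mask[prev] and levels[prev] == levels[p]:
                continue  # not a run start
            g = levels[p]
            length = 1
            q = tuple(c + o for c, o in zip(p, off))
            while _inside(q, shape) and mask[q] and levels[q] == g:
                length += 1
                q = tuple(c + o for c, o in zip(q, off))
            runs[(g, length)] = runs.get((g, length), 0) + 1
            max_len = max(max_len, length)
        mats.append(runs)
    out = np.zeros((len(DIRECTIONS), ng, max_len))
    for d, runs in enumerate(mats):
        for (g, length), c in runs.items():
            out[d, g - 1, length - 1] = c
    return out


def naive_glszm(levels, mask, ng):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in np.ndindex(shape):
        if not mask[p] or seen[p]:
            continue
        g = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in NEIGHBORS_26:
                q = tuple(c + o for c, o in zip(cur, off))
                if _inside(q, shape) and mask[q] and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    out = np.zeros((ng, max_size))
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def naive_gldm(levels, mask, ng, distance=1, alpha=0):
    shape = levels.shape
    deps = []
    for p in np.ndindex(shape):
        if not mask[p]:
            continue
        dep = 1
        for off in NEIGHBORS_26:
            q = tuple(c + o * distance for c, o in zip(p, off))
            if _inside(q, shape) and mask[q] and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        deps.append((levels[p], dep))
    max_dep = max(d for _, d in deps)
    out = np.zeros((ng, max_dep))
    for g, d in deps:
        out[g - 1, d - 1] += 1
    return out


def naive_ngtdm(levels, mask, ng, distance=1):
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    n_valid = 0
    for p in np.ndindex(shape):
        if not mask[p]:
            continue
        neigh = []
        for off in NEIGHBORS_26:
            q = tuple(c + o * distance for c, o in zip(p, off))
            if _inside(q, shape) and mask[q]:
                neigh.append(int(levels[q]))
        if not neigh:
            continue
        n_valid += 1
        g = int(levels[p])
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(neigh) / len(neigh))
    p_col = n / n_valid if n_valid else n
    return np.stack([n, p_col, s], axis=1), n_valid


# ---------------------------------------------------------------------------
# naive feature formulas (scalar loops over matrix entries)


def _log2(v):
    return math.log(v, 2)


def naive_glcm_features_one(counts):
    ng = counts.shape[0]
    total = counts.sum()
    p = counts / total
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    f = {}
    f["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
    )
    f["JointAverage"] = mu_x
    for name, power in (("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)):
        f[name] = sum(
            (i + 1 + j + 1 - mu_x - mu_y) ** power * p[i][j]
            for i in range(ng)
            for j in range(ng)
        )
    f["Contrast"] = sum(
        (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    if sig_x * sig_y > 1e-12:
        f["Correlation"] = (f["Autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
    else:
        f["Correlation"] = 1.0
    da = sum(k * v for k, v in p_diff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(v * _log2(v + EPS) for v in p_diff.values())
    f["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    f["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(
        p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    f["Idn"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    hxy = -sum(p[i][j] * _log2(p[i][j] + EPS) for i in range(ng) for j in range(ng))
    hxy1 = -sum(
        p[i][j] * _log2(px[i] * py[j] + EPS) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j] + EPS)
        for i in range(ng)
        for j in range(ng)
    )
    hx = -sum(v * _log2(v + EPS) for v in px)
    hy = -sum(v * _log2(v + EPS) for v in py)
    div = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / div if div > EPS else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    f["MCC"] = _naive_mcc(p, px, py, ng)
    f["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    f["SumAverage"] = sum(k * v for k, v in p_sum.items())
    f["SumEntropy"] = -sum(v * _log2(v + EPS) for v in p_sum.values())
    f["SumSquares"] = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    return f


def _naive_mcc(p, px, py, ng):
    if ng == 1:
        return 1.0
    q = np.zeros((ng, ng))
    for i in range(ng):
        for j in range(ng):
            if px[i] <= 0 or py[j] <= 0:
                continue
            q[i][j] = sum(
                p[i][k] * p[j][k] / (py[k] + EPS)
                for k in range(ng)
                if py[k] > 0
            ) / (px[i] + EPS)
    ev = sorted(np.real(np.linalg.eigvals(q)))
    return math.sqrt(max(0.0, ev[-2])) if len(ev) > 1 else 1.0


def _naive_size_matrix_features(counts, n_voxels):
    """Generic (gray level x size) features keyed by short codes."""
    ng, nl = counts.shape
    ns = counts.sum()
    p = counts / ns
    pg = [sum(p[i][j] for j in range(nl)) for i in range(ng)]
    ps = [sum(p[i][j] for i in range(ng)) for j in range(nl)]
    mu_i = sum((i + 1) * pg[i] for i in range(ng))
    mu_j = sum((j + 1) * ps[j] for j in range(nl))
    f = {}
    f["sse"] = sum(p[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nl))
    f["lse"] = sum(p[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nl))
    f["gln"] = sum(sum(counts[i]) ** 2 for i in range(ng)) / ns
    f["glnn"] = sum(v**2 for v in pg)
    f["sn"] = sum(sum(counts[i][j] for i in range(ng)) ** 2 for j in range(nl)) / ns
    f["snn"] = sum(v**2 for v in ps)
    f["pct"] = ns / n_voxels
    f["glv"] = sum(
        (i + 1 - mu_i) ** 2 * p[i][j] for i in range(ng) for j in range(nl)
    )
    f["sv"] = sum(
        (j + 1 - mu_j) ** 2 * p[i][j] for i in range(ng) for j in range(nl)
    )
    f["ent"] = -sum(
        p[i][j] * _log2(p[i][j] + EPS) for i in range(ng) for j in range(nl)
    )
    f["lgl"] = sum(p[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nl))
    f["hgl"] = sum(p[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nl))
    f["slgl"] = sum(
        p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nl)
    )
    f["shgl"] = sum(
        p[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nl)
    )
    f["llgl"] = sum(
        p[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nl)
    )
    f["lhgl"] = sum(
        p[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nl)
    )
    return f


_RL_KEYS = {
    "ShortRunEmphasis": "sse", "LongRunEmphasis": "lse",
    "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "sn", "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "pct", "GrayLevelVariance": "glv", "RunVariance": "sv",
    "RunEntropy": "ent", "LowGrayLevelRunEmphasis": "lgl",
    "HighGrayLevelRunEmphasis": "hgl", "ShortRunLowGrayLevelEmphasis": "slgl",
    "ShortRunHighGrayLevelEmphasis": "shgl", "LongRunLowGrayLevelEmphasis": "llgl",
    "LongRunHighGrayLevelEmphasis": "lhgl",
}
_SZ_KEYS = {
    "SmallAreaEmphasis": "sse", "LargeAreaEmphasis": "lse",
    "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "sn", "SizeZoneNonUniformityNormalized": "snn",
    "ZonePercentage": "pct", "GrayLevelVariance": "glv", "ZoneVariance": "sv",
    "ZoneEntropy": "ent", "LowGrayLevelZoneEmphasis": "lgl",
    "HighGrayLevelZoneEmphasis": "hgl", "SmallAreaLowGrayLevelEmphasis": "slgl",
    "SmallAreaHighGrayLevelEmphasis": "shgl", "LargeAreaLowGrayLevelEmphasis": "llgl",
    "LargeAreaHighGrayLevelEmphasis": "lhgl",
}
_DM_KEYS = {
    "SmallDependenceEmphasis": "sse", "LargeDependenceEmphasis": "lse",
    "GrayLevelNonUniformity": "gln", "DependenceNonUniformity": "sn",
    "DependenceNonUniformityNormalized": "snn", "GrayLevelVariance": "glv",
    "DependenceVariance": "sv", "DependenceEntropy": "ent",
    "LowGrayLevelEmphasis": "lgl", "HighGrayLevelEmphasis": "hgl",
    "SmallDependenceLowGrayLevelEmphasis": "slgl",
    "SmallDependenceHighGrayLevelEmphasis": "shgl",
    "LargeDependenceLowGrayLevelEmphasis": "llgl",
    "LargeDependenceHighGrayLevelEmphasis": "lhgl",
}


def _avg_dirs(stack, n_voxels, keys):
    acc, n = {}, 0
    for m in stack:
        if m.sum() <= 0:
            continue
        f = _naive_size_matrix_features(m, n_voxels)
        for name, code in keys.items():
            acc[name] = acc.get(name, 0.0) + f[code]
        n += 1
    return {k: v / n for k, v in acc.items()}


def naive_glcm_features(stack):
    acc, n = {}, 0
    for m in stack:
        if m.sum() <= 0:
            continue
        f = naive_glcm_features_one(m)
        for k, v in f.items():
            acc[k] = acc.get(k, 0.0) + v
        n += 1
    return {k: v / n for k, v in acc.items()}


def naive_glrlm_features(stack, n_voxels):
    return _avg_dirs(stack, n_voxels, _RL_KEYS)


def naive_glszm_features(counts, n_voxels):
    f = _naive_size_matrix_features(counts, n_voxels)
    return {name: f[code] for name, code in _SZ_KEYS.items()}


def naive_gldm_features(counts, n_voxels):
    f = _naive_size_matrix_features(counts, n_voxels)
    return {name: f[code] for name, code in _DM_KEYS.items()}


def naive_ngtdm_features(table, n_valid):
    ng = table.shape[0]
    n = table[:, 0]
    p = table[:, 1]
    s = table[:, 2]
    levels = [i + 1 for i in range(ng) if p[i] > 0]
    ngp = len(levels)
    f = {}
    denom = sum(p[i] * s[i] for i in range(ng))
    f["Coarseness"] = 1.0 / denom if denom > EPS else 1e6
    if ngp > 1 and n_valid > 0:
        f["Contrast"] = (
            sum(
                p[i - 1] * p[j - 1] * (i - j) ** 2
                for i in levels
                for j in levels
            )
            / (ngp * (ngp - 1))
            * sum(s)
            / n_valid
        )
        busy_den = sum(
            abs(i * p[i - 1] - j * p[j - 1]) for i in levels for j in levels
        )
        f["Busyness"] = denom / busy_den if busy_den > EPS else 0.0
        f["Complexity"] = (
            sum(
                abs(i - j)
                * (p[i - 1] * s[i - 1] + p[j - 1] * s[j - 1])
                / (p[i - 1] + p[j - 1])
                for i in levels
                for j in levels
            )
            / n_valid
        )
        ssum = sum(s)
        f["Strength"] = (
            sum(
                (p[i - 1] + p[j - 1]) * (i - j) ** 2
                for i in levels
                for j in levels
            )
            / ssum
            if ssum > EPS
            else 0.0
        )
    else:
        f.update(Contrast=0.0, Busyness=0.0, Complexity=0.0, Strength=0.0)
    return f


def naive_all_matrix_features(levels, mask, ng, distance=1):
    """All five families' features from scratch on one discretized image."""
    n_voxels = int(mask.sum())
    out = {}
    for k, v in naive_glcm_features(naive_glcm(levels, mask, ng, distance)).items():
        out[f"glcm_{k}"] = v
    for k, v in naive_glrlm_features(naive_glrlm(levels, mask, ng), n_voxels).items():
        out[f"glrlm_{k}"] = v
    for k, v in naive_glszm_features(naive_glszm(levels, mask, ng), n_voxels).items():
        out[f"glszm_{k}"] = v
    for k, v in naive_gldm_features(
        naive_gldm(levels, mask, ng, distance), n_voxels
    ).items():
        out[f"gldm_{k}"] = v
    table, n_valid = naive_ngtdm(levels, mask, ng, distance)
    for k, v in naive_ngtdm_features(table, n_valid).items():
        out[f"ngtdm_{k}"] = v
    return out
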