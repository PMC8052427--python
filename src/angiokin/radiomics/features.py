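"""Feature formulas for the gray-level matrix families.

Per-direction families (GLCM, GLRLM) are computed on each of the 13
direction matrices and averaged; single-matrix families (GLSZM, GLDM,
NGTDM) are computed once. Entropies use log base 2; all ratio and log
arguments carry an eps = 1e-16 guard. Degenerate single-level regions
give 0 for entropy- and variance-like features (Correlation and MCC
conventionally 1 for a perfectly uniform region).
"""

from __future__ import annotations

import numpy as np

from .matrices import GrayLevelMatrix

EPS = 1e-16


def _avg_over_directions(stack: np.ndarray, func) -> dict:
    feats: dict[str, float] = {}
    n = 0
    for m in stack:
        if m.sum() <= 0:
            continue
        f = func(m)
        for k, v in f.items():
            feats[k] = feats.get(k, 0.0) + v
        n += 1
    if n == 0:
        raise ValueError("no direction produced any counts")
    return {k: v / n for k, v in feats.items()}


# ---------------------------------------------------------------------------
# GLCM


def _glcm_one(counts: np.ndarray) -> dict:
    p = counts / counts.sum()
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # sum / difference marginals
    ks = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in ks])
    kd = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in kd])

    autoc = float((ii * jj * p).sum())
    f: dict[str, float] = {}
    f["Autocorrelation"] = autoc
    f["JointAverage"] = mu_x
    c = ii + jj - mu_x - mu_y
    f["ClusterProminence"] = float((c**4 * p).sum())
    f["ClusterShade"] = float((c**3 * p).sum())
    f["ClusterTendency"] = float((c**2 * p).sum())
    f["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sig_x * sig_y > 1e-12:
        f["Correlation"] = (autoc - mu_x * mu_y) / (sig_x * sig_y)
    else:
        f["Correlation"] = 1.0
    da = float((kd * p_diff).sum())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = float(-(p_diff * np.log2(p_diff + EPS)).sum())
    f["DifferenceVariance"] = float(((kd - da) ** 2 * p_diff).sum())
    absd = np.abs(ii - jj)
    f["Id"] = float((p / (1.0 + absd)).sum())
    f["Idm"] = float((p / (1.0 + absd**2)).sum())
    f["Idmn"] = float((p / (1.0 + (absd / ng) ** 2)).sum())
    f["Idn"] = float((p / (1.0 + absd / ng)).sum())
    hxy = float(-(p * np.log2(p + EPS)).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * np.log2(pxpy + EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + EPS)).sum())
    hx = float(-(px * np.log2(px + EPS)).sum())
    hy = float(-(py * np.log2(py + EPS)).sum())
    div = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / div if div > EPS else 0.0
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = absd > 0
    f["InverseVariance"] = float((p[off] / absd[off] ** 2).sum()) if off.any() else 0.0
    f["JointEnergy"] = float((p**2).sum())
    f["JointEntropy"] = hxy
    f["MCC"] = _glcm_mcc(p, px, py)
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = float((ks * p_sum).sum())
    f["SumEntropy"] = float(-(p_sum * np.log2(p_sum + EPS)).sum())
    f["SumSquares"] = float(((ii - mu_x) ** 2 * p).sum())
    return f


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    ng = p.shape[0]
    if ng == 1:
        return 1.0
    nz = (px > 0) & (py > 0)
    q = np.zeros((ng, ng))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(py[None, :] > 0, p / (py[None, :] + EPS), 0.0)
        q[np.ix_(nz, nz)] = (p[nz] @ a[nz].T) / (px[nz, None] + EPS)
    ev = np.linalg.eigvals(q)
    ev = np.sort(np.real(ev))
    if len(ev) < 2:
        return 1.0
    return float(np.sqrt(max(0.0, ev[-2])))


def glcm_features(glm: GrayLevelMatrix) -> dict:
    return _avg_over_directions(glm.matrix, _glcm_one)


# ---------------------------------------------------------------------------
# run-length / size-zone shared machinery


def _rl_core(counts: np.ndarray) -> dict:
    """Common statistics for a (gray level x size) count matrix."""
    ns = counts.sum()
    p = counts / ns
    ng, nl = counts.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((i[:, 0] * pg).sum())
    mu_j = float((j[0, :] * ps).sum())
    return {
        "n": ns,
        "p": p,
        "i": i,
        "j": j,
        "pg": pg,
        "ps": ps,
        "mu_i": mu_i,
        "mu_j": mu_j,
        "counts": counts,
    }


def _rl_features(counts: np.ndarray, n_voxels: int, names: dict) -> dict:
    c = _rl_core(counts)
    p, i, j = c["p"], c["i"], c["j"]
    ns = c["n"]
    f = {}
    f[names["sse"]] = float((p / j**2).sum())
    f[names["lse"]] = float((p * j**2).sum())
    f[names["gln"]] = float((counts.sum(axis=1) ** 2).sum() / ns)
    f[names["glnn"]] = float((c["pg"] ** 2).sum())
    f[names["sn"]] = float((counts.sum(axis=0) ** 2).sum() / ns)
    f[names["snn"]] = float((c["ps"] ** 2).sum())
    f[names["pct"]] = float(ns / n_voxels)
    f[names["glv"]] = float(((i - c["mu_i"]) ** 2 * p).sum())
    f[names["sv"]] = float(((j - c["mu_j"]) ** 2 * p).sum())
    f[names["ent"]] = float(-(p * np.log2(p + EPS)).sum())
    f[names["lgl"]] = float((p / i**2).sum())
    f[names["hgl"]] = float((p * i**2).sum())
    f[names["slgl"]] = float((p / (i**2 * j**2)).sum())
    f[names["shgl"]] = float((p * i**2 / j**2).sum())
    f[names["llgl"]] = float((p * j**2 / i**2).sum())
    f[names["lhgl"]] = float((p * i**2 * j**2).sum())
    return f


_GLRLM_NAMES = {
    "sse": "ShortRunEmphasis",
    "lse": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity",
    "snn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage",
    "glv": "GrayLevelVariance",
    "sv": "RunVariance",
    "ent": "RunEntropy",
    "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis",
    "slgl": "ShortRunLowGrayLevelEmphasis",
    "shgl": "ShortRunHighGrayLevelEmphasis",
    "llgl": "LongRunLowGrayLevelEmphasis",
    "lhgl": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "sse": "SmallAreaEmphasis",
    "lse": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity",
    "snn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "sv": "ZoneVariance",
    "ent": "ZoneEntropy",
    "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis",
    "slgl": "SmallAreaLowGrayLevelEmphasis",
    "shgl": "SmallAreaHighGrayLevelEmphasis",
    "llgl": "LargeAreaLowGrayLevelEmphasis",
    "lhgl": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(glm: GrayLevelMatrix) -> dict:
    return _avg_over_directions(
        glm.matrix, lambda m: _rl_features(m, glm.n_voxels, _GLRLM_NAMES)
    )


def glszm_features(glm: GrayLevelMatrix) -> dict:
    return _rl_features(glm.matrix, glm.n_voxels, _GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(glm: GrayLevelMatrix) -> dict:
    counts = glm.matrix
    c = _rl_core(counts)
    p, i, j = c["p"], c["i"], c["j"]
    ns = c["n"]
    f = {}
    f["SmallDependenceEmphasis"] = float((p / j**2).sum())
    f["LargeDependenceEmphasis"] = float((p * j**2).sum())
    f["GrayLevelNonUniformity"] = float((counts.sum(axis=1) ** 2).sum() / ns)
    f["DependenceNonUniformity"] = float((counts.sum(axis=0) ** 2).sum() / ns)
    f["DependenceNonUniformityNormalized"] = float((c["ps"] ** 2).sum())
    f["GrayLevelVariance"] = float(((i - c["mu_i"]) ** 2 * p).sum())
    f["DependenceVariance"] = float(((j - c["mu_j"]) ** 2 * p).sum())
    f["DependenceEntropy"] = float(-(p * np.log2(p + EPS)).sum())
    f["LowGrayLevelEmphasis"] = float((p / i**2).sum())
    f["HighGrayLevelEmphasis"] = float((p * i**2).sum())
    f["SmallDependenceLowGrayLevelEmphasis"] = float((p / (i**2 * j**2)).sum())
    f["SmallDependenceHighGrayLevelEmphasis"] = float((p * i**2 / j**2).sum())
    f["LargeDependenceLowGrayLevelEmphasis"] = float((p * j**2 / i**2).sum())
    f["LargeDependenceHighGrayLevelEmphasis"] = float((p * i**2 * j**2).sum())
    return f


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(glm: GrayLevelMatrix) -> dict:
    table = glm.matrix
    n = table[:, 0]
    p = table[:, 1]
    s = table[:, 2]
    nvp = glm.n_voxels
    i = np.arange(1, len(p) + 1, dtype=float)
    nz = p > 0
    ngp = int(nz.sum())

    f = {}
    denom = float((p * s).sum())
    f["Coarseness"] = 1.0 / denom if denom > EPS else 1e6
    if ngp > 1 and nvp > 0:
        ii = i[nz][:, None]
        jj = i[nz][None, :]
        pi = p[nz][:, None]
        pj = p[nz][None, :]
        si = s[nz][:, None]
        sj = s[nz][None, :]
        f["Contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (ngp * (ngp - 1))
            * s.sum()
            / nvp
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        f["Busyness"] = denom / busy_den if busy_den > EPS else 0.0
        f["Complexity"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / nvp
        )
        ssum = float(s.sum())
        f["Strength"] = (
            float(((pi + pj) * (ii - jj) ** 2).sum()) / ssum if ssum > EPS else 0.0
        )
    else:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    return f


FAMILY_FEATURES = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "GLDM": gldm_features,
    "NGTDM": ngtdm_features,
}


def features_from_family(glm: GrayLevelMatrix, family: str | None = None) -> dict:
    """Compute the full feature set of one matrix family."""
    fam = (family or glm.family).upper()
    if fam not in FAMILY_FEATURES:
        raise ValueError(f"unknown family {fam!r}")
    return FAMILY_FEATURES[fam](glm)
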