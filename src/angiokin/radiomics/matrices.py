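"""Gray-level texture matrices: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All builders operate on a :class:`~angiokin.radiomics.preprocess.DiscretizedVolume`
(integer levels 1..Ng over a mask) and return raw counts; normalization
happens in the feature formulas.

Conventions
-----------
* GLCM / GLRLM: the 13 unique 3D direction vectors at Chebyshev
  distance 1 (one per opposite pair of the 26-neighborhood); GLCM
  matrices are symmetrized per direction.
* GLSZM: zones are 26-connected components of equal gray level.
* GLDM: a neighbor is "dependent" when |level difference| <= alpha
  (default 0); the dependence size of a voxel is 1 (itself) plus its
  number of dependent in-mask neighbors within the 26-neighborhood.
* NGTDM: per level i, n_i voxels, s_i the summed absolute difference
  between i and the mean level of each voxel's valid in-mask
  neighbors; voxels with no valid neighbor are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedVolume

# one representative per opposite-direction pair of the 26-neighborhood
OFFSETS_13 = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

OFFSETS_26 = tuple(
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
)

FAMILIES = ("GLCM", "GLRLM", "GLSZM", "GLDM", "NGTDM")


@dataclass
class GrayLevelMatrix:
    """A texture matrix with its family tag and axis semantics.

    For GLCM and GLRLM ``matrix`` has a leading direction axis
    (13, Ng, ...); GLSZM/GLDM are (Ng, size); NGTDM is an (Ng, 3)
    table of per-level [count n_i, probability p_i, difference sum s_i].
    Entries are raw counts (``normalized`` False) except the NGTDM
    probability column.
    """

    family: str
    matrix: np.ndarray
    n_levels: int
    n_voxels: int
    directions: tuple = ()
    normalized: bool = False


def _pair_views(arr: np.ndarray, off):
    """Views (a, b) such that b is a shifted by `off` (b = arr at x+off)."""
    slc_a, slc_b = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            slc_a.append(slice(0, n - o))
            slc_b.append(slice(o, n))
        else:
            slc_a.append(slice(-o, n))
            slc_b.append(slice(0, n + o))
    return arr[tuple(slc_a)], arr[tuple(slc_b)]


def glcm(dv: DiscretizedVolume, distance: int = 1) -> GrayLevelMatrix:
    """Symmetric co-occurrence counts, one (Ng, Ng) matrix per direction."""
    ng = dv.n_levels
    lev, mask = dv.levels, dv.mask
    out = np.zeros((len(OFFSETS_13), ng, ng), dtype=float)
    for d, off in enumerate(OFFSETS_13):
        off_d = tuple(o * distance for o in off)
        la, lb = _pair_views(lev, off_d)
        ma, mb = _pair_views(mask, off_d)
        sel = ma & mb
        a = la[sel] - 1
        b = lb[sel] - 1
        m = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        out[d] = m + m.T
    return GrayLevelMatrix(
        "GLCM", out, ng, int(mask.sum()), directions=OFFSETS_13
    )


def glrlm(dv: DiscretizedVolume) -> GrayLevelMatrix:
    """Run-length counts per direction: (13, Ng, max_run_length)."""
    ng = dv.n_levels
    lev, mask = dv.levels, dv.mask
    shape = lev.shape
    per_dir = []
    max_len = 1
    for off in OFFSETS_13:
        # a run starts at an in-mask voxel whose predecessor (x - off)
        # is outside the grid, outside the mask, or a different level
        cont = np.zeros(shape, dtype=bool)
        la, lb = _pair_views(lev, off)  # lb = level at x, la = level at x-off
        ma, mb = _pair_views(mask, off)
        sub = ma & mb & (la == lb)
        _, dst = _pair_views(cont, off)
        dst[...] = sub
        starts = np.argwhere(mask & ~cont)
        runs: dict[tuple[int, int], int] = {}
        for p in starts:
            g = int(lev[tuple(p)])
            length = 1
            q = p + off
            while (
                (0 <= q).all()
                and (q < shape).all()
                and mask[tuple(q)]
                and lev[tuple(q)] == g
            ):
                length += 1
                q = q + off
            runs[(g, length)] = runs.get((g, length), 0) + 1
            max_len = max(max_len, length)
        per_dir.append(runs)
    out = np.zeros((len(OFFSETS_13), ng, max_len), dtype=float)
    for d, runs in enumerate(per_dir):
        for (g, length), c in runs.items():
            out[d, g - 1, length - 1] = c
    return GrayLevelMatrix(
        "GLRLM", out, ng, int(mask.sum()), directions=OFFSETS_13
    )


def glszm(dv: DiscretizedVolume) -> GrayLevelMatrix:
    """26-connected equal-level zone-size counts: (Ng, max_zone_size)."""
    ng = dv.n_levels
    lev, mask = dv.levels, dv.mask
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, ng + 1):
        labels, n = ndimage.label(lev == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    out = np.zeros((ng, max_size), dtype=float)
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return GrayLevelMatrix("GLSZM", out, ng, int(mask.sum()))


def gldm(dv: DiscretizedVolume, distance: int = 1, alpha: int = 0) -> GrayLevelMatrix:
    """Dependence counts: (Ng, max_dependence) with dependence >= 1."""
    ng = dv.n_levels
    lev, mask = dv.levels, dv.mask
    dep = np.ones(lev.shape, dtype=np.int32)  # the center depends on itself
    for off in OFFSETS_26:
        off_d = tuple(o * distance for o in off)
        la, lb = _pair_views(lev, off_d)
        ma, mb = _pair_views(mask, off_d)
        ok = ma & mb & (np.abs(la - lb) <= alpha)
        _, dst = _pair_views(dep, off_d)
        dst[ok] += 1
    dep_m = dep[mask]
    lev_m = lev[mask]
    max_dep = int(dep_m.max())
    out = np.zeros((ng, max_dep), dtype=float)
    np.add.at(out, (lev_m - 1, dep_m - 1), 1.0)
    return GrayLevelMatrix("GLDM", out, ng, int(mask.sum()))


def ngtdm(dv: DiscretizedVolume, distance: int = 1) -> GrayLevelMatrix:
    """Per-level [n_i, p_i, s_i] table from neighborhood gray-tone differences."""
    ng = dv.n_levels
    lev, mask = dv.levels, dv.mask
    nsum = np.zeros(lev.shape, dtype=float)
    ncnt = np.zeros(lev.shape, dtype=np.int32)
    for off in OFFSETS_26:
        off_d = tuple(o * distance for o in off)
        la, lb = _pair_views(lev, off_d)
        ma, mb = _pair_views(mask, off_d)
        ok = ma & mb
        _, dsum = _pair_views(nsum, off_d)
        _, dcnt = _pair_views(ncnt, off_d)
        dsum[ok] += la[ok]
        dcnt[ok] += 1
    valid = mask & (ncnt > 0)
    n_valid = int(valid.sum())
    table = np.zeros((ng, 3), dtype=float)
    if n_valid:
        abar = nsum[valid] / ncnt[valid]
        lv = lev[valid]
        np.add.at(table[:, 0], lv - 1, 1.0)
        np.add.at(table[:, 2], lv - 1, np.abs(lv - abar))
        table[:, 1] = table[:, 0] / n_valid
    return GrayLevelMatrix("NGTDM", table, ng, n_valid)


_BUILDERS = {
    "GLCM": glcm,
    "GLRLM": lambda dv, distance=1: glrlm(dv),
    "GLSZM": lambda dv, distance=1: glszm(dv),
    "GLDM": gldm,
    "NGTDM": ngtdm,
}


def build_matrix(dv: DiscretizedVolume, family: str, distance: int = 1) -> GrayLevelMatrix:
    """Build one texture matrix family; ``family`` is case-insensitive."""
    key = family.upper()
    if key not in _BUILDERS:
        raise ValueError(f"unknown matrix family {family!r}; expected one of {FAMILIES}")
    return _BUILDERS[key](dv, distance=distance)
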