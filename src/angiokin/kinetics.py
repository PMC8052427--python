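"""Semi-quantitative DCE-MRI kinetic analysis.

Voxel-wise percent enhancement (PE) and signal enhancement ratio (SER)
maps over a tumor mask, plus the four per-lesion summaries used in
breast DCE-MRI angiogenesis work: peak PE, peak SER (3x3x3 hot-spot
window means), functional tumor volume (FTV) and washout fraction (WF).

Definitions
-----------
With S0 the pre-contrast signal, S1 the early (~120 s) and S2 the late
(~480 s) post-contrast signals:

    PE  = 100 * (S1 - S0) / S0          [%]
    SER = (S1 - S0) / (S2 - S0)         [unitless]

SER is computed only where PE >= 50%. A voxel "washes out" when
PE >= 50% and SER >= 1.1. FTV is the summed volume of PE >= 50% voxels
(cm^3); WF is the percentage of all defined tumor voxels that wash out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

PE_THRESHOLD_PCT = 50.0
SER_WASHOUT_THRESHOLD = 1.1
SER_MAX = 10.0
_EPS_REL = 1e-6


@dataclass(frozen=True)
class DceSeries:
    """A 4-timepoint DCE-MRI series on a common voxel grid.

    volumes : sequence of four 3D arrays ordered by acquisition time
        (pre-contrast, then three post-contrast volumes).
    spacing_mm : (dx, dy, dz) voxel spacing in mm.
    timing_s : acquisition times in seconds (first must be pre-contrast).
    """

    volumes: tuple
    spacing_mm: tuple
    timing_s: tuple

    def __post_init__(self):
        if len(self.volumes) != 4 or len(self.timing_s) != 4:
            raise ValueError("a DCE series must have exactly four timepoints")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError(f"volumes have mismatched shapes: {shapes}")
        if any(s <= 0 for s in self.spacing_mm) or len(self.spacing_mm) != 3:
            raise ValueError("spacing_mm must be three positive lengths")
        if not all(b > a for a, b in zip(self.timing_s, self.timing_s[1:])):
            raise ValueError("timing_s must be strictly increasing")

    @property
    def shape(self):
        return self.volumes[0].shape

    @property
    def s0(self) -> np.ndarray:
        """Pre-contrast volume."""
        return np.asarray(self.volumes[0], dtype=float)

    def _nearest_post(self, target_s: float) -> np.ndarray:
        post_times = self.timing_s[1:]
        idx = int(np.argmin([abs(t - target_s) for t in post_times]))
        return np.asarray(self.volumes[1 + idx], dtype=float)

    @property
    def s1(self) -> np.ndarray:
        """Post-contrast volume acquired nearest 120 s."""
        return self._nearest_post(120.0)

    @property
    def s2(self) -> np.ndarray:
        """Post-contrast volume acquired nearest 480 s."""
        return self._nearest_post(480.0)


@dataclass(frozen=True)
class TumorMask:
    """Binary tumor mask on the same grid as a :class:`DceSeries`."""

    data: np.ndarray
    spacing_mm: tuple

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data).astype(bool))
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.n_voxels < 1:
            raise ValueError("mask must contain at least one foreground voxel")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class KineticMaps:
    """Voxel-wise PE (%) and SER maps (NaN = undefined) plus washout mask."""

    pe_map: np.ndarray
    ser_map: np.ndarray
    washout_mask: np.ndarray


@dataclass
class KineticSummary:
    """Per-lesion semi-quantitative kinetic summary.

    ``peak_ser`` is None (with ``ser_defined`` False) when no voxel
    reaches the 50% PE threshold, i.e. SER is nowhere defined.
    """

    peak_pe_pct: float
    peak_ser: float | None
    ftv_cm3: float
    wf_pct: float
    n_mask_voxels: int
    n_enhancing_voxels: int
    n_washout_voxels: int
    ser_defined: bool = True
    peak_pe_center: tuple | None = None
    peak_ser_center: tuple | None = None

    def as_dict(self) -> dict:
        return {
            "peak_pe_pct": self.peak_pe_pct,
            "peak_ser": self.peak_ser,
            "ftv_cm3": self.ftv_cm3,
            "wf_pct": self.wf_pct,
            "n_mask_voxels": self.n_mask_voxels,
            "n_enhancing_voxels": self.n_enhancing_voxels,
            "n_washout_voxels": self.n_washout_voxels,
            "ser_defined": self.ser_defined,
        }


def _check_aligned(series: DceSeries, mask: TumorMask) -> None:
    if series.shape != mask.data.shape:
        raise ValueError(
            f"series shape {series.shape} != mask shape {mask.data.shape}"
        )


def compute_pe_map(series: DceSeries, mask: TumorMask) -> np.ndarray:
    """Percent enhancement map: 100*(S1-S0)/S0 on in-mask voxels.

    Voxels outside the mask, or with S0 <= 0 (undefined baseline), are
    NaN and are excluded from every downstream count.
    """
    _check_aligned(series, mask)
    s0, s1 = series.s0, series.s1
    pe = np.full(s0.shape, np.nan)
    valid = mask.data & (s0 > 0)
    pe[valid] = 100.0 * (s1[valid] - s0[valid]) / s0[valid]
    return pe


def compute_ser_map(
    series: DceSeries,
    pe_map: np.ndarray,
    pe_threshold: float = PE_THRESHOLD_PCT,
    ser_max: float = SER_MAX,
) -> np.ndarray:
    """Signal enhancement ratio map: (S1-S0)/(S2-S0) where PE >= threshold.

    Where the late enhancement S2-S0 is non-positive (or below a small
    relative epsilon of S0) the contrast has cleared to or below
    baseline — the strongest washout — and SER is clamped to ``ser_max``;
    the same cap bounds near-degenerate denominators so hot-spot window
    means stay finite.
    """
    s0, s1, s2 = series.s0, series.s1, series.s2
    ser = np.full(s0.shape, np.nan)
    eligible = np.isfinite(pe_map) & (pe_map >= pe_threshold)
    num = s1 - s0
    den = s2 - s0
    degen = eligible & (den <= _EPS_REL * s0)
    ok = eligible & ~degen
    ser[ok] = np.minimum(num[ok] / den[ok], ser_max)
    ser[degen] = ser_max
    return ser


def washout_mask(
    pe_map: np.ndarray,
    ser_map: np.ndarray,
    pe_threshold: float = PE_THRESHOLD_PCT,
    ser_threshold: float = SER_WASHOUT_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of washout voxels: PE >= 50% and SER >= 1.1 (inclusive)."""
    with np.errstate(invalid="ignore"):
        return (
            np.isfinite(pe_map)
            & (pe_map >= pe_threshold)
            & np.isfinite(ser_map)
            & (ser_map >= ser_threshold)
        )


def find_hotspot_peak(
    value_map: np.ndarray,
    mask: TumorMask,
    window: tuple = (3, 3, 3),
    min_defined: int = 14,
) -> tuple[float, tuple]:
    """Peak hot-spot mean of a kinetic map.

    Slides a ``window`` (default 3x3x3) over every voxel center in the
    image; the window mean is taken over defined (finite) in-mask voxels
    only, windows extending past the image edge are simply truncated,
    and windows with fewer than ``min_defined`` such voxels are
    ineligible. Returns the maximum mean and its center index; ties are
    broken by the lexicographically smallest (z, y, x) center.
    """
    defined = np.isfinite(value_map) & mask.data
    if not defined.any():
        raise ValueError("value map has no defined in-mask voxel")
    vals = np.where(defined, value_map, 0.0)
    kernel = np.ones(window)
    sums = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(defined.astype(float), kernel, mode="constant", cval=0.0)
    counts = np.rint(counts)
    eligible = counts >= min_defined
    if not eligible.any():
        raise ValueError(
            f"no {window} window holds >= {min_defined} defined in-mask voxels; "
            "lesion too small for hot-spot analysis"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(eligible, sums / counts, -np.inf)
    peak = float(means.max())
    # ties: smallest (z, y, x); arrays are indexed (x, y, z)
    cands = np.argwhere(means == peak)
    order = np.lexsort((cands[:, 0], cands[:, 1], cands[:, 2]))
    center = tuple(int(c) for c in cands[order[0]])
    return peak, center


def compute_ftv(
    pe_map: np.ndarray,
    mask: TumorMask,
    spacing_mm: Sequence[float] | None = None,
    pe_threshold: float = PE_THRESHOLD_PCT,
) -> float:
    """Functional tumor volume in cm^3: volume of in-mask voxels with PE >= 50%."""
    spacing = tuple(spacing_mm) if spacing_mm is not None else tuple(mask.spacing_mm)
    with np.errstate(invalid="ignore"):
        n = int((np.isfinite(pe_map) & mask.data & (pe_map >= pe_threshold)).sum())
    voxel_mm3 = float(np.prod(spacing))
    return n * voxel_mm3 / 1000.0


def compute_washout_fraction(
    pe_map: np.ndarray,
    ser_map: np.ndarray,
    mask: TumorMask,
    pe_threshold: float = PE_THRESHOLD_PCT,
    ser_threshold: float = SER_WASHOUT_THRESHOLD,
) -> float:
    """Washout fraction (%): washout voxels over all defined tumor voxels.

    The denominator is every in-mask voxel with a defined PE (all tumor
    voxels), not only the enhancing subset.
    """
    defined = np.isfinite(pe_map) & mask.data
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("no defined in-mask voxels")
    n_wash = int(washout_mask(pe_map, ser_map, pe_threshold, ser_threshold).sum())
    return 100.0 * n_wash / n_def


def compute_maps(
    series: DceSeries,
    mask: TumorMask,
    pe_threshold: float = PE_THRESHOLD_PCT,
    ser_threshold: float = SER_WASHOUT_THRESHOLD,
) -> KineticMaps:
    """PE map, SER map and washout mask in one call."""
    pe = compute_pe_map(series, mask)
    ser = compute_ser_map(series, pe, pe_threshold)
    return KineticMaps(pe, ser, washout_mask(pe, ser, pe_threshold, ser_threshold))


def summarize_lesion(
    series: DceSeries,
    mask: TumorMask,
    pe_threshold: float = PE_THRESHOLD_PCT,
    ser_threshold: float = SER_WASHOUT_THRESHOLD,
    window: tuple = (3, 3, 3),
) -> KineticSummary:
    """Compute the four per-lesion summaries: peak PE, peak SER, FTV, WF."""
    maps = compute_maps(series, mask, pe_threshold, ser_threshold)
    peak_pe, pe_center = find_hotspot_peak(maps.pe_map, mask, window)
    enhancing = np.isfinite(maps.pe_map) & (maps.pe_map >= pe_threshold)
    if np.isfinite(maps.ser_map).any():
        peak_ser, ser_center = find_hotspot_peak(maps.ser_map, mask, window)
        ser_defined = True
    else:
        peak_ser, ser_center, ser_defined = None, None, False
    return KineticSummary(
        peak_pe_pct=peak_pe,
        peak_ser=peak_ser,
        ftv_cm3=compute_ftv(maps.pe_map, mask, pe_threshold=pe_threshold),
        wf_pct=compute_washout_fraction(
            maps.pe_map, maps.ser_map, mask, pe_threshold, ser_threshold
        ),
        n_mask_voxels=int((np.isfinite(maps.pe_map) & mask.data).sum()),
        n_enhancing_voxels=int(enhancing.sum()),
        n_washout_voxels=int(maps.washout_mask.sum()),
        ser_defined=ser_defined,
        peak_pe_center=pe_center,
        peak_ser_center=ser_center,
    )


def grow_enhancing_roi(
    pe_map: np.ndarray,
    seed_index: tuple,
    spacing_mm: Sequence[float],
    pe_threshold: float = PE_THRESHOLD_PCT,
) -> TumorMask:
    """26-connected region of PE >= threshold voxels containing the seed.

    A simple enhancing-voxel region grower; a stand-in segmentation
    convenience, not an expert tumor delineation.
    """
    seed_index = tuple(int(i) for i in seed_index)
    with np.errstate(invalid="ignore"):
        enhancing = np.isfinite(pe_map) & (pe_map >= pe_threshold)
    if not enhancing[seed_index]:
        raise ValueError(f"seed voxel {seed_index} has PE below {pe_threshold}%")
    labels, _ = ndimage.label(enhancing, structure=np.ones((3, 3, 3), dtype=int))
    region = labels == labels[seed_index]
    return TumorMask(region, tuple(spacing_mm))


# ---------------------------------------------------------------------------
# NIfTI I/O helpers


def _affine(spacing_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_series(series: DceSeries, path: str | Path) -> Path:
    """Write a series as a single 4D NIfTI (time on the 4th axis)."""
    path = Path(path)
    data = np.stack([np.asarray(v, dtype=np.float32) for v in series.volumes], axis=-1)
    img = nib.Nifti1Image(data, _affine(series.spacing_mm))
    img.header.set_zooms(tuple(series.spacing_mm) + (1.0,))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    with open(str(sidecar) + ".timing.json", "w") as fh:
        json.dump({"timing_s": list(series.timing_s)}, fh)
    return path


def load_series(path: str | Path, timing_s: Sequence[float] | None = None) -> DceSeries:
    """Read a 4D NIfTI series; timing from argument or the .timing.json sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 4:
        raise ValueError("expected a 4D NIfTI with four timepoints")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if timing_s is None:
        sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".timing.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                timing_s = json.load(fh)["timing_s"]
        else:
            timing_s = (0.0, 120.0, 300.0, 480.0)
    vols = tuple(data[..., t] for t in range(4))
    return DceSeries(vols, spacing, tuple(float(t) for t in timing_s))


def save_mask(mask: TumorMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing_mm))
    img.header.set_zooms(tuple(mask.spacing_mm))
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> TumorMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TumorMask(np.asarray(img.dataobj) > 0, spacing)


def save_map(arr: np.ndarray, spacing_mm: Sequence[float], path: str | Path) -> Path:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(spacing_mm))
    img.header.set_zooms(tuple(spacing_mm))
    nib.save(img, str(path))
    return Path(path)
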