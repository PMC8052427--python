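"""Synthetic DCE-MRI phantom lesions and cohorts with known ground truth.

Each lesion is an ellipsoidal region embedded in a homogeneous
background, its voxels partitioned into three kinetic classes —
washout, plateau and persistent — arranged as concentric shells
(washout innermost). Signals at the four timepoints are synthesized so
that, noise-free, each class hits its designed (PE, SER) targets
exactly:

    S0 = baseline
    S1 = S0 * (1 + PE/100)
    S2 = S0 + (S1 - S0) / SER
    S_mid = linear interpolation of S1..S2 at the middle timepoint

Cohorts couple per-lesion microvessel-density (MVD) reader counts to
the designed washout fraction through a negative-binomial count model,
so that association analyses can be validated against a known design.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import DceSeries, TumorMask

CLASS_NAMES = ("washout", "plateau", "persistent")
# background=0, washout=1, plateau=2, persistent=3
DEFAULT_CLASS_KINETICS = ((220.0, 1.9), (160.0, 1.0), (110.0, 0.65))


@dataclass(frozen=True)
class PhantomSpec:
    """Design of a single synthetic lesion.

    class_fractions are the (washout, plateau, persistent) voxel
    proportions; class_kinetics the per-class (PE_mean %, SER_mean)
    targets. Timing defaults follow a standard clinical protocol with
    post-contrast volumes centered near 120, 300 and 480 s, on a
    0.5 x 0.5 x 1.3 mm grid.
    """

    grid_shape: tuple = (48, 48, 20)
    spacing_mm: tuple = (0.5, 0.5, 1.3)
    timing_s: tuple = (0.0, 120.0, 300.0, 480.0)
    lesion_radius_mm: float = 6.0
    class_fractions: tuple = (0.4, 0.35, 0.25)
    class_kinetics: tuple = DEFAULT_CLASS_KINETICS
    noise_sd: float = 0.0
    baseline_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be nonnegative")
        if not all(b > a for a, b in zip(self.timing_s, self.timing_s[1:])):
            raise ValueError("timing_s must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion_radius_mm must be positive")
        for pe, ser in self.class_kinetics:
            if pe < 0:
                raise ValueError(f"class PE target must be >= 0, got {pe}")
            if ser <= 0:
                raise ValueError(f"class SER target must be > 0, got {ser}")


@dataclass
class PhantomGroundTruth:
    """Designed truth for one lesion (recovery-test oracle)."""

    class_map: np.ndarray  # 0 background, 1..3 kinetic class
    true_wf_pct: float
    true_peak_pe_pct: float
    true_peak_ser: float
    true_ftv_cm3: float
    class_counts: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.true_wf_pct <= 100.0:
            raise ValueError("true_wf_pct must be in [0, 100]")


@dataclass(frozen=True)
class CohortDesign:
    """Design of a phantom cohort with MVD coupled to washout burden.

    Half the lesions are drawn around each group washout-fraction (WF)
    median; expected MVD is ``intercept + slope * true_wf`` with
    negative-binomial dispersion, and each of two readers observes the
    lesion count plus independent Gaussian reading noise.

    Default group medians (22.5 and 50.6 %) follow the low/high-MVD
    contrast reported for invasive breast cancers; the default count
    model keeps counts inside the commonly reported 8-56 range with
    median near 17.
    """

    n_lesions: int = 27
    group_wf_medians_pct: tuple = (22.5, 50.6)
    wf_spread: float = 8.0
    mvd_model: tuple = (5.0, 0.4, 10.0)  # (intercept, slope, NB dispersion k)
    reader_noise_sd: float = 2.0
    seed: int = 0
    # lesion-level geometry kept small so cohort simulation stays cheap;
    # radius varies per lesion so size-driven measures (FTV) have spread
    grid_shape: tuple = (24, 24, 16)
    spacing_mm: tuple = (0.5, 0.5, 1.3)
    lesion_radius_range_mm: tuple = (3.0, 5.0)
    noise_sd: float = 2.0
    baseline_intensity: float = 100.0

    def __post_init__(self):
        if self.n_lesions < 4:
            raise ValueError("n_lesions must be >= 4")
        for m in self.group_wf_medians_pct:
            if not 0.0 <= m <= 100.0:
                raise ValueError("group WF medians must be in [0, 100]")
        if self.reader_noise_sd < 0:
            raise ValueError("reader_noise_sd must be nonnegative")


def _lesion_mask_and_classes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoid mask plus per-voxel class labels as concentric shells."""
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    center = (np.asarray(shape) - 1) / 2.0
    coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    )
    phys = (coords - center) * spacing  # mm from lesion center
    r2 = (phys**2).sum(axis=-1)
    half_extent = (np.asarray(shape) * spacing) / 2.0
    if spec.lesion_radius_mm >= half_extent.min():
        raise ValueError(
            f"lesion radius {spec.lesion_radius_mm} mm does not fit in the "
            f"grid (half extents {tuple(half_extent)} mm)"
        )
    mask = r2 <= spec.lesion_radius_mm**2
    n = int(mask.sum())
    if n == 0:
        raise ValueError("lesion radius smaller than a voxel")

    # exact class counts: round washout & plateau, remainder persistent
    n_wash = int(round(spec.class_fractions[0] * n))
    n_plat = int(round(spec.class_fractions[1] * n))
    n_plat = min(n_plat, n - n_wash)
    counts = (n_wash, n_plat, n - n_wash - n_plat)

    # order in-mask voxels by radius (stable, lexicographic tie-break)
    idx = np.argwhere(mask)
    radii = r2[mask]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], radii))
    class_map = np.zeros(shape, dtype=np.uint8)
    labels = np.empty(n, dtype=np.uint8)
    labels[: counts[0]] = 1
    labels[counts[0] : counts[0] + counts[1]] = 2
    labels[counts[0] + counts[1] :] = 3
    sorted_idx = idx[order]
    class_map[tuple(sorted_idx.T)] = labels
    return mask, class_map


def generate_lesion(
    spec: PhantomSpec,
) -> tuple[DceSeries, TumorMask, PhantomGroundTruth]:
    """Synthesize one seeded lesion; identical spec+seed is bit-identical."""
    rng = np.random.default_rng(spec.seed)
    mask, class_map = _lesion_mask_and_classes(spec)
    b = spec.baseline_intensity

    s0 = np.full(spec.grid_shape, b)
    s1 = s0.copy()
    s2 = s0.copy()
    for k, (pe, ser) in enumerate(spec.class_kinetics, start=1):
        sel = class_map == k
        s1[sel] = b * (1.0 + pe / 100.0)
        s2[sel] = b + (s1[sel] - b) / ser
    t0, t1, t2, t3 = spec.timing_s
    frac = (t2 - t1) / (t3 - t1)
    s_mid = s1 + (s2 - s1) * frac

    vols = []
    for v in (s0, s1, s_mid, s2):
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
        vols.append(v)
    series = DceSeries(tuple(vols), spec.spacing_mm, spec.timing_s)
    tumor = TumorMask(mask, spec.spacing_mm)

    counts = tuple(int((class_map == k).sum()) for k in (1, 2, 3))
    n = sum(counts)
    present = [
        (pe, ser) for c, (pe, ser) in zip(counts, spec.class_kinetics) if c > 0
    ]
    voxel_cm3 = float(np.prod(spec.spacing_mm)) / 1000.0
    n_enh = sum(
        c for c, (pe, _) in zip(counts, spec.class_kinetics) if c > 0 and pe >= 50.0
    )
    truth = PhantomGroundTruth(
        class_map=class_map,
        true_wf_pct=100.0 * counts[0] / n,
        true_peak_pe_pct=max(pe for pe, _ in present),
        true_peak_ser=max(ser for _, ser in present),
        true_ftv_cm3=n_enh * voxel_cm3,
        class_counts=counts,
    )
    return series, tumor, truth


# ---------------------------------------------------------------------------
# cohort generation


def _sample_design_level(design: CohortDesign, rng: np.random.Generator):
    """Draw (group, true-ish WF targets, reader counts) without images.

    Used both by :func:`generate_cohort` (which then builds the image
    for each lesion) and by design-level Monte-Carlo calibrations.
    """
    n = design.n_lesions
    n_low = (n + 1) // 2
    groups = np.array(["low"] * n_low + ["high"] * (n - n_low))
    medians = np.where(
        groups == "low",
        design.group_wf_medians_pct[0],
        design.group_wf_medians_pct[1],
    )
    wf = np.clip(rng.normal(medians, design.wf_spread), 1.0, 97.0)
    intercept, slope, k = design.mvd_model
    mean = intercept + slope * wf
    if (mean < 0).any():
        warnings.warn("mvd_model produced negative expected counts; clipping at 0")
        mean = np.clip(mean, 0.0, None)
    # negative binomial with mean m, dispersion k: p = k/(k+m)
    base = np.where(
        mean > 0, rng.negative_binomial(k, k / (k + np.maximum(mean, 1e-12))), 0
    )
    readers = []
    for _ in range(2):
        if design.reader_noise_sd > 0:
            obs = np.rint(base + rng.normal(0, design.reader_noise_sd, size=n))
        else:
            obs = base.astype(float)
        readers.append(np.clip(obs, 0, None).astype(int))
    return groups, wf, base.astype(int), readers[0], readers[1]


def generate_cohort(design: CohortDesign) -> list[dict]:
    """Generate a seeded phantom cohort.

    Returns one dict per lesion with keys ``lesion_id``, ``series``,
    ``mask``, ``truth``, ``reader1_count``, ``reader2_count``, ``group``.
    All randomness flows from ``design.seed`` via spawned substreams,
    so per-lesion content does not depend on iteration order.
    """
    master = np.random.SeedSequence(design.seed)
    design_ss, *lesion_ss = master.spawn(design.n_lesions + 1)
    rng = np.random.default_rng(design_ss)
    groups, wf_targets, _, r1, r2 = _sample_design_level(design, rng)

    lo_r, hi_r = design.lesion_radius_range_mm
    radii = rng.uniform(lo_r, hi_r, size=design.n_lesions)

    cohort = []
    for i in range(design.n_lesions):
        w = wf_targets[i] / 100.0
        rest = 1.0 - w
        spec = PhantomSpec(
            grid_shape=design.grid_shape,
            spacing_mm=design.spacing_mm,
            lesion_radius_mm=float(radii[i]),
            class_fractions=(w, rest / 2.0, rest - rest / 2.0),
            noise_sd=design.noise_sd,
            baseline_intensity=design.baseline_intensity,
            seed=int(lesion_ss[i].generate_state(1)[0] % (2**31)),
        )
        series, mask, truth = generate_lesion(spec)
        cohort.append(
            {
                "lesion_id": f"lesion_{i:03d}",
                "series": series,
                "mask": mask,
                "truth": truth,
                "reader1_count": int(r1[i]),
                "reader2_count": int(r2[i]),
                "group": str(groups[i]),
            }
        )
    return cohort


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(bundle, directory: str | Path) -> dict:
    """Write a lesion or cohort bundle as NIfTI + CSV/JSON files.

    ``bundle`` is either the (series, mask, truth) triple from
    :func:`generate_lesion` or the list from :func:`generate_cohort`.
    Returns a dict of written paths.
    """
    from . import kinetics as kin

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _write_lesion(series, mask, truth, stem):
        paths = {}
        paths["series"] = kin.save_series(series, directory / f"{stem}_series.nii")
        paths["mask"] = kin.save_mask(mask, directory / f"{stem}_mask.nii")
        gt = {
            "true_wf_pct": truth.true_wf_pct,
            "true_peak_pe_pct": truth.true_peak_pe_pct,
            "true_peak_ser": truth.true_peak_ser,
            "true_ftv_cm3": truth.true_ftv_cm3,
            "class_counts": list(truth.class_counts),
        }
        p = directory / f"{stem}_truth.json"
        with open(p, "w") as fh:
            json.dump(gt, fh, indent=1)
        paths["truth"] = p
        return paths

    if isinstance(bundle, tuple) and len(bundle) == 3:
        return _write_lesion(*bundle, "lesion")

    paths: dict = {"lesions": []}
    rows = []
    for rec in bundle:
        stem = rec["lesion_id"]
        paths["lesions"].append(
            _write_lesion(rec["series"], rec["mask"], rec["truth"], stem)
        )
        rows.append(
            {
                "lesion_id": stem,
                "reader1_count": rec["reader1_count"],
                "reader2_count": rec["reader2_count"],
                "true_wf_pct": rec["truth"].true_wf_pct,
                "group": rec["group"],
            }
        )
    cohort_csv = directory / "cohort.csv"
    with open(cohort_csv, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    paths["cohort_csv"] = cohort_csv
    return paths
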