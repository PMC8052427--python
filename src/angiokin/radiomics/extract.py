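"""Full 108-feature extraction for one tumor volume."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import all_feature_names, catalog_version, family_names, load_catalog
from .features import features_from_family
from .firstorder import firstorder_features
from .matrices import build_matrix
from .preprocess import discretize, preprocess
from .shape import shape_features


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction settings; recorded alongside every feature vector."""

    bin_width: float = 0.25  # in z-score units
    target_spacing_mm: float = 1.0
    distance: int = 1

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be positive")


@dataclass
class FeatureVector:
    """Ordered map of the 108 qualified feature names to values."""

    values: dict
    catalog_version: str = field(default_factory=catalog_version)

    def __post_init__(self):
        expected = all_feature_names()
        if tuple(self.values.keys()) != expected:
            missing = set(expected) - set(self.values)
            extra = set(self.values) - set(expected)
            raise ValueError(
                f"feature vector does not match the catalog "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict:
        return dict(self.values)


def extract_all(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing_mm,
    config: RadiomicsConfig | None = None,
) -> FeatureVector:
    """Compute the full catalog on the masked volume.

    Pipeline: whole-volume z-score normalization -> isotropic
    resampling -> fixed-bin-width discretization -> shape, first-order
    and the five gray-level matrix families. Deterministic for fixed
    input and config.
    """
    cfg = config or RadiomicsConfig()
    pv = preprocess(volume, mask, spacing_mm, cfg.target_spacing_mm)
    dv = discretize(pv, cfg.bin_width)
    spacing_iso = (cfg.target_spacing_mm,) * 3

    by_family = {
        "shape": shape_features(pv.mask, spacing_iso),
        "firstorder": firstorder_features(pv, dv),
    }
    for fam in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
        glm = build_matrix(dv, fam, distance=cfg.distance)
        by_family[fam] = features_from_family(glm)

    values = {}
    for family in load_catalog()["families"]:
        feats = by_family[family]
        for name in family_names(family):
            values[f"{family}_{name}"] = float(feats[name])
    return FeatureVector(values)
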