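"""First-order intensity statistics over the masked, preprocessed volume."""

from __future__ import annotations

import numpy as np

from .catalog import family_names
from .preprocess import DiscretizedVolume, PreprocessedVolume

EPS = 1e-16


def firstorder_features(
    pv: PreprocessedVolume, dv: DiscretizedVolume | None = None
) -> dict:
    """The 19 first-order statistics on in-mask intensities.

    Variance and its derivatives use the population (divide-by-N)
    convention; Kurtosis is non-excess (a normal distribution scores
    3). Entropy and Uniformity are computed on the discretized
    gray-level histogram (``dv``; required).
    """
    if dv is None:
        raise ValueError("firstorder Entropy/Uniformity need a DiscretizedVolume")
    x = pv.image[pv.mask].astype(float)
    n = x.size
    if n == 0:
        raise ValueError("empty mask")
    mean = float(x.mean())
    var = float(x.var())  # population
    sd = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    voxel_volume = float(pv.target_spacing_mm**3)

    levels = dv.levels[dv.mask]
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n

    f: dict[str, float] = {}
    f["Energy"] = float((x**2).sum())
    f["TotalEnergy"] = voxel_volume * f["Energy"]
    f["Entropy"] = float(-(p * np.log2(p + EPS)).sum())
    f["Minimum"] = float(x.min())
    f["10Percentile"] = float(p10)
    f["90Percentile"] = float(p90)
    f["Maximum"] = float(x.max())
    f["Mean"] = mean
    f["Median"] = float(p50)
    f["InterquartileRange"] = float(p75 - p25)
    f["Range"] = float(x.max() - x.min())
    f["MeanAbsoluteDeviation"] = float(np.abs(x - mean).mean())
    robust = x[(x >= p10) & (x <= p90)]
    f["RobustMeanAbsoluteDeviation"] = (
        float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    )
    f["RootMeanSquared"] = float(np.sqrt((x**2).mean()))
    f["StandardDeviation"] = sd
    if sd > EPS:
        f["Skewness"] = float(((x - mean) ** 3).mean() / sd**3)
        f["Kurtosis"] = float(((x - mean) ** 4).mean() / var**2)
    else:
        f["Skewness"] = 0.0
        f["Kurtosis"] = 0.0
    f["Variance"] = var
    f["Uniformity"] = float((p**2).sum())

    assert set(f) == set(family_names("firstorder"))
    return f
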