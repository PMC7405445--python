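"""First-order intensity statistics (19 features).

Definitions follow the standard radiomics reference set.  Energy and total
energy use raw (unshifted) intensities; entropy and uniformity are computed
on the discretized histogram; skewness and kurtosis use population moments
(kurtosis is the Pearson form, 3 for a normal distribution).
"""

from __future__ import annotations

import numpy as np

from ..core import RegionError, VolumeGrid
from .discretize import DiscretizationSpec, discretize

FIRSTORDER_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile_10",
    "percentile_90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)


def firstorder_features(
    image: VolumeGrid,
    mask: np.ndarray,
    spec: DiscretizationSpec | None = None,
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("first-order features need a non-empty region")
    spec = spec or DiscretizationSpec()
    v = image.data[mask].astype(np.float64)
    n = v.size
    mean = v.mean()
    var = v.var()  # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]

    levels, _ = discretize(image, mask, spec)
    counts = np.bincount(levels[mask])[1:]
    p = counts[counts > 0] / n

    if var > 0:
        m3 = ((v - mean) ** 3).mean()
        m4 = ((v - mean) ** 4).mean()
        skew = m3 / sd**3
        kurt = m4 / var**2
    else:
        skew, kurt = 0.0, 0.0

    return {
        "energy": float((v**2).sum()),
        "total_energy": float((v**2).sum() * image.voxel_volume),
        "entropy": float(-(p * np.log2(p)).sum()),
        "minimum": float(v.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "maximum": float(v.max()),
        "mean": float(mean),
        "median": float(p50),
        "interquartile_range": float(p75 - p25),
        "range": float(v.max() - v.min()),
        "mean_absolute_deviation": float(np.abs(v - mean).mean()),
        "robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "root_mean_squared": float(np.sqrt((v**2).mean())),
        "standard_deviation": float(sd),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "variance": float(var),
        "uniformity": float((p**2).sum()),
    }
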