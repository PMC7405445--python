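"""The eight analysis regions and region geometry utilities.

The four base tumour compartments (contrast-enhancement ``cet``,
non-enhancing tumour ``net``, necrosis ``nec``, edema ``ed``) are combined
into eight single and combined labels:

======== ======================================
wt       whole tumour, cet U net U nec U ed
core     wt without edema
net_ncr  net U nec
net_ed   net U ed
======== ======================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GeometryError, LabelMap, REGION_NAMES


@dataclass
class RegionSet:
    """Eight named binary masks sharing one grid."""

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if set(self.masks) != set(REGION_NAMES):
            raise GeometryError(f"RegionSet needs exactly the regions {REGION_NAMES}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def empty_regions(self) -> list[str]:
        return [n for n in REGION_NAMES if not self.masks[n].any()]


def combine_labels(labels: LabelMap) -> RegionSet:
    """Derive the eight analysis regions from the four base labels.

    Empty masks are allowed but reported with a warning so that downstream
    feature extraction can record missing values.
    """
    base = {name: labels.mask(name) for name in ("cet", "net", "nec", "ed")}
    masks = dict(base)
    masks["wt"] = base["cet"] | base["net"] | base["nec"] | base["ed"]
    masks["core"] = masks["wt"] & ~base["ed"]
    masks["net_ncr"] = base["net"] | base["nec"]
    masks["net_ed"] = base["net"] | base["ed"]
    rs = RegionSet(masks, labels.spacing)
    empty = rs.empty_regions()
    if empty:
        warnings.warn(f"empty regions: {empty}", stacklevel=2)
    return rs


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a n b| / (|a| + |b|).

    Both masks empty is defined as perfect agreement (1.0, with a warning):
    perturbing an absent label should not register as disagreement.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def centroid_features(
    regions: RegionSet, brain_mask: np.ndarray
) -> dict[str, float]:
    """Normalized centroid offset of each region from the brain-frame centre.

    For each of the eight regions: the Euclidean distance (mm) between the
    region's binary-mask centroid and the centre of the brain-mask bounding
    box, divided by the half-diagonal of that box.  This scalarizes tumour
    location into one value per region (0 at the brain centre, 1 at a
    bounding-box corner) in a deterministic normalized brain frame, standing
    in for atlas registration.  Empty regions yield NaN.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise GeometryError("brain mask is empty")
    spacing = np.asarray(regions.spacing)
    idx = np.argwhere(brain_mask)
    lo = idx.min(axis=0) * spacing
    hi = idx.max(axis=0) * spacing
    center = (lo + hi) / 2.0
    half_diag = float(np.linalg.norm((hi - lo) / 2.0))
    out: dict[str, float] = {}
    for name in REGION_NAMES:
        m = regions[name]
        if not m.any() or half_diag == 0:
            out[name] = float("nan")
            continue
        c = np.argwhere(m).mean(axis=0) * spacing
        out[name] = float(np.linalg.norm(c - center) / half_diag)
    return out
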