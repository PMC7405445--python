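"""Gray-value quantization for histogram-based feature families."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import RegionError, VolumeGrid


@dataclass(frozen=True)
class DiscretizationSpec:
    """How to bin gray values before building texture matrices.

    ``fixed_bin_count`` divides the masked intensity range into ``n_bins``
    equal bins (the count must lie in the 30-130 range the binning
    perturbation sweeps); ``fixed_bin_width`` uses absolute bins of
    ``bin_width`` intensity units anchored at zero.
    """

    mode: str = "fixed_bin_count"
    n_bins: int = 80
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and not (30 <= self.n_bins <= 130):
            raise ValueError(f"n_bins must lie in [30, 130], got {self.n_bins}")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def discretize(
    image: VolumeGrid, mask: np.ndarray, spec: DiscretizationSpec
) -> tuple[np.ndarray, int]:
    """Quantize masked voxels to integer levels 1..G (0 outside the mask).

    Returns ``(levels, G)``.  A constant region maps to a single level.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("cannot discretize an empty region")
    vals = image.data[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        return levels, 1
    if spec.mode == "fixed_bin_count":
        width = (hi - lo) / spec.n_bins
        lv = np.floor((vals - lo) / width).astype(np.int32) + 1
        np.clip(lv, 1, spec.n_bins, out=lv)
        g = int(lv.max())
    else:
        lv = (
            np.floor(vals / spec.bin_width) - np.floor(lo / spec.bin_width)
        ).astype(np.int32) + 1
        g = int(lv.max())
    levels[mask] = lv
    return levels, g
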