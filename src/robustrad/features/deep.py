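"""Pluggable deep-feature extractor with a seeded random-weight stand-in.

The interface mirrors CNN transfer-learning feature extraction: the image is
cropped to the mask bounding box, resized to a fixed input grid, passed
through a small convolutional trunk and two fully-connected layers, and the
activations of both FC layers are concatenated (output widths summing to
8192).  The default network draws its weights from a seeded generator and is
deliberately NOT pretrained; it exists so that the high-dimensional sparse
feature plumbing (robustness screening, sparsity filtering) can be exercised
end to end.  Outputs are deterministic given (image, mask, weights_seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from ..core import VolumeGrid

_INPUT_SHAPE = (12, 12, 12)
_N_CHANNELS = 4
_POOL = 2
_HIDDEN = 256


@dataclass(frozen=True)
class DeepExtractorSpec:
    """Two FC output widths (must sum to 8192) and the weight seed."""

    layer_sizes: tuple[int, int] = (4096, 4096)
    weights_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.layer_sizes) != 8192:
            raise ValueError(
                f"layer sizes must sum to 8192, got {self.layer_sizes}"
            )


@lru_cache(maxsize=4)
def _weights(spec: DeepExtractorSpec):
    rng = np.random.default_rng(spec.weights_seed)
    conv = rng.normal(0, 1.0 / np.sqrt(27), size=(_N_CHANNELS, 3, 3, 3)).astype(np.float32)
    pooled = tuple(s // _POOL for s in _INPUT_SHAPE)
    flat = int(np.prod(pooled)) * _N_CHANNELS
    w_h = rng.normal(0, 1.0 / np.sqrt(flat), size=(flat, _HIDDEN)).astype(np.float32)
    w1 = rng.normal(0, 1.0 / np.sqrt(_HIDDEN), size=(_HIDDEN, spec.layer_sizes[0])).astype(np.float32)
    w2 = rng.normal(
        0, 1.0 / np.sqrt(spec.layer_sizes[0]),
        size=(spec.layer_sizes[0], spec.layer_sizes[1]),
    ).astype(np.float32)
    return conv, w_h, w1, w2


def deep_features(
    image: VolumeGrid, mask: np.ndarray, extractor: DeepExtractorSpec
) -> np.ndarray:
    """8192 deterministic stand-in deep features of the masked region."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(8192, np.nan)
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    crop = image.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float32)
    rng_span = float(crop.max() - crop.min())
    if rng_span > 0:
        crop = (crop - crop.min()) / rng_span
    zoom = [t / s for t, s in zip(_INPUT_SHAPE, crop.shape)]
    x = ndimage.zoom(crop, zoom, order=1, mode="nearest", grid_mode=False)
    x = np.resize(x, _INPUT_SHAPE)  # guard off-by-one from zoom rounding

    conv, w_h, w1, w2 = _weights(extractor)
    maps = [np.maximum(ndimage.convolve(x, k, mode="constant"), 0.0) for k in conv]
    pooled = np.stack(
        [m.reshape(6, _POOL, 6, _POOL, 6, _POOL).max(axis=(1, 3, 5)) for m in maps]
    )
    h = np.maximum(pooled.ravel() @ w_h, 0.0)
    fc1 = np.maximum(h @ w1, 0.0)
    fc2 = np.maximum(fc1 @ w2, 0.0)
    return np.concatenate([fc1, fc2]).astype(np.float64)
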