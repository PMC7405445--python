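"""Simulated multi-centre perturbations.

Six families, each seeded and parameterized, applied one-factor-at-a-time:

============= ====================================== ===================
noise         additive Gaussian, sigma calibrated     10 levels/sequence
binning       gray-level bin count 30..130            54 levels/sequence
interrater    elastic label deformation to a Dice     10 levels/region
voxelsize     isotropic 1..1.5 mm acquisition         10 levels/sequence
slicespacing  axial 1..4 mm (T2/FLAIR), 1..1.5 (T1*)  10 levels/sequence
kspace        random frequency-domain mask 0.80..1.00 21 levels/sequence
============= ====================================== ===================

Resampling perturbations simulate a coarse acquisition and then return to
the original analysis grid, so feature-extraction geometry never changes.
Noise levels are calibrated against the cohort's white-matter SNR; the
inter-rater deformation amplitude is calibrated by bisection to hit a
target Dice overlap.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    CalibrationError,
    FeatureTable,
    LabelMap,
    MRIStudy,
    REGION_NAMES,
    RegionError,
    SEQUENCES,
    VolumeGrid,
)
from .features import DiscretizationSpec, ExtractionConfig, extract_feature_table
from .regions import combine_labels, dice

SLICE_RANGES = {"T1": (1.0, 1.5), "T1c": (1.0, 1.5), "T2": (1.0, 4.0), "FLAIR": (1.0, 4.0)}

FAMILIES = ("noise", "binning", "interrater", "voxelsize", "slicespacing", "kspace")


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation instance: family, parameter value, seed, scope."""

    family: str
    value: float
    seed: int
    applies_to: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown perturbation family {self.family!r}")
        v = self.value
        if self.family == "kspace" and not (0.8 <= v <= 1.0):
            raise ValueError(f"k-space kept fraction must lie in [0.8, 1.0], got {v}")
        if self.family == "voxelsize" and not (1.0 <= v <= 1.5):
            raise ValueError(f"voxel size must lie in [1, 1.5] mm, got {v}")
        if self.family == "binning" and not (30 <= v <= 130):
            raise ValueError(f"bin count must lie in [30, 130], got {v}")
        if self.family == "interrater" and not (0.0 < v <= 1.0):
            raise ValueError(f"Dice target must lie in (0, 1], got {v}")
        if self.family == "slicespacing":
            for seq in self.applies_to:
                lo, hi = SLICE_RANGES[seq]
                if not (lo <= v <= hi):
                    raise ValueError(
                        f"slice spacing {v} mm outside the {seq} range [{lo}, {hi}] mm"
                    )


@dataclass
class PlanConfig:
    """Per-family level counts (Table-style defaults) and parameter ranges."""

    n_noise: int = 10
    n_binning: int = 54
    n_interrater: int = 10
    n_voxelsize: int = 10
    n_slicespacing: int = 10
    n_kspace: int = 21
    bin_range: tuple[int, int] = (30, 130)
    voxel_range: tuple[float, float] = (1.0, 1.5)
    kspace_range: tuple[float, float] = (0.8, 1.0)
    dice_range: tuple[float, float] = (0.85, 0.94)
    noise_sigma_max: float = 10.0  # fallback when no calibration is supplied
    sequences: tuple[str, ...] = SEQUENCES
    regions: tuple[str, ...] = REGION_NAMES
    base_seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_noise, self.n_binning, self.n_interrater,
                  self.n_voxelsize, self.n_slicespacing, self.n_kspace):
            if n < 1:
                raise ValueError("per-family level counts must be >= 1")


@dataclass
class PerturbationPlan:
    specs: list[PerturbationSpec]

    def by_family(self) -> dict[str, list[PerturbationSpec]]:
        out: dict[str, list[PerturbationSpec]] = {}
        for s in self.specs:
            out.setdefault(s.family, []).append(s)
        return out

    def counts_per_scope(self) -> dict[str, int]:
        """Number of levels per sequence (or per region for interrater)."""
        fam = self.by_family()
        out = {}
        for family, specs in fam.items():
            scopes = {s.applies_to for s in specs}
            out[family] = len(specs) // max(len(scopes), 1)
        return out


# --------------------------------------------------------------------------
# SNR and noise
# --------------------------------------------------------------------------

def measure_snr(image: VolumeGrid, wm_mask: np.ndarray) -> float:
    """mean/sd over the white-matter mask; NaN (flagged) when sd is zero."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise RegionError("SNR needs a non-empty white-matter mask")
    vals = image.data[wm_mask]
    sd = vals.std()
    if sd == 0:
        warnings.warn("zero variance in WM region: SNR undefined", stacklevel=2)
        return float("nan")
    return float(vals.mean() / sd)


def apply_noise(image: VolumeGrid, sigma: float, seed: int) -> VolumeGrid:
    """Additive Gaussian noise; negative voxels are clipped at zero."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    out = image.data + rng.normal(0.0, sigma, size=image.shape)
    if (out < 0).any():
        warnings.warn("noise produced negative intensities; clipped at 0", stacklevel=2)
        out = np.clip(out, 0.0, None)
    return VolumeGrid(out, image.spacing)


def calibrate_noise_levels(
    cohort: list[MRIStudy],
    n_levels: int,
    sequences: tuple[str, ...] = SEQUENCES,
    n_iter: int = 40,
) -> dict[str, list[float]]:
    """Per sequence: ``n_levels`` strictly increasing sigmas up to the
    largest sigma keeping the cohort-mean post-noise WM SNR at or above
    (mean SNR - 1 SD) of the unperturbed cohort.  Found by bisection with
    re-measurement."""
    out: dict[str, list[float]] = {}
    for seq in sequences:
        snrs = []
        for st in cohort:
            s = measure_snr(st.sequences[seq], st.wm_mask)
            if np.isfinite(s):
                snrs.append(s)
        if not snrs:
            raise CalibrationError(f"SNR undefined on every case for {seq}")
        snrs = np.asarray(snrs)
        bound = float(snrs.mean() - snrs.std())

        def mean_snr(sigma: float) -> float:
            vals = []
            for k, st in enumerate(cohort):
                img = apply_noise(st.sequences[seq], sigma, seed=k)
                s = measure_snr(img, st.wm_mask)
                if np.isfinite(s):
                    vals.append(s)
            return float(np.mean(vals))

        hi = 1.0
        while mean_snr(hi) >= bound and hi < 1e4:
            hi *= 2.0
        lo = 0.0
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            if mean_snr(mid) >= bound:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-3:
                break
        sigma_max = lo if lo > 0 else hi
        out[seq] = list(np.linspace(sigma_max / n_levels, sigma_max, n_levels))
    return out


# --------------------------------------------------------------------------
# k-space and resampling
# --------------------------------------------------------------------------

def kspace_subsample(image: VolumeGrid, fraction: float, seed: int) -> VolumeGrid:
    """Random frequency-domain masking keeping ``fraction`` of the bins.

    Forward 3-D FFT, Bernoulli(fraction) mask with the DC bin always kept,
    inverse FFT, magnitude.  No Hermitian symmetrization is enforced (the
    phase is treated as already lost); keeping DC preserves mean intensity.
    """
    if not (0.8 <= fraction <= 1.0):
        raise ValueError(f"kept fraction must lie in [0.8, 1.0], got {fraction}")
    if fraction == 1.0:
        return image.copy()
    rng = np.random.default_rng(seed)
    spec = np.fft.fftn(image.data)
    keep = rng.random(image.shape) < fraction
    keep[0, 0, 0] = True
    out = np.abs(np.fft.ifftn(spec * keep))
    return VolumeGrid(out, image.spacing)


def _zoom_roundtrip(data: np.ndarray, factors, order: int) -> np.ndarray:
    coarse = ndimage.zoom(data, factors, order=order, mode="nearest", grid_mode=True)
    back = [o / c for o, c in zip(data.shape, coarse.shape)]
    fine = ndimage.zoom(coarse, back, order=order, mode="nearest", grid_mode=True)
    if fine.shape != data.shape:  # guard rounding off-by-one
        fine = np.resize(fine, data.shape)
    return fine


def resample_voxelsize(volume, iso_mm: float, kind: str = "intensity"):
    """Simulate an isotropic coarse acquisition at ``iso_mm`` and resample
    back to the analysis grid (linear for intensities, nearest for labels)."""
    if not (1.0 <= iso_mm <= 1.5):
        raise ValueError(f"iso voxel size must lie in [1, 1.5] mm, got {iso_mm}")
    spacing = volume.spacing
    factors = [s / iso_mm for s in spacing]
    order = 1 if kind == "intensity" else 0
    data = volume.data if kind == "intensity" else volume.data.astype(float)
    fine = _zoom_roundtrip(data, factors, order)
    if kind == "intensity":
        return VolumeGrid(fine, spacing)
    return LabelMap(np.rint(fine).astype(volume.data.dtype), spacing)


def resample_slicespacing(volume, axial_mm: float, sequence: str, kind: str = "intensity"):
    """Thick-slice acquisition along the axial axis, then back to the grid.

    Intensities get a slice-profile (boxcar) average before decimation;
    labels are decimated nearest-neighbour.  In-plane resolution untouched.
    """
    lo, hi = SLICE_RANGES[sequence]
    if not (lo <= axial_mm <= hi):
        raise ValueError(
            f"axial spacing {axial_mm} mm outside the {sequence} range [{lo}, {hi}] mm"
        )
    spacing = volume.spacing
    ratio = axial_mm / spacing[2]
    if ratio == 1.0:
        return volume.copy()
    order = 1 if kind == "intensity" else 0
    data = volume.data.astype(float)
    if kind == "intensity":
        width = max(1, int(round(ratio)))
        data = ndimage.uniform_filter1d(data, size=width, axis=2, mode="nearest")
    factors = [1.0, 1.0, 1.0 / ratio]
    fine = _zoom_roundtrip(data, factors, order)
    if kind == "intensity":
        return VolumeGrid(fine, spacing)
    return LabelMap(np.rint(fine).astype(volume.data.dtype), spacing)


# --------------------------------------------------------------------------
# inter-rater simulation
# --------------------------------------------------------------------------

def _smooth_field(shape, sigma_vox: float, rng: np.random.Generator) -> np.ndarray:
    field_ = np.stack(
        [ndimage.gaussian_filter(rng.normal(size=shape), sigma_vox) for _ in range(3)]
    )
    rms = np.sqrt((field_**2).mean())
    return field_ / rms if rms > 0 else field_


def _warp_labels(labels: LabelMap, field_: np.ndarray, amplitude: float) -> LabelMap:
    coords = np.meshgrid(*[np.arange(n) for n in labels.shape], indexing="ij")
    sample = [c + amplitude * f for c, f in zip(coords, field_)]
    warped = ndimage.map_coordinates(labels.data, sample, order=0, mode="constant")
    return LabelMap(warped.astype(labels.data.dtype), labels.spacing)


def deform_labels_to_dice(
    labels: LabelMap,
    target_dice: float,
    seed: int,
    region: str = "wt",
    tolerance: float = 0.02,
    smooth_mm: float = 6.0,
    max_iter: int = 25,
) -> LabelMap:
    """Random smooth deformation whose ``region`` Dice against the original
    hits ``target_dice`` within ``tolerance``; amplitude found by bisection.

    All compartments are warped by the same displacement field with
    nearest-neighbour re-labelling, so the result is a valid label map.
    """
    if not (0.0 < target_dice <= 1.0):
        raise ValueError(f"target Dice must lie in (0, 1], got {target_dice}")
    if target_dice >= 1.0 - 1e-12:
        return labels.copy()
    rng = np.random.default_rng(seed)
    sigma_vox = smooth_mm / labels.spacing[0]
    field_ = _smooth_field(labels.shape, sigma_vox, rng)
    ref = combine_labels(labels)[region]

    def measure(amplitude: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warped = combine_labels(_warp_labels(labels, field_, amplitude))[region]
            return dice(ref, warped)

    lo, hi = 0.0, 2.0
    while measure(hi) > target_dice and hi < 64.0:
        hi *= 2.0
    achieved = None
    best_amp = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d = measure(mid)
        if abs(d - target_dice) <= tolerance:
            achieved, best_amp = d, mid
            break
        if d > target_dice:
            lo = mid
        else:
            hi = mid
    if achieved is None:
        achieved = measure(0.5 * (lo + hi))
        if abs(achieved - target_dice) > tolerance:
            raise CalibrationError(
                f"could not reach Dice {target_dice:.3f}; achieved {achieved:.3f}"
            )
        best_amp = 0.5 * (lo + hi)
    return _warp_labels(labels, field_, best_amp)


# --------------------------------------------------------------------------
# plans
# --------------------------------------------------------------------------

def build_plan(
    config: PlanConfig | None = None,
    noise_sigmas: dict[str, list[float]] | None = None,
) -> PerturbationPlan:
    """Default plan with Table-style counts and evenly spaced levels.

    ``noise_sigmas`` (from :func:`calibrate_noise_levels`) overrides the
    fallback evenly spaced noise levels.  Every spec carries a distinct
    deterministic seed derived from ``config.base_seed``.
    """
    config = config or PlanConfig()
    specs: list[PerturbationSpec] = []
    counter = 0

    def mk(family, value, applies_to):
        nonlocal counter
        seed = (config.base_seed * 1_000_003 + counter) % (2**31 - 1)
        counter += 1
        specs.append(PerturbationSpec(family, float(value), seed, tuple(applies_to)))

    for seq in config.sequences:
        sigmas = (
            noise_sigmas[seq]
            if noise_sigmas is not None
            else np.linspace(
                config.noise_sigma_max / config.n_noise,
                config.noise_sigma_max,
                config.n_noise,
            )
        )
        for s in sigmas:
            mk("noise", s, [seq])
    lo, hi = config.bin_range
    bins = np.rint(np.linspace(lo, hi, config.n_binning)).astype(int)
    for seq in config.sequences:
        for b in bins:
            mk("binning", b, [seq])
    dlo, dhi = config.dice_range
    for region in config.regions:
        for d in np.linspace(dlo, dhi, config.n_interrater):
            mk("interrater", d, [region])
    vlo, vhi = config.voxel_range
    for seq in config.sequences:
        for v in np.linspace(vlo, vhi, config.n_voxelsize):
            mk("voxelsize", v, [seq])
    for seq in config.sequences:
        slo, shi = SLICE_RANGES[seq]
        for v in np.linspace(slo, shi, config.n_slicespacing):
            mk("slicespacing", v, [seq])
    klo, khi = config.kspace_range
    for seq in config.sequences:
        for f in np.linspace(klo, khi, config.n_kspace):
            mk("kspace", f, [seq])
    return PerturbationPlan(specs)


def perturb_study(study: MRIStudy, spec: PerturbationSpec, case_seed: int) -> MRIStudy:
    """Apply one perturbation to one study (images or labels, never both)."""
    out = copy.copy(study)
    out.sequences = dict(study.sequences)
    if spec.family == "noise":
        for seq in spec.applies_to:
            out.sequences[seq] = apply_noise(study.sequences[seq], spec.value, case_seed)
    elif spec.family == "kspace":
        for seq in spec.applies_to:
            out.sequences[seq] = kspace_subsample(
                study.sequences[seq], spec.value, case_seed
            )
    elif spec.family == "voxelsize":
        for seq in spec.applies_to:
            out.sequences[seq] = resample_voxelsize(
                study.sequences[seq], spec.value, kind="intensity"
            )
    elif spec.family == "slicespacing":
        for seq in spec.applies_to:
            out.sequences[seq] = resample_slicespacing(
                study.sequences[seq], spec.value, seq, kind="intensity"
            )
    elif spec.family == "interrater":
        region = spec.applies_to[0] if spec.applies_to else "wt"
        out.labels = deform_labels_to_dice(
            study.labels, spec.value, case_seed, region=region
        )
    elif spec.family == "binning":
        pass  # handled via the extraction config, not the images
    return out


def apply_plan(
    cohort: list[MRIStudy],
    plan: PerturbationPlan,
    extraction_config: ExtractionConfig | None = None,
) -> dict[str, list[FeatureTable]]:
    """One-factor-at-a-time re-extraction.

    Returns, per family, a list of feature tables whose first entry is the
    unperturbed original; each following entry corresponds to one spec of
    that family.
    """
    extraction_config = extraction_config or ExtractionConfig()
    original = extract_feature_table(cohort, extraction_config)

    def merged_variant(source: list[MRIStudy], cfg: ExtractionConfig) -> FeatureTable:
        """Re-extract only the affected sequence's intensity (and deep)
        features and splice them into the original table: image-level
        perturbations cannot touch label-only or other-sequence features."""
        part = extract_feature_table(source, cfg)
        df = original.df.copy()
        df[part.df.columns] = part.df
        return FeatureTable(df)

    out: dict[str, list[FeatureTable]] = {}
    for family, specs in plan.by_family().items():
        tables = [original]
        for spec in specs:
            if family == "interrater":  # labels change: everything re-extracted
                perturbed = [
                    perturb_study(st, spec, case_seed=spec.seed + k)
                    for k, st in enumerate(cohort)
                ]
                tables.append(extract_feature_table(perturbed, extraction_config))
                continue
            seqs = spec.applies_to or extraction_config.sequences
            cfg = replace(
                extraction_config,
                sequences=tuple(s for s in extraction_config.sequences if s in seqs),
                include_shape=False,
                include_geometry=False,
                include_centroids=False,
                include_age=False,
            )
            if family == "binning":
                cfg = replace(
                    cfg,
                    discretization=DiscretizationSpec(
                        mode="fixed_bin_count", n_bins=int(spec.value)
                    ),
                )
                source = cohort
            else:
                source = [
                    perturb_study(st, spec, case_seed=spec.seed + k)
                    for k, st in enumerate(cohort)
                ]
            tables.append(merged_variant(source, cfg))
        out[family] = tables
    return out
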