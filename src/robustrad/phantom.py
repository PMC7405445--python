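"""Synthetic multi-sequence brain-tumour phantoms.

Generates cohorts with the statistical structure the pipeline assumes: a
two-tissue ellipsoidal brain (white/grey matter), a compartmentalized tumour
(necrosis inside contrast-enhancement inside a non-enhancing core, edema
shell outside), sequence-dependent tissue contrasts, centre-specific
acquisition profiles (axial slice thickness, noise level, scanner gain), and
overall-survival times linked to tumour geometry through a log-linear model.

The geometry is nested ellipsoids with random orientation, per-axis jitter
and a per-case global size factor, so every geometry feature varies across
cases while remaining analytically controllable.  Intensities are noiseless
tissue means plus a smooth random bias field plus per-sequence Gaussian
noise, which makes white-matter SNR measurable and calibratable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import (
    GeometryError,
    LABEL_CODES,
    LabelMap,
    MRIStudy,
    SEQUENCES,
    VolumeGrid,
)

# tissue means per sequence; values are arbitrary scanner units chosen to
# mimic the qualitative contrast ordering of each sequence (e.g. edema and
# necrosis bright on T2/FLAIR, enhancing rim bright on T1c)
DEFAULT_CONTRAST = {
    "T1": {"wm": 100.0, "gm": 80.0, "cet": 110.0, "net": 90.0, "nec": 60.0, "ed": 75.0},
    "T1c": {"wm": 100.0, "gm": 80.0, "cet": 170.0, "net": 95.0, "nec": 55.0, "ed": 75.0},
    "T2": {"wm": 80.0, "gm": 100.0, "cet": 100.0, "net": 110.0, "nec": 140.0, "ed": 150.0},
    "FLAIR": {"wm": 90.0, "gm": 100.0, "cet": 105.0, "net": 115.0, "nec": 70.0, "ed": 160.0},
}


@dataclass
class PhantomParams:
    """Geometry and intensity parameters of the synthetic brain.

    ``tumor_axes`` holds the mm half-axes of the four nested ellipsoids;
    they must nest (necrosis inside enhancement inside core inside
    core+edema) axis by axis.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    base_spacing: float = 1.0
    tumor_axes: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "nec": (5.0, 4.5, 4.0),
            "cet": (9.0, 8.0, 7.0),
            "core": (12.0, 11.0, 9.5),
            "ed": (17.0, 15.0, 13.0),
        }
    )
    contrast_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(t) for s, t in DEFAULT_CONTRAST.items()}
    )
    intensity_field_smoothness: float = 12.0  # mm, bias-field correlation scale
    bias_amplitude: float = 2.0  # intensity units (sd of the smooth field)
    wm_fraction: float = 0.55  # of brain volume modelled as white matter
    size_sigma: float = 0.18  # sd of per-case log size factor
    axis_jitter: float = 0.08  # relative per-axis half-axis jitter
    center_jitter_mm: float = 4.0  # tumour-centre offset range per axis
    enh_sigma: float = 0.35  # sd of the per-case log enhancement-intensity factor

    def __post_init__(self) -> None:
        if self.base_spacing <= 0:
            raise GeometryError("base_spacing must be positive")
        order = ["nec", "cet", "core", "ed"]
        for inner, outer in zip(order[:-1], order[1:]):
            if not all(
                a < b for a, b in zip(self.tumor_axes[inner], self.tumor_axes[outer])
            ):
                raise GeometryError(
                    f"tumor half-axes must nest: {inner} must be inside {outer}"
                )
        if any(v < 0 for t in self.contrast_table.values() for v in t.values()):
            raise GeometryError("tissue intensities must be non-negative")


@dataclass
class CenterProfile:
    """Centre-specific acquisition characteristics."""

    name: str
    axial_spacing: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SEQUENCES}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {s: 3.0 for s in SEQUENCES}
    )
    intensity_scale: float = 1.0
    scale_jitter: float = 0.0  # sd of the per-case log scanner gain

    def __post_init__(self) -> None:
        for s, sp in self.axial_spacing.items():
            if not (1.0 <= sp <= 4.0):
                raise ValueError(f"axial spacing for {s} must lie in [1, 4] mm, got {sp}")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SurvivalModel:
    """Log-linear overall-survival model.

    log OS (days) = baseline_log_os + volume_coeff * core_volume_mL
                  + rim_coeff * rim_width_mm + Normal(0, noise_sd).
    All OS are observed (no censoring), matching a cohort restricted to
    known survival.
    """

    baseline_log_os: float = 7.53
    volume_coeff: float = -0.15  # per mL of tumour core
    rim_coeff: float = -0.10  # per mm of enhancing-rim width
    enh_coeff: float = 0.0  # per unit WM-relative T1c enhancement (optional term)
    noise_sd: float = 0.45  # sd on the log-day scale

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def single_center_profile() -> CenterProfile:
    """Homogeneous-acquisition profile: thin slices, low noise, near-constant
    scanner gain."""
    return CenterProfile(name="single", scale_jitter=0.02)


def multi_center_profile() -> CenterProfile:
    """Heterogeneous-acquisition profile: thicker T2/FLAIR slices, more noise,
    a scanner gain offset."""
    return CenterProfile(
        name="multi",
        axial_spacing={"T1": 1.5, "T1c": 1.5, "T2": 3.0, "FLAIR": 3.0},
        noise_sd={s: 6.0 for s in SEQUENCES},
        intensity_scale=1.15,
        scale_jitter=0.25,  # many scanners: per-case gain is not comparable
    )


def single_center_survival() -> SurvivalModel:
    """Defaults aimed at the single-centre OS marginal (mean ~22.8 months)."""
    return SurvivalModel(baseline_log_os=7.53, noise_sd=0.45)


def multi_center_survival() -> SurvivalModel:
    """Defaults aimed at the shorter-survival multi-centre marginal
    (mean ~14.8 months), reproducing the distribution shift between cohorts."""
    return SurvivalModel(baseline_log_os=7.02, noise_sd=0.60)


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: float,
    center_mm: np.ndarray,
    half_axes: np.ndarray,
    rotation: np.ndarray,
) -> np.ndarray:
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * spacing for n in shape], indexing="ij"), axis=-1
    )
    rel = (coords - center_mm) @ rotation
    return ((rel / half_axes) ** 2).sum(axis=-1) <= 1.0


def _bias_field(
    shape: tuple[int, int, int], smoothness_vox: float, amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), smoothness_vox)
    sd = field_.std()
    if sd == 0 or amplitude == 0:
        return np.zeros(shape)
    return field_ * (amplitude / sd)


def _axial_partial_volume(data: np.ndarray, spacing_ratio: float) -> np.ndarray:
    """Thick-slice partial-volume effect: boxcar average along the axial axis."""
    size = max(1, int(round(spacing_ratio)))
    if size == 1:
        return data
    return ndimage.uniform_filter1d(data, size=size, axis=2, mode="nearest")


def generate_case(
    params: PhantomParams,
    profile: CenterProfile,
    seed: int,
    case_id: str = "case",
) -> MRIStudy:
    """Generate one synthetic study (four sequences, labels, masks, age).

    OS is set to NaN; :func:`generate_cohort` assigns it from the geometry.
    Deterministic given ``(params, profile, seed)``.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(params.grid_shape)
    sp = params.base_spacing
    extent = np.array(shape) * sp

    brain_axes = extent * 0.45
    brain_center = extent / 2.0
    brain = _ellipsoid_mask(shape, sp, brain_center, brain_axes, np.eye(3))
    wm_axes = brain_axes * params.wm_fraction ** (1.0 / 3.0)
    wm_outer = _ellipsoid_mask(shape, sp, brain_center, wm_axes, np.eye(3))

    # nominal fit check: the unjittered outer ellipsoid must fit the brain
    nominal_outer = max(params.tumor_axes["ed"])
    if nominal_outer >= brain_axes.min():
        raise GeometryError(
            f"grid {shape} too small: tumour outer half-axis "
            f"{nominal_outer:.1f} mm exceeds the brain half-axes "
            f"{np.round(brain_axes, 1).tolist()} mm"
        )

    # per-case tumour geometry: global log-normal size factor, per-axis
    # jitter, random orientation, jittered centre
    size = math.exp(rng.normal(0.0, params.size_sigma))
    jitter = 1.0 + rng.uniform(-params.axis_jitter, params.axis_jitter, size=3)
    rotation = _rotation_matrix(rng)
    offset = rng.uniform(-params.center_jitter_mm, params.center_jitter_mm, size=3)
    tumor_center = brain_center + offset

    # support extent of the rotated unit-size outer ellipsoid along each axis
    unit_outer = np.asarray(params.tumor_axes["ed"]) * jitter
    extent_unit = np.sqrt(((rotation * unit_outer[None, :]) ** 2).sum(axis=1))
    size_cap = float(np.min((brain_axes - np.abs(offset)) / extent_unit)) * 0.95
    size = min(size, size_cap)

    comp_masks = {}
    for comp in ("nec", "cet", "core", "ed"):
        axes = np.asarray(params.tumor_axes[comp]) * size * jitter
        comp_masks[comp] = _ellipsoid_mask(shape, sp, tumor_center, axes, rotation)

    label_data = np.zeros(shape, dtype=np.int16)
    label_data[comp_masks["ed"]] = LABEL_CODES["ed"]
    label_data[comp_masks["core"]] = LABEL_CODES["net"]
    label_data[comp_masks["cet"]] = LABEL_CODES["cet"]
    label_data[comp_masks["nec"]] = LABEL_CODES["nec"]
    label_data[~brain] = 0
    labels = LabelMap(label_data, (sp, sp, sp))

    tumor = label_data > 0
    wm_mask = wm_outer & ~tumor & brain
    smooth_vox = params.intensity_field_smoothness / sp

    # per-case biology and scanner state: how strongly the rim enhances on
    # T1c (a survival-linked factor) and the effective scanner gain (MRI
    # intensities are not quantitative; gain varies per acquisition)
    enh_factor = math.exp(rng.normal(0.0, params.enh_sigma))
    gain = profile.intensity_scale * math.exp(rng.normal(0.0, profile.scale_jitter))

    tissue_of_code = {LABEL_CODES[k]: k for k in ("cet", "net", "nec", "ed")}
    sequences: dict[str, VolumeGrid] = {}
    for seq in SEQUENCES:
        table = dict(params.contrast_table[seq])
        if seq == "T1c":
            table["cet"] = table["cet"] * enh_factor
        img = np.zeros(shape)
        img[brain] = table["gm"]
        img[wm_outer & brain] = table["wm"]
        for code, tissue in tissue_of_code.items():
            img[label_data == code] = table[tissue]
        img = img + _bias_field(shape, smooth_vox, params.bias_amplitude, rng)
        img *= gain
        img = _axial_partial_volume(img, profile.axial_spacing[seq] / sp)
        sd = profile.noise_sd[seq]
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=shape)
        img[~brain] = 0.0
        sequences[seq] = VolumeGrid(np.clip(img, 0.0, None), (sp, sp, sp))

    if all(profile.noise_sd[s] == 0 for s in SEQUENCES) and params.bias_amplitude == 0:
        warnings.warn(
            "zero noise and zero bias field: white-matter SNR is undefined",
            stacklevel=2,
        )

    age = float(
        stats.truncnorm.rvs(
            (18 - 62.75) / 9.96, (95 - 62.75) / 9.96, loc=62.75, scale=9.96,
            random_state=rng,
        )
    )
    return MRIStudy(
        case_id=case_id,
        sequences=sequences,
        labels=labels,
        wm_mask=wm_mask,
        brain_mask=brain,
        age=age,
        os_days=float("nan"),
        center=profile.name,
    )


def geometry_summary(study: MRIStudy) -> dict[str, float]:
    """Core volume (mL), equivalent-sphere rim width (mm), and WM-relative
    T1c enhancement (gain-invariant intensity ratio)."""
    vox_ml = float(np.prod(study.spacing)) / 1000.0
    lab = study.labels.data
    core = np.isin(lab, [LABEL_CODES["cet"], LABEL_CODES["net"], LABEL_CODES["nec"]])
    cet_total = np.isin(lab, [LABEL_CODES["cet"], LABEL_CODES["nec"]])
    nec = lab == LABEL_CODES["nec"]
    v_out = cet_total.sum() * vox_ml * 1000.0  # mm^3
    v_in = nec.sum() * vox_ml * 1000.0
    r_out = (3.0 * v_out / (4.0 * math.pi)) ** (1.0 / 3.0) if v_out > 0 else 0.0
    r_in = (3.0 * v_in / (4.0 * math.pi)) ** (1.0 / 3.0) if v_in > 0 else 0.0
    cet = lab == LABEL_CODES["cet"]
    t1c = study.sequences["T1c"].data
    wm_mean = t1c[study.wm_mask].mean() if study.wm_mask.any() else 0.0
    rel_enh = float(t1c[cet].mean() / wm_mean) if cet.any() and wm_mean > 0 else 1.0
    return {
        "core_volume_ml": float(core.sum() * vox_ml),
        "rim_width_mm": r_out - r_in,
        "relative_enhancement": rel_enh,
    }


def assign_survival(
    geometry: dict[str, float], survival: SurvivalModel, seed: int
) -> float:
    """Draw one OS (days) from the log-linear geometry model."""
    rng = np.random.default_rng(seed)
    log_os = (
        survival.baseline_log_os
        + survival.volume_coeff * geometry["core_volume_ml"]
        + survival.rim_coeff * geometry["rim_width_mm"]
        + survival.enh_coeff * geometry.get("relative_enhancement", 0.0)
    )
    if survival.noise_sd > 0:
        log_os += rng.normal(0.0, survival.noise_sd)
    return float(math.exp(log_os))


def generate_cohort(
    n: int,
    params: PhantomParams,
    profile: CenterProfile | list[CenterProfile],
    survival: SurvivalModel,
    seed: int,
) -> tuple[list[MRIStudy], pd.DataFrame]:
    """Generate ``n`` cases plus the clinical table.

    With a list of profiles, cases are assigned round-robin, giving a
    multi-centre cohort.  Returns (studies, table) where the table has
    columns case_id, center, age, os_days.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    profiles = profile if isinstance(profile, list) else [profile]
    rng = np.random.default_rng(seed)
    studies: list[MRIStudy] = []
    rows = []
    for i in range(n):
        prof = profiles[i % len(profiles)]
        case_seed = int(rng.integers(0, 2**31 - 1))
        study = generate_case(params, prof, case_seed, case_id=f"case_{i:03d}")
        study.os_days = assign_survival(
            geometry_summary(study), survival, int(rng.integers(0, 2**31 - 1))
        )
        studies.append(study)
        rows.append(
            {
                "case_id": study.case_id,
                "center": study.center,
                "age": study.age,
                "os_days": study.os_days,
            }
        )
    return studies, pd.DataFrame(rows)
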