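"""Perturbation families: closed forms, calibrations, plan defaults."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from robustrad.core import LabelMap, RegionError, VolumeGrid
from robustrad.perturb import (
    PerturbationSpec,
    PlanConfig,
    apply_noise,
    apply_plan,
    build_plan,
    calibrate_noise_levels,
    deform_labels_to_dice,
    kspace_subsample,
    measure_snr,
    resample_slicespacing,
    resample_voxelsize,
)
from robustrad.features import ExtractionConfig
from robustrad.regions import combine_labels, dice


def _grid(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(data, dtype=float), spacing)


# --------------------------------------------------------------------------
# SNR and noise
# --------------------------------------------------------------------------

def test_snr_is_mean_over_sd():
    rng = np.random.default_rng(0)
    data = rng.normal(100.0, 10.0, size=(32, 32, 32))
    mask = np.ones((32, 32, 32), dtype=bool)
    snr = measure_snr(_grid(data), mask)
    assert snr == pytest.approx(data.mean() / data.std(), rel=1e-12)
    assert snr == pytest.approx(10.0, rel=0.05)


def test_snr_constant_region_flagged_undefined():
    with pytest.warns(UserWarning, match="undefined"):
        snr = measure_snr(_grid(np.full((4, 4, 4), 3.0)), np.ones((4, 4, 4), bool))
    assert np.isnan(snr)
    with pytest.raises(RegionError):
        measure_snr(_grid(np.ones((4, 4, 4))), np.zeros((4, 4, 4), bool))


def test_added_noise_lowers_snr_toward_closed_form():
    rng = np.random.default_rng(1)
    mean, sd0, sigma = 100.0, 8.0, 6.0
    data = rng.normal(mean, sd0, size=(64, 64, 16))
    img = apply_noise(_grid(data), sigma, seed=2)
    snr = measure_snr(img, np.ones(data.shape, bool))
    assert snr == pytest.approx(mean / np.sqrt(sd0**2 + sigma**2), rel=0.02)


def test_noise_zero_is_identity_and_variance_matches():
    rng = np.random.default_rng(2)
    data = rng.uniform(50, 150, size=(64, 64, 64))
    img = _grid(data)
    np.testing.assert_array_equal(apply_noise(img, 0.0, seed=0).data, data)
    sigma = 5.0
    noised = apply_noise(img, sigma, seed=3)
    added = noised.data - data
    assert added.var() == pytest.approx(sigma**2, rel=0.02)
    other = apply_noise(img, sigma, seed=4)
    assert not np.array_equal(noised.data, other.data)


def test_noise_calibration_respects_snr_bound(small_cohort):
    studies, _ = small_cohort
    sigmas = calibrate_noise_levels(studies, 10, sequences=("T1c",))
    levels = sigmas["T1c"]
    assert len(levels) == 10
    assert all(b > a for a, b in zip(levels, levels[1:]))
    snrs = np.array([measure_snr(s.sequences["T1c"], s.wm_mask) for s in studies])
    bound = snrs.mean() - snrs.std()
    post = np.mean([
        measure_snr(apply_noise(s.sequences["T1c"], levels[-1], seed=k), s.wm_mask)
        for k, s in enumerate(studies)
    ])
    assert post >= bound * 0.95  # achieved SNR within 5% of the bound
    assert post <= snrs.mean()  # noise can only lower it


# --------------------------------------------------------------------------
# k-space
# --------------------------------------------------------------------------

def test_kspace_full_fraction_reproduces_input():
    rng = np.random.default_rng(5)
    data = rng.uniform(10, 100, size=(24, 24, 24))
    out = kspace_subsample(_grid(data), 1.0, seed=0)
    assert np.abs(out.data - data).max() <= 1e-6 * np.abs(data).max()


def test_kspace_keeps_dc_and_expected_bin_count():
    shape = (24, 24, 24)
    n = np.prod(shape)
    fraction = 0.85
    rng = np.random.default_rng(7)
    keep = rng.random(shape) < fraction
    keep[0, 0, 0] = True
    # the implementation draws the same mask from the same seed
    data = np.zeros(shape)
    data[0, 0, 0] = 1.0
    out = kspace_subsample(_grid(np.full(shape, 50.0)), fraction, seed=7)
    # DC kept -> spatial mean preserved for a constant image up to the
    # removed bins' (zero) content
    assert out.data.mean() == pytest.approx(50.0, rel=1e-9)
    kept = keep.sum()
    sd = np.sqrt(n * fraction * (1 - fraction))
    assert abs(kept - fraction * n) < 5 * sd


def test_kspace_energy_nonincreasing_and_range_checked():
    rng = np.random.default_rng(8)
    data = rng.uniform(0, 100, size=(16, 16, 16))
    out = kspace_subsample(_grid(data), 0.8, seed=1)
    assert (out.data**2).sum() <= (data**2).sum() + 1e-6
    with pytest.raises(ValueError):
        kspace_subsample(_grid(data), 0.5, seed=0)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def test_voxelsize_native_spacing_is_near_identity():
    rng = np.random.default_rng(9)
    data = rng.uniform(0, 100, size=(20, 20, 20))
    out = resample_voxelsize(_grid(data), 1.0, kind="intensity")
    np.testing.assert_allclose(out.data, data, atol=1e-9)


def test_voxelsize_label_stays_binary_with_bounded_volume_change(study):
    lm = study.labels
    out = resample_voxelsize(lm, 1.5, kind="label")
    assert set(np.unique(out.data)) <= set(np.unique(lm.data))
    v0 = (lm.data > 0).sum()
    v1 = (out.data > 0).sum()
    assert abs(v1 - v0) / v0 <= 0.05
    with pytest.raises(ValueError):
        resample_voxelsize(lm, 2.0)


def test_slicespacing_identity_and_sequence_ranges():
    rng = np.random.default_rng(10)
    data = rng.uniform(0, 100, size=(16, 16, 16))
    out = resample_slicespacing(_grid(data), 1.0, "T1", kind="intensity")
    np.testing.assert_array_equal(out.data, data)
    with pytest.raises(ValueError, match="T1 range"):
        resample_slicespacing(_grid(data), 3.0, "T1")
    resample_slicespacing(_grid(data), 3.0, "T2")  # allowed for T2


def test_slicespacing_widens_thin_plate_monotonically():
    data = np.zeros((8, 8, 40))
    data[:, :, 20] = 100.0
    widths = []
    for spacing in (1.0, 2.0, 3.0, 4.0):
        out = resample_slicespacing(_grid(data), spacing, "FLAIR", kind="intensity")
        profile = out.data[4, 4, :]
        half = profile.max() / 2.0
        widths.append(int((profile >= half).sum()))
    assert all(b >= a for a, b in zip(widths, widths[1:]))
    assert widths[-1] > widths[0]


# --------------------------------------------------------------------------
# inter-rater deformation
# --------------------------------------------------------------------------

def test_deform_target_one_is_identity(study):
    out = deform_labels_to_dice(study.labels, 1.0, seed=0)
    np.testing.assert_array_equal(out.data, study.labels.data)


def test_deform_hits_dice_target_and_stays_valid(study):
    target = 0.85
    out = deform_labels_to_dice(study.labels, target, seed=3)
    assert isinstance(out, LabelMap)  # exclusive integer codes enforced
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = dice(combine_labels(study.labels)["wt"], combine_labels(out)["wt"])
    assert abs(d - target) <= 0.02


# --------------------------------------------------------------------------
# plans
# --------------------------------------------------------------------------

def test_default_plan_counts_match_table():
    plan = build_plan()
    counts = plan.counts_per_scope()
    assert counts == {
        "noise": 10, "binning": 54, "interrater": 10,
        "voxelsize": 10, "slicespacing": 10, "kspace": 21,
    }
    by_fam = plan.by_family()
    assert len(by_fam["kspace"]) == 21 * 4
    assert len(by_fam["interrater"]) == 10 * 8
    fracs = sorted({s.value for s in by_fam["kspace"]})
    np.testing.assert_allclose(fracs, np.arange(0.80, 1.001, 0.01), atol=1e-9)
    bins = sorted({s.value for s in by_fam["binning"]})
    assert len(bins) == 54 and min(bins) == 30 and max(bins) == 130
    seeds = [s.seed for s in plan.specs]
    assert len(set(seeds)) == len(seeds)


def test_spec_value_ranges_validated():
    with pytest.raises(ValueError):
        PerturbationSpec("kspace", 0.5, 0)
    with pytest.raises(ValueError):
        PerturbationSpec("voxelsize", 2.0, 0)
    with pytest.raises(ValueError):
        PerturbationSpec("binning", 20, 0)
    with pytest.raises(ValueError):
        PerturbationSpec("slicespacing", 3.0, 0, applies_to=("T1",))


def test_apply_plan_one_factor_at_a_time(small_cohort):
    studies, _ = small_cohort
    cohort = studies[:3]
    cfg = PlanConfig(
        n_noise=1, n_binning=1, n_interrater=1, n_voxelsize=1,
        n_slicespacing=1, n_kspace=1, sequences=("T1c",), regions=("wt",),
    )
    plan = build_plan(cfg, noise_sigmas={"T1c": [2.0]})
    ext = ExtractionConfig(sequences=("T1c",), regions=("wt", "cet"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variants = apply_plan(cohort, plan, ext)
    assert set(variants) == {
        "noise", "binning", "interrater", "voxelsize", "slicespacing", "kspace"
    }
    original = variants["noise"][0]
    for family, tables in variants.items():
        assert len(tables) == 2  # original + one variant
        if family == "interrater":
            continue
        # image-level perturbations leave label-only features bit-identical
        noisy = tables[1]
        shape_cols = [c for c in original.df.columns if c[2] in ("shape", "geometry", "centroid")]
        np.testing.assert_array_equal(
            original.df[shape_cols].to_numpy(), noisy.df[shape_cols].to_numpy()
        )
    # deterministic: re-running gives identical tables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variants2 = apply_plan(cohort, plan, ext)
    np.testing.assert_array_equal(
        variants["kspace"][1].values, variants2["kspace"][1].values
    )
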