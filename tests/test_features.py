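"""Feature bank: registry counts, closed forms, brute-force texture oracles,
and invariance properties."""

import itertools
import warnings

import numpy as np
import pytest

from robustrad.core import FeatureID, RegionError, VolumeGrid
from robustrad.features import (
    DiscretizationSpec,
    ExtractionConfig,
    FAMILY_COUNTS,
    FAMILY_NAMES,
    FIRSTORDER_NAMES,
    GEOMETRY_NAMES,
    SHAPE_NAMES,
    discretize,
    enhancement_geometry,
    extract_feature_table,
    extract_study_features,
    firstorder_features,
    registry_counts,
    shape_features,
    texture_features,
    texture_features_from_levels,
)
from robustrad.features.texture import glcm_matrix, glrlm_matrix, glszm_matrix
from robustrad.regions import RegionSet

from conftest import make_ball_mask


def _grid(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(data, dtype=float), spacing)


def _full_mask(shape):
    return np.ones(shape, dtype=bool)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

def test_family_cardinalities_match_registry():
    counts = registry_counts()
    assert counts["shape"] == 26
    assert counts["firstorder"] == 19
    assert counts["GLCM"] == 24
    assert counts["GLRLM"] == 16
    assert counts["GLSZM"] == 16
    assert counts["NGTDM"] == 5
    assert counts["GLDM"] == 14
    assert counts["total_per_sequence_region"] == 120
    assert counts["geometry"] == 7
    assert counts["centroid"] == 8
    assert counts == {**FAMILY_COUNTS, "total_per_sequence_region": 120,
                      "geometry": 7, "centroid": 8}


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------

def test_discretize_constant_region_single_level():
    img = _grid(np.full((4, 4, 4), 7.0))
    levels, g = discretize(img, _full_mask((4, 4, 4)), DiscretizationSpec(n_bins=30))
    assert g == 1
    assert (levels == 1).all()


def test_discretize_uniform_range_closed_form():
    vals = np.arange(100, dtype=float).reshape(10, 10, 1)
    img = _grid(vals)
    levels, g = discretize(
        img, _full_mask((10, 10, 1)), DiscretizationSpec(mode="fixed_bin_width", bin_width=10)
    )
    expected = np.floor(vals / 10).astype(int) + 1
    np.testing.assert_array_equal(levels, expected)
    assert g == 10


def test_discretize_level_histogram_sums_to_mask_size():
    rng = np.random.default_rng(0)
    data = rng.normal(50, 20, size=(8, 8, 8))
    mask = rng.random((8, 8, 8)) > 0.4
    levels, g = discretize(_grid(data), mask, DiscretizationSpec(n_bins=32))
    counts = np.bincount(levels[mask], minlength=g + 1)[1:]
    assert counts.sum() == mask.sum()
    # independent binning oracle
    vals = data[mask]
    width = (vals.max() - vals.min()) / 32
    oracle = np.minimum(np.floor((vals - vals.min()) / width).astype(int) + 1, 32)
    np.testing.assert_array_equal(np.sort(levels[mask]), np.sort(oracle))


def test_discretize_empty_mask_rejected():
    with pytest.raises(RegionError):
        discretize(_grid(np.ones((3, 3, 3))), np.zeros((3, 3, 3), bool), DiscretizationSpec())


# --------------------------------------------------------------------------
# first order
# --------------------------------------------------------------------------

def test_firstorder_constant_region_closed_forms():
    n = 27
    f = firstorder_features(_grid(np.full((3, 3, 3), 5.0)), _full_mask((3, 3, 3)))
    assert f["mean"] == 5.0
    assert f["variance"] == 0.0
    assert f["energy"] == pytest.approx(n * 25.0)
    assert f["entropy"] == 0.0
    assert f["uniformity"] == 1.0
    assert set(f) == set(FIRSTORDER_NAMES) and len(f) == 19


def test_firstorder_small_sample_statistics():
    data = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
    f = firstorder_features(_grid(data), _full_mask((4, 1, 1)))
    assert f["mean"] == pytest.approx(2.5)
    assert f["median"] == pytest.approx(2.5)
    assert f["range"] == pytest.approx(3.0)
    assert f["minimum"] == 1.0 and f["maximum"] == 4.0


def test_skewness_kurtosis_match_moment_oracle():
    vals = np.array([2.0, 3.0, 3.0, 4.0, 5.0, 5.0, 5.0, 8.0, 9.0, 12.0])
    f = firstorder_features(_grid(vals.reshape(10, 1, 1)), _full_mask((10, 1, 1)))
    mu = vals.mean()
    m2 = ((vals - mu) ** 2).mean()
    m3 = ((vals - mu) ** 3).mean()
    m4 = ((vals - mu) ** 4).mean()
    assert f["skewness"] == pytest.approx(m3 / m2**1.5, rel=1e-12)
    assert f["kurtosis"] == pytest.approx(m4 / m2**2, rel=1e-12)
    assert f["variance"] == pytest.approx(m2, rel=1e-12)


def test_firstorder_affine_intensity_equivariance():
    rng = np.random.default_rng(3)
    data = rng.normal(100, 15, size=(6, 6, 6))
    mask = rng.random((6, 6, 6)) > 0.3
    f1 = firstorder_features(_grid(data), mask)
    f2 = firstorder_features(_grid(2.0 * data + 10.0), mask)
    for name in ("mean", "median", "percentile_10", "percentile_90", "minimum", "maximum"):
        assert f2[name] == pytest.approx(2.0 * f1[name] + 10.0, rel=1e-9)
    assert f2["standard_deviation"] == pytest.approx(2.0 * f1["standard_deviation"], rel=1e-9)


# --------------------------------------------------------------------------
# shape
# --------------------------------------------------------------------------

def test_shape_cube_closed_forms():
    mask = np.zeros((14, 14, 14), dtype=bool)
    mask[2:12, 2:12, 2:12] = True
    f = shape_features(mask, (1.0, 1.0, 1.0))
    assert len(f) == 26 and set(f) == set(SHAPE_NAMES)
    assert f["voxel_volume"] == pytest.approx(1000.0)
    assert f["mesh_volume"] == pytest.approx(1000.0, rel=0.02)
    # the mesh chamfers voxel edges, so the area sits slightly below the
    # voxel-face count of 600 mm^2
    assert f["surface_area"] == pytest.approx(600.0, rel=0.07)
    assert f["surface_area"] < 600.0
    assert f["surface_volume_ratio"] == pytest.approx(
        f["surface_area"] / f["mesh_volume"], rel=1e-12
    )


def test_shape_spacing_scaling_dimensional_analysis():
    mask = make_ball_mask((20, 20, 20), (9.5, 9.5, 9.5), 6.0)
    f1 = shape_features(mask, (1.0, 1.0, 1.0))
    f2 = shape_features(mask, (2.0, 2.0, 2.0))
    assert f2["mesh_volume"] == pytest.approx(8.0 * f1["mesh_volume"], rel=1e-5)
    assert f2["voxel_volume"] == pytest.approx(8.0 * f1["voxel_volume"], rel=1e-9)
    assert f2["maximum_3d_diameter"] == pytest.approx(2.0 * f1["maximum_3d_diameter"], rel=1e-9)
    assert f2["major_axis_length"] == pytest.approx(2.0 * f1["major_axis_length"], rel=1e-9)


def test_digital_ball_sphericity_near_one():
    mask = make_ball_mask((28, 28, 28), (13.5, 13.5, 13.5), 12.0)
    f = shape_features(mask, (1.0, 1.0, 1.0))
    assert 0.9 <= f["sphericity"] <= 1.0
    # mesh-based oracle: sphericity from the analytic sphere of equal mesh volume
    r = (3.0 * f["mesh_volume"] / (4 * np.pi)) ** (1 / 3)
    assert f["surface_area"] == pytest.approx(4 * np.pi * r**2 / f["sphericity"], rel=1e-6)


def test_shape_ignores_intensity(study):
    from robustrad.regions import combine_labels

    rs = combine_labels(study.labels)
    f1 = shape_features(rs["wt"], study.spacing)
    f2 = shape_features(rs["wt"], study.spacing)  # no image argument at all
    assert f1 == f2


# --------------------------------------------------------------------------
# texture oracles
# --------------------------------------------------------------------------

TOY = np.array([[1, 1, 2], [2, 2, 3], [3, 3, 3]], dtype=np.int32).reshape(3, 3, 1)


def _brute_force_glcm(levels, n_levels):
    """Per-direction symmetric co-occurrence by explicit coordinate walking,
    normalized and averaged exactly as the contract states."""
    pts = list(zip(*np.nonzero(levels)))
    vox = {p: int(levels[p]) for p in pts}
    dirs = [d for d in itertools.product((-1, 0, 1), repeat=3)
            if d != (0, 0, 0) and d > (0, 0, 0)]
    acc = np.zeros((n_levels, n_levels))
    n_dir = 0
    for d in dirs:
        m = np.zeros((n_levels, n_levels))
        for p, gp in vox.items():
            q = tuple(a + b for a, b in zip(p, d))
            if q in vox:
                m[gp - 1, vox[q] - 1] += 1
        m = m + m.T
        if m.sum() > 0:
            acc += m / m.sum()
            n_dir += 1
    return acc / n_dir


def test_glcm_counts_match_hand_enumeration():
    mat = glcm_matrix(TOY, 3)
    expected = _brute_force_glcm(TOY, 3)
    np.testing.assert_allclose(mat, expected, atol=1e-12)
    assert mat.sum() == pytest.approx(1.0)
    assert mat == pytest.approx(mat.T)


def _brute_force_runs(levels):
    """Enumerate maximal runs per direction by explicit walking."""
    runs = {}
    pts = set(zip(*np.nonzero(levels)))
    dirs = [d for d in itertools.product((-1, 0, 1), repeat=3)
            if d != (0, 0, 0) and d > (0, 0, 0)]
    for d in dirs:
        for p in pts:
            prev = tuple(a - b for a, b in zip(p, d))
            if prev in pts and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = tuple(a + b for a, b in zip(p, d))
            while q in pts and levels[q] == levels[p]:
                length += 1
                q = tuple(a + b for a, b in zip(q, d))
            key = (int(levels[p]), length)
            runs[key] = runs.get(key, 0) + 1
    return runs


def test_glrlm_counts_match_hand_enumeration():
    mat = glrlm_matrix(TOY, 3)  # averaged over the 13 directions
    brute = _brute_force_runs(TOY)
    expected = np.zeros_like(mat)
    for (g, l), c in brute.items():
        expected[g - 1, l - 1] = c / 13.0
    np.testing.assert_allclose(mat, expected, atol=1e-12)


def test_glszm_isolated_voxels_all_zones_single():
    # stride-2 lattice: no two foreground voxels touch, even diagonally
    levels = np.zeros((4, 4, 4), dtype=np.int32)
    levels[::2, ::2, ::2] = 1
    mat = glszm_matrix(levels, 1)
    n_vox = int((levels > 0).sum())
    assert mat.shape[1] == 1  # all zones size 1
    assert mat[0, 0] == n_vox


def test_constant_region_degenerate_texture_values():
    levels = np.ones((4, 4, 4), dtype=np.int32)
    glcm = texture_features_from_levels(levels, 1, "GLCM")
    assert glcm["contrast"] == 0.0
    assert np.isnan(glcm["correlation"])  # undefined, flagged
    ngtdm = texture_features_from_levels(levels, 1, "NGTDM")
    assert ngtdm["coarseness"] == pytest.approx(1e6)  # degenerate cap


def test_single_voxel_mask_pairwise_family_flagged():
    levels = np.zeros((3, 3, 3), dtype=np.int32)
    levels[1, 1, 1] = 1
    with pytest.warns(UserWarning, match="single-voxel"):
        f = texture_features_from_levels(levels, 1, "GLCM")
    assert all(np.isnan(v) for v in f.values())


def test_texture_invariant_under_joint_translation():
    rng = np.random.default_rng(5)
    data = np.zeros((10, 10, 10))
    data[1:6, 1:6, 1:6] = rng.normal(10, 3, size=(5, 5, 5))
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[1:6, 1:6, 1:6] = True
    shifted = np.roll(data, (3, 2, 1), axis=(0, 1, 2))
    mask_shifted = np.roll(mask, (3, 2, 1), axis=(0, 1, 2))
    spec = DiscretizationSpec(n_bins=30)
    for fam in ("GLCM", "GLRLM", "GLSZM", "NGTDM", "GLDM"):
        f1 = texture_features(_grid(data), mask, spec, fam)
        f2 = texture_features(_grid(shifted), mask_shifted, spec, fam)
        for name in f1:
            np.testing.assert_allclose(f1[name], f2[name], rtol=1e-10, err_msg=f"{fam}:{name}")


def test_texture_family_name_counts():
    assert {f: len(n) for f, n in FAMILY_NAMES.items()} == {
        "GLCM": 24, "GLRLM": 16, "GLSZM": 16, "NGTDM": 5, "GLDM": 14,
    }


# --------------------------------------------------------------------------
# enhancement geometry
# --------------------------------------------------------------------------

def _regions_with(cet, nec):
    zero = np.zeros_like(cet)
    wt = cet | nec
    return RegionSet(
        {
            "cet": cet, "nec": nec, "net": zero, "ed": zero,
            "wt": wt, "core": wt, "net_ncr": nec, "net_ed": zero,
        },
        (1.0, 1.0, 1.0),
    )


def test_spherical_shell_rim_width_analytic():
    shape = (28, 28, 28)
    c = (13.5, 13.5, 13.5)
    outer = make_ball_mask(shape, c, 10.0)
    inner = make_ball_mask(shape, c, 8.0)
    f = enhancement_geometry(_regions_with(outer & ~inner, inner), (1.0, 1.0, 1.0))
    assert set(f) == set(GEOMETRY_NAMES) and len(f) == 7
    assert f["rim_width"] == pytest.approx(2.0, abs=0.15)
    assert f["total_volume"] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)


def test_empty_necrosis_rim_is_equivalent_radius_of_total():
    shape = (20, 20, 20)
    ball = make_ball_mask(shape, (9.5, 9.5, 9.5), 6.0)
    f = enhancement_geometry(_regions_with(ball, np.zeros_like(ball)), (1.0, 1.0, 1.0))
    assert f["inner_volume"] == 0.0
    r_eq = (3 * f["ce_volume"] / (4 * np.pi)) ** (1 / 3)
    assert f["rim_width"] == pytest.approx(r_eq, rel=1e-9)


def test_empty_cet_gives_missing_values():
    zero = np.zeros((6, 6, 6), dtype=bool)
    f = enhancement_geometry(_regions_with(zero, zero), (1.0, 1.0, 1.0))
    assert all(np.isnan(v) for v in f.values())


def test_ball_more_regular_than_ellipsoid():
    ball = make_ball_mask((24, 24, 24), (11.5, 11.5, 11.5), 8.0)
    coords = np.stack(np.meshgrid(*[np.arange(28)] * 3, indexing="ij"), axis=-1)
    rel = (coords - 13.5) / np.array([16.0, 8.0, 4.0])
    ellipsoid = (rel**2).sum(-1) <= 1.0
    f_ball = enhancement_geometry(_regions_with(ball, np.zeros_like(ball)), (1, 1, 1))
    f_ell = enhancement_geometry(_regions_with(ellipsoid, np.zeros_like(ellipsoid)), (1, 1, 1))
    assert f_ball["surface_regularity"] >= f_ell["surface_regularity"]


# --------------------------------------------------------------------------
# extraction table
# --------------------------------------------------------------------------

def test_full_registry_column_count(study):
    feats = extract_study_features(study, ExtractionConfig())
    expected = 26 * 8 + 94 * 4 * 8 + 7 + 8 + 1
    assert len(feats) == expected
    assert len(set(feats)) == expected  # IDs unique


def test_empty_region_features_missing_row_retained(small_params):
    from dataclasses import replace
    from robustrad.phantom import generate_case, single_center_profile

    st = generate_case(small_params, single_center_profile(), seed=2)
    st.labels.data[st.labels.data == 4] = 2  # remove edema entirely
    cfg = ExtractionConfig(sequences=("T1c",), regions=("ed", "wt"))
    table = extract_feature_table([st], cfg)
    assert len(table) == 1
    ed_cols = [f for f in table.feature_ids if f.region == "ed" and f.family != "centroid"]
    assert ed_cols
    assert table.df[[tuple(f) for f in ed_cols]].isna().all().all()
    wt_cols = [f for f in table.feature_ids if f.region == "wt" and f.family == "firstorder"]
    assert table.df[[tuple(f) for f in wt_cols]].notna().all().all()
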