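import numpy as np
import pytest
from scipy import ndimage, stats
from skimage.feature import graycomatrix

from conftest import random_blob_fixture
from dynfet.parametric import ParametricImage, VoxelMask
from dynfet.radiomics import (
    DiscretizationRule,
    FEATURE_NAMES,
    discretize,
    extract_all,
    iqr4_bin_width,
    resample_isotropic,
)
from dynfet.radiomics.firstorder import first_order_features
from dynfet.radiomics.shape import shape_features
from dynfet.radiomics.texture import texture_features

ISO = (2.03, 2.03, 2.03)


class TestDiscretize:
    def test_iqr4_single_patient(self):
        assert iqr4_bin_width([[1, 2, 3, 4]]) == pytest.approx(0.375)

    def test_iqr4_averages_patients(self):
        # patients with IQRs 0.6 and 1.0 -> mean 0.8, width 0.2
        a = np.percentile([0.0, 0.2, 0.4, 0.6], [25, 75])
        assert a[1] - a[0] == pytest.approx(0.3)
        patients = [[0, 0.4, 0.8, 1.2], [0, 2 / 3, 4 / 3, 2.0]]
        assert iqr4_bin_width(patients) == pytest.approx((0.6 + 1.0) / 2 / 4)

    def test_iqr4_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            iqr4_bin_width([])

    def test_floor_arithmetic(self):
        levels, ng = discretize(np.array([0.0, 0.17, 0.18, 0.35]), DiscretizationRule(0.18))
        assert levels.tolist() == [1, 1, 2, 2] and ng == 2

    def test_constant_values_single_level(self):
        levels, ng = discretize(np.full(5, 3.3), DiscretizationRule(0.5))
        assert ng == 1 and set(levels) == {1}

    def test_ttp_midpoints_map_to_sparse_levels(self):
        mids = np.array([2.5, 7.5, 12.5, 17.5, 25.0, 35.0])
        levels, ng = discretize(mids, DiscretizationRule(5.0))
        assert levels.tolist() == [1, 2, 3, 4, 5, 7] and ng == 7

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            DiscretizationRule(0.0)

    def test_doubling_width_never_increases_level_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(size=50)
            w = float(rng.uniform(0.05, 1.0))
            _, ng1 = discretize(v, DiscretizationRule(w))
            _, ng2 = discretize(v, DiscretizationRule(2 * w))
            assert ng2 <= ng1


class TestFirstOrder:
    RULE = DiscretizationRule(0.5)

    def test_constant_region_closed_forms(self):
        f = first_order_features(np.full(27, 2.0), self.RULE, voxel_volume_mm3=3.0)
        assert f["Energy"] == pytest.approx(27 * 4.0)
        assert f["TotalEnergy"] == pytest.approx(3.0 * 27 * 4.0)
        assert f["Variance"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Entropy"] == 0.0

    def test_two_point_set(self):
        f = first_order_features(np.array([1.0, 3.0]), self.RULE)
        assert f["Mean"] == 2.0
        assert f["Range"] == 2.0
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(5))

    def test_moments_match_scipy(self):
        rng = np.random.default_rng(2)
        v = rng.gamma(2.0, 1.5, 200)
        f = first_order_features(v, self.RULE)
        assert f["Skewness"] == pytest.approx(stats.skew(v, bias=True))
        assert f["Kurtosis"] == pytest.approx(stats.kurtosis(v, bias=True, fisher=False))
        assert f["Variance"] == pytest.approx(np.var(v))


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, ISO)
        assert f["VoxelVolume"] == pytest.approx(2.03**3)
        assert f["MajorAxisLength"] == 0.0

    def test_cuboid_diameter_ordering(self):
        mask = np.zeros((8, 6, 5), bool)
        mask[1:7, 1:5, 1:4] = True
        f = shape_features(mask, ISO)
        for axis in ("Slice", "Column", "Row"):
            assert f["Maximum3DDiameter"] >= f[f"Maximum2DDiameter{axis}"]

    def test_sphere_against_analytic_values(self):
        shape = (16, 16, 16)
        g = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        mask = sum((gg - 7.5) ** 2 for gg in g) <= 5.0**2
        f = shape_features(mask, (1.0, 1.0, 1.0))
        r = 5.0
        assert f["MeshVolume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
        # marching cubes on a binary voxelisation overestimates a smooth sphere's area
        assert f["SurfaceArea"] == pytest.approx(4 * np.pi * r**2, rel=0.15)
        assert 0.85 < f["Sphericity"] <= 1.0
        assert f["Elongation"] == pytest.approx(1.0, abs=0.05)


class TestTextureConventions:
    def test_constant_region_degenerate_values(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        mask = np.ones((4, 4, 4), bool)
        f = texture_features(levels, mask)
        # single grey level: non-uniformity-normalised measures collapse to 1
        assert f["glrlm.GreyLevelNonUniformityNormalized"] == pytest.approx(1.0)
        assert f["glszm.GreyLevelNonUniformityNormalized"] == pytest.approx(1.0)
        assert f["glcm.Correlation"] == 1.0
        assert f["glcm.MCC"] == 1.0
        assert f["glcm.JointEnergy"] == pytest.approx(1.0)  # single nonzero entry
        assert f["gldm.GreyLevelNonUniformity"] == pytest.approx(64.0)

    def test_glcm_counts_match_skimage_on_2d_fixture(self):
        rng = np.random.default_rng(3)
        img2d = rng.integers(1, 5, (9, 9)).astype(np.int64)
        levels = img2d[:, :, None]
        mask = np.ones_like(levels, bool)
        from dynfet.radiomics.texture import DIRECTIONS_13, _glcm_matrices

        mats = _glcm_matrices(levels, mask, np.unique(levels))
        in_plane = [m for d, m in zip(DIRECTIONS_13, mats) if d[2] == 0]
        ours = sum(in_plane)
        sk = graycomatrix(
            (img2d - 1).astype(np.uint8),
            distances=[1],
            angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=4,
            symmetric=True,
        )
        theirs = sk[:, :, 0, :].sum(axis=-1).astype(float)
        assert np.array_equal(ours, theirs)

    def test_lower_uniformity_for_mixed_category_maps(self):
        rng = np.random.default_rng(5)
        mask = np.ones((8, 8, 8), bool)
        homogeneous = np.full((8, 8, 8), 7, dtype=np.int64)
        mixed = rng.choice([1, 2, 7], size=(8, 8, 8)).astype(np.int64)
        f_h = texture_features(homogeneous, mask)
        f_m = texture_features(mixed, mask)
        assert f_m["glrlm.GreyLevelNonUniformityNormalized"] < f_h["glrlm.GreyLevelNonUniformityNormalized"]
        assert f_m["glszm.GreyLevelNonUniformityNormalized"] < f_h["glszm.GreyLevelNonUniformityNormalized"]


class TestResample:
    def test_identity_at_target_spacing(self):
        img = ParametricImage(np.random.default_rng(0).random((6, 6, 6)), "TTP", ISO)
        mask = VoxelMask(np.ones((6, 6, 6), bool))
        out_img, out_mask = resample_isotropic(img, mask, 2.03)
        assert out_img is img and out_mask is mask

    def test_constant_image_stays_constant(self):
        img = ParametricImage(np.full((8, 8, 6), 2.5), "TBR_20_40", (2.03, 2.03, 2.43))
        mask = VoxelMask(np.ones((8, 8, 6), bool))
        out_img, out_mask = resample_isotropic(img, mask, 2.03)
        assert np.allclose(out_img.grid, 2.5)
        assert out_mask.grid.all()

    def test_grid_arithmetic_floor_convention(self):
        img = ParametricImage(np.zeros((10, 10, 10)), "TBR_20_40", (2.03, 2.03, 2.43))
        mask = VoxelMask(np.ones((10, 10, 10), bool))
        out_img, _ = resample_isotropic(img, mask, 2.03)
        assert out_img.grid.shape == (10, 10, int(np.floor(10 * 2.43 / 2.03)))

    def test_matches_scipy_trilinear_interpolation(self):
        rng = np.random.default_rng(7)
        grid = rng.random((9, 8, 10))
        spacing = (2.03, 2.03, 2.43)
        img = ParametricImage(grid, "TBR_20_40", spacing)
        mask = VoxelMask(np.ones(grid.shape, bool))
        out_img, _ = resample_isotropic(img, mask, 2.03)
        new_shape = out_img.grid.shape
        coords = np.meshgrid(
            *(np.arange(n) * 2.03 / s for n, s in zip(new_shape, spacing)), indexing="ij"
        )
        expected = ndimage.map_coordinates(grid, np.stack(coords), order=1, mode="nearest")
        assert np.allclose(out_img.grid, expected, atol=1e-6)

    def test_empty_resampled_mask_is_an_error(self):
        img = ParametricImage(np.zeros((9, 9, 3)), "TBR_20_40", (1.0, 1.0, 1.0))
        mask = np.zeros((9, 9, 3), bool)
        mask[0, 0, 2] = True  # single voxel beyond the coarser grid's extent
        with pytest.raises(ValueError, match="empty"):
            resample_isotropic(img, VoxelMask(mask), 2.5)


class TestExtractAll:
    def test_returns_exactly_107_named_features(self):
        rng = np.random.default_rng(1)
        image, mask = random_blob_fixture(rng)
        feats = extract_all(image, mask, DiscretizationRule(0.3))
        named = [k for k in feats if not k.startswith("_")]
        assert sorted(named) == sorted(FEATURE_NAMES)
        assert len(named) == 107
        assert all(np.isfinite(feats[k]) for k in named)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        shape = (12, 12, 10)
        img = rng.normal(2, 0.5, shape)
        mask = np.zeros(shape, bool)
        mask[2:6, 2:6, 2:5] = True
        f1 = extract_all(ParametricImage(img, "TBR_20_40", ISO), VoxelMask(mask), DiscretizationRule(0.3))
        img2 = np.roll(img, (3, 2, 1), axis=(0, 1, 2))
        mask2 = np.roll(mask, (3, 2, 1), axis=(0, 1, 2))
        f2 = extract_all(ParametricImage(img2, "TBR_20_40", ISO), VoxelMask(mask2), DiscretizationRule(0.3))
        for k in FEATURE_NAMES:
            assert f2[k] == pytest.approx(f1[k], rel=1e-9), k

    def test_records_bin_width(self):
        rng = np.random.default_rng(3)
        image, mask = random_blob_fixture(rng)
        feats = extract_all(image, mask, DiscretizationRule(0.25))
        assert feats["_bin_width"] == 0.25

    def test_empty_mask_error_names_stage(self):
        img = ParametricImage(np.ones((4, 4, 4)), "TTP", ISO)
        with pytest.raises(ValueError, match="mask is empty"):
            extract_all(img, VoxelMask(np.zeros((4, 4, 4), bool)), DiscretizationRule(1.0))
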