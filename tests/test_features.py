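"""Unit, oracle and property tests for the 93-feature extractor."""

import numpy as np
import pytest

import radstab as r
from radstab.features import (
    ALL_FEATURE_NAMES,
    DiscretizedROI,
    FAMILY_COUNTS,
    discretize_roi,
    first_order_features,
    gldm_features,
    gldm_matrix,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
)
from conftest import (
    brute_gldm,
    brute_glcm,
    brute_ngtdm,
    brute_runs,
    brute_zones,
    random_toy_roi,
)


def disc_from_grid(grid, mask=None):
    grid = np.asarray(grid, dtype=np.int64)
    if mask is None:
        mask = grid > 0
    return DiscretizedROI(grid, np.asarray(mask, dtype=bool),
                          int(grid[mask].max()), 25.0)


class TestDiscretization:
    @pytest.mark.parametrize(
        "values,width,expected,ng",
        [
            ([0, 24, 25, 74], 25, [1, 1, 2, 3], 3),
            ([5, 5, 5], 25, [1, 1, 1], 1),
            ([-10, 60], 25, [1, 3], 3),
        ],
    )
    def test_min_anchored_fixed_bin_width(self, values, width, expected, ng):
        levels = r.discretize_fixed_bin_width(values, width)
        assert levels.tolist() == expected
        assert levels.max() == ng

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            r.discretize_fixed_bin_width([], 25)

    def test_roi_grid_keeps_coordinates(self):
        vol = np.zeros((2, 3, 3))
        mask = np.zeros_like(vol, dtype=bool)
        mask[0, 1, 1] = mask[1, 2, 2] = True
        vol[1, 2, 2] = 50.0
        disc = discretize_roi(vol, mask, 25.0)
        assert disc.n_levels == 3
        assert disc.levels.tolist() == [1, 3]


class TestFirstOrder:
    def test_direct_arithmetic_example(self):
        f = first_order_features([1, 2, 3, 4])
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Range"] == pytest.approx(3.0)
        assert f["Energy"] == pytest.approx(30.0)

    def test_constant_roi_degenerate_values(self):
        f = first_order_features([7.0] * 20)
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0
        assert f["Kurtosis"] == 0.0

    def test_monte_carlo_against_independent_computation(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=1000)
        f = first_order_features(x)
        se_mean = 1 / np.sqrt(len(x))
        assert abs(f["Mean"]) < 4 * se_mean
        assert abs(f["Variance"] - 1) < 4 * np.sqrt(2 / len(x))
        # independent direct computation of a few definitions
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(np.mean(x**2)))
        assert f["MeanAbsoluteDeviation"] == pytest.approx(
            np.mean(np.abs(x - x.mean())))
        sub = x[(x >= np.percentile(x, 10)) & (x <= np.percentile(x, 90))]
        assert f["RobustMeanAbsoluteDeviation"] == pytest.approx(
            np.mean(np.abs(sub - sub.mean())))

    def test_total_energy_scales_with_voxel_volume(self):
        f1 = first_order_features([1, 2, 3], voxel_volume=1.0)
        f2 = first_order_features([1, 2, 3], voxel_volume=2.5)
        assert f2["TotalEnergy"] == pytest.approx(2.5 * f1["TotalEnergy"])
        assert f2["Energy"] == f1["Energy"]


class TestGLCM:
    def test_constant_roi_single_entry(self):
        disc = disc_from_grid(np.ones((1, 4, 4), dtype=int))
        for p in glcm_matrix(disc):
            assert p.shape == (1, 1)
            assert p[0, 0] == pytest.approx(1.0)

    def test_pair_counts_match_enumeration_oracle(self):
        grid = np.array([[[1, 1], [1, 2]]])
        disc = disc_from_grid(grid)
        in_plane = [(0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1)]
        for d in in_plane:
            ref = brute_glcm(disc.grid, disc.mask, d, 2)
            mats = glcm_matrix(disc, directions=[d])
            assert np.allclose(mats[0], ref / ref.sum())

    def test_checkerboard_contrast(self):
        yy, xx = np.mgrid[0:4, 0:4]
        grid = (1 + (yy + xx) % 2)[None]
        disc = disc_from_grid(grid)
        for d in [(0, 0, 1), (0, 1, 0)]:
            f = glcm_features(glcm_matrix(disc, directions=[d]))
            assert f["Contrast"] == pytest.approx(1.0)
            assert f["MaximumProbability"] == pytest.approx(0.5)

    def test_constant_roi_feature_guards(self):
        disc = disc_from_grid(np.ones((1, 4, 4), dtype=int))
        f = glcm_features(glcm_matrix(disc))
        assert f["Contrast"] == 0.0
        assert f["JointEntropy"] == 0.0
        assert f["MaximumProbability"] == 1.0
        assert f["Correlation"] == 0.0  # documented flat-region guard
        assert f["MCC"] == 1.0

    def test_hand_filled_contrast_oracle(self):
        p = np.array([[0.2, 0.1, 0.0], [0.1, 0.3, 0.1], [0.0, 0.1, 0.1]])
        f = glcm_features([p])
        expected = sum(
            p[i, j] * (i - j) ** 2 for i in range(3) for j in range(3))
        assert f["Contrast"] == pytest.approx(expected, abs=1e-12)

    def test_id_and_idm_bounded(self):
        rng = np.random.default_rng(0)
        disc = disc_from_grid(rng.integers(1, 4, size=(2, 5, 5)))
        f = glcm_features(glcm_matrix(disc))
        assert 0 < f["Id"] <= 1
        assert 0 < f["Idm"] <= 1


class TestGLRLM:
    def test_single_axial_run(self):
        disc = disc_from_grid(np.ones((4, 1, 1), dtype=int))
        mats = glrlm_matrix(disc, directions=[(1, 0, 0)])
        assert mats[0].shape == (1, 4)
        assert mats[0][0, 3] == 1
        f = glrlm_features(mats, disc.n_voxels)
        assert f["LongRunEmphasis"] == pytest.approx(16.0)

    def test_hand_enumerated_row(self):
        disc = disc_from_grid(np.array([[[1, 1, 2, 2, 2]]]))
        mats = glrlm_matrix(disc, directions=[(0, 0, 1)])
        assert mats[0][0, 1] == 1  # level 1, length 2
        assert mats[0][1, 2] == 1  # level 2, length 3
        f = glrlm_features(mats, disc.n_voxels)
        assert f["RunPercentage"] == pytest.approx(2 / 5)

    def test_alternating_levels_all_short_runs(self):
        disc = disc_from_grid(np.array([[[1, 2, 1, 2, 1, 2]]]))
        f = glrlm_features(glrlm_matrix(disc, directions=[(0, 0, 1)]),
                           disc.n_voxels)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0)


class TestGLSZM:
    def test_single_zone_constant_roi(self):
        disc = disc_from_grid(np.ones((2, 3, 3), dtype=int))
        s = glszm_matrix(disc)
        assert s.sum() == 1
        f = glszm_features(s, disc.n_voxels)
        assert f["SizeZoneNonUniformity"] == pytest.approx(1.0)

    def test_two_plateaus_against_flood_fill_oracle(self):
        grid = np.full((1, 3, 5), 2, dtype=np.int64)
        grid[0, 0, 0:2] = 1   # plateau of size 2
        grid[0, 2, 1:4] = 1   # plateau of size 3
        disc = disc_from_grid(grid)
        assert np.array_equal(glszm_matrix(disc),
                              brute_zones(disc.grid, disc.mask, 2))

    def test_checkerboard_every_voxel_its_own_zone(self):
        yy, xx = np.mgrid[0:4, 0:4]
        # 4-level pattern: diagonal neighbours always differ
        grid = (1 + (yy % 2) * 2 + xx % 2)[None]
        disc = disc_from_grid(grid)
        f = glszm_features(glszm_matrix(disc), disc.n_voxels)
        assert f["SmallAreaEmphasis"] == pytest.approx(1.0)
        assert f["ZonePercentage"] == pytest.approx(1.0)


class TestGLDM:
    def test_constant_roi_neighbor_counts(self):
        disc = disc_from_grid(np.ones((1, 3, 3), dtype=int))
        d = gldm_matrix(disc, alpha=0)
        ref = brute_gldm(disc.grid, disc.mask, 0, 1)
        assert np.array_equal(d, ref)
        assert d[0, 8] == 1   # centre: 8 dependent neighbours
        assert d[0, 5] == 4   # edges
        assert d[0, 3] == 4   # corners

    def test_checkerboard_zero_dependence(self):
        yy, xx = np.mgrid[0:4, 0:4]
        grid = (1 + (yy % 2) * 2 + xx % 2)[None]
        disc = disc_from_grid(grid)
        d = gldm_matrix(disc, alpha=0)
        assert d[:, 1:].sum() == 0  # all dependence counts are 0
        f = gldm_features(d)
        assert f["DependenceNonUniformityNormalized"] == pytest.approx(1.0)

    def test_alpha_saturation(self):
        rng = np.random.default_rng(1)
        disc = disc_from_grid(rng.integers(1, 5, size=(2, 4, 4)))
        d = gldm_matrix(disc, alpha=100)
        ref = brute_gldm(disc.grid, disc.mask, 100, disc.n_levels)
        assert np.array_equal(d, ref)
        # every voxel's dependence equals its in-ROI neighbour count
        assert d[:, 0].sum() == 0


class TestNGTDM:
    def test_constant_roi_guards(self):
        disc = disc_from_grid(np.ones((1, 3, 3), dtype=int))
        f = ngtdm_features(disc)
        assert f["Coarseness"] == 1e6
        assert f["Contrast"] == 0.0

    def test_bright_center_hand_computed(self):
        grid = np.ones((1, 3, 3), dtype=np.int64)
        grid[0, 1, 1] = 2
        disc = disc_from_grid(grid)
        n_i, p_i, s_i = ngtdm_table(disc)
        ref_n, ref_s = brute_ngtdm(disc.grid, disc.mask, 2)
        assert np.array_equal(n_i, ref_n)
        assert np.allclose(s_i, ref_s)
        # centre: |2 - mean(eight 1s)| = 1; each edge voxel sees the bright
        # centre among its in-plane neighbours
        assert s_i[1] == pytest.approx(1.0)

    def test_contrast_formula_against_direct_summation(self):
        rng = np.random.default_rng(2)
        disc = disc_from_grid(rng.integers(1, 3, size=(1, 4, 4)))
        n_i, p_i, s_i = ngtdm_table(disc)
        ngp = int((p_i > 0).sum())
        i = np.arange(1, len(p_i) + 1)
        direct = 0.0
        for a in range(len(p_i)):
            for b in range(len(p_i)):
                if p_i[a] > 0 and p_i[b] > 0:
                    direct += p_i[a] * p_i[b] * (i[a] - i[b]) ** 2
        direct = direct / (ngp * (ngp - 1)) * s_i.sum() / n_i.sum()
        assert ngtdm_features(disc)["Contrast"] == pytest.approx(direct, abs=1e-12)


class TestExtraction:
    def test_exactly_93_features_with_family_split(self, ground_truth):
        vol, rois = ground_truth
        fv = r.feature_vector(vol.voxels, rois.mask(1))
        assert len(fv) == 93
        from collections import Counter

        counts = Counter(k.split(".")[0] for k in fv)
        assert counts == FAMILY_COUNTS
        assert tuple(fv) == ALL_FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values())

    def test_deterministic(self, ground_truth):
        vol, rois = ground_truth
        a = r.feature_vector(vol.voxels, rois.mask(5))
        b = r.feature_vector(vol.voxels, rois.mask(5))
        assert a == b

    def test_shift_invariance_of_texture_families(self, ground_truth):
        vol, rois = ground_truth
        mask = rois.mask(3)
        base = r.feature_vector(vol.voxels, mask)
        shifted = r.feature_vector(vol.voxels + 100.0, mask)
        assert shifted["firstorder.Mean"] == pytest.approx(
            base["firstorder.Mean"] + 100.0)
        for name in ALL_FEATURE_NAMES:
            if not name.startswith("firstorder."):
                assert shifted[name] == pytest.approx(base[name], rel=1e-9), name

    def test_all_finite_on_degenerate_rois(self):
        # constant, single-voxel and checkerboard ROIs
        vol = np.zeros((4, 6, 6))
        yy, xx = np.mgrid[0:6, 0:6]
        checker = 25.0 * ((yy + xx) % 2)
        cases = []
        m_const = np.zeros_like(vol, dtype=bool)
        m_const[:, :3, :3] = True
        cases.append((vol, m_const))
        m_single = np.zeros_like(vol, dtype=bool)
        m_single[0, 0, 0] = True
        cases.append((vol, m_single))
        vol_check = np.broadcast_to(checker, vol.shape).copy()
        m_all = np.ones_like(vol, dtype=bool)
        cases.append((vol_check, m_all))
        for voxels, mask in cases:
            fv = r.feature_vector(voxels, mask)
            assert all(np.isfinite(v) for v in fv.values())

    def test_extract_all_skips_empty_roi_and_continues(self, ground_truth):
        import pandas as pd

        vol, rois = ground_truth
        labels = rois.labels.copy()
        labels[labels == 1] = 0  # ROI 1 becomes empty
        broken = r.ROISet(labels, rois.class_of)
        df = r.extract_all(vol, broken)
        assert isinstance(df, pd.DataFrame)
        assert set(df["roi_id"].unique()) == set(range(2, 25))

    def test_mask_volume_shape_mismatch_rejected(self, ground_truth):
        vol, rois = ground_truth
        bad = r.ROISet(rois.labels[:, :64, :64], rois.class_of)
        with pytest.raises(ValueError, match="shape"):
            r.extract_all(vol, bad)


class TestMatrixOraclesOnRandomToys:
    """Every texture matrix equals brute-force enumeration on random toys."""

    def test_all_families_match_brute_force(self):
        rng = np.random.default_rng(7)
        dirs = [(0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1), (0, 1, -1),
                (1, 1, 0), (1, 0, 1), (1, 1, 1), (1, -1, -1)]
        for trial in range(25):
            disc = random_toy_roi(rng)
            ng = disc.n_levels
            for d in dirs:
                ref = brute_glcm(disc.grid, disc.mask, d, ng)
                if ref.sum() == 0:
                    continue
                mats = glcm_matrix(disc, directions=[d])
                assert np.allclose(mats[0], ref / ref.sum()), (trial, d)
                ref_r = brute_runs(disc.grid, disc.mask, d, ng)
                got_r = glrlm_matrix(disc, directions=[d])[0]
                assert np.array_equal(got_r, ref_r), (trial, d)
            assert np.array_equal(glszm_matrix(disc),
                                  brute_zones(disc.grid, disc.mask, ng)), trial
            for alpha in (0, 1):
                assert np.array_equal(
                    gldm_matrix(disc, alpha=alpha),
                    brute_gldm(disc.grid, disc.mask, alpha, ng)), (trial, alpha)
            n_i, _, s_i = ngtdm_table(disc)
            ref_n, ref_s = brute_ngtdm(disc.grid, disc.mask, ng)
            assert np.array_equal(n_i, ref_n), trial
            assert np.allclose(s_i, ref_s), trial
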