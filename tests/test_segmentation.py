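"""Segmentation methods: threshold formulas, the σ/μ volume-growing
rule, the Hessian vesselness response (against a brute-force
reimplementation), K-means classification and the hybrid combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from angioct import (LATParams, MSParams, ScalarVolume, SoftTissueStats,
                     apply_corrections, fit_soft_tissue, gt_segment,
                     lat_segment, lat_thresholds, ms_segment, mslat_segment,
                     multiscale_enhance, vesselness_response)
from angioct.segmentation import _eigvalsh3, _hessian_central

from conftest import cylinder_volume


class TestSoftTissueFit:
    def test_recovers_known_background_distribution(self):
        rng = np.random.default_rng(0)
        data = rng.normal(100.0, 10.0, size=(40, 40, 40))
        bright = rng.random(data.shape) < 0.01
        data[bright] = 500.0
        stats = fit_soft_tissue(ScalarVolume(data, 12.0), np.ones(data.shape, bool))
        assert stats.mu_st == pytest.approx(100.0, rel=0.05)
        assert stats.sigma_st == pytest.approx(10.0, rel=0.05)
        assert stats.h_max == pytest.approx(500.0, rel=0.05)

    def test_constant_volume_rejected(self):
        vol = ScalarVolume(np.full((20, 20, 20), 7.0), 12.0)
        with pytest.raises(ValueError, match="constant|degenerate"):
            fit_soft_tissue(vol, np.ones(vol.shape, bool))

    def test_tiny_voi_rejected(self):
        vol = ScalarVolume(np.random.default_rng(1).normal(size=(10, 10, 10)), 12.0)
        voi = np.zeros(vol.shape, bool)
        voi[:3, :3, :3] = True
        with pytest.raises(ValueError, match="1000"):
            fit_soft_tissue(vol, voi)

    def test_tau_is_cv(self):
        s = SoftTissueStats(mu_st=80.0, sigma_st=20.0, h_max=400.0)
        assert s.tau == 0.25


class TestLATThresholds:
    def test_printed_formula_values(self):
        s = SoftTissueStats(mu_st=100.0, sigma_st=10.0, h_max=400.0)
        p = lat_thresholds(s)
        assert p.t_low == pytest.approx(120.0)
        assert p.t_high == pytest.approx(260.0)

    def test_insufficient_contrast_rejected(self):
        s = SoftTissueStats(mu_st=100.0, sigma_st=10.0, h_max=180.0)
        with pytest.raises(ValueError, match="contrast"):
            lat_thresholds(s)  # t_low=120 >= t_high=117

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_thresholds_scale_linearly_with_intensity(self, c):
        s1 = SoftTissueStats(mu_st=100.0, sigma_st=10.0, h_max=400.0)
        s2 = SoftTissueStats(mu_st=100.0 * c, sigma_st=10.0 * c, h_max=400.0 * c)
        p1, p2 = lat_thresholds(s1), lat_thresholds(s2)
        assert p2.t_low == pytest.approx(c * p1.t_low)
        assert p2.t_high == pytest.approx(c * p1.t_high)


class TestLATSegment:
    def test_noiseless_two_valued_phantom_segmented_exactly(self):
        mask, vol = cylinder_volume((40, 40, 40), radius_um=36.0, voxel_size=12.0)
        stats = SoftTissueStats(mu_st=100.0, sigma_st=10.0, h_max=500.0)
        params = lat_thresholds(stats)  # t_high=325 < 500: all vessel voxels seed
        out = lat_segment(vol, np.ones(vol.shape, bool), params, stats)
        np.testing.assert_array_equal(out, mask)

    def test_boundary_cv_equal_to_alpha_tau_is_soft_tissue(self):
        # neighbourhood with σ/μ exactly == α·τ must NOT be grown into
        rng = np.random.default_rng(2)
        data = np.full((9, 9, 9), 100.0)
        data[4, 4, 4] = 300.0  # seed
        # make candidate voxel at (4,4,5) lie in [t_low, t_high)
        data[4, 4, 5] = 200.0
        stats = SoftTissueStats(mu_st=100.0, sigma_st=25.0, h_max=400.0)
        params = LATParams(alpha=1.0, t_low=150.0, t_high=260.0)
        from angioct.segmentation import neighbourhood_stats
        mean, sd = neighbourhood_stats(data)
        cv = sd[4, 4, 5] / mean[4, 4, 5]
        # pick τ exactly at the voxel's CV via alpha
        params = LATParams(alpha=cv / stats.tau, t_low=150.0, t_high=260.0)
        out = lat_segment(ScalarVolume(data, 12.0), np.ones(data.shape, bool),
                          params, stats)
        assert out[4, 4, 4] and not out[4, 4, 5]

    def test_result_contained_in_voi(self, small_phantom):
        _, _, mask, vol = small_phantom
        voi = np.zeros(vol.shape, bool)
        voi[30:90, 30:90, 30:90] = True
        stats = fit_soft_tissue(vol, voi)
        out = lat_segment(vol, voi, lat_thresholds(stats), stats)
        assert not (out & ~voi).any()

    def test_no_seeds_warns_and_returns_empty(self):
        vol = ScalarVolume(np.random.default_rng(3).normal(100, 5, (20, 20, 20)), 12.0)
        stats = SoftTissueStats(mu_st=100.0, sigma_st=5.0, h_max=10000.0)
        with pytest.warns(UserWarning, match="no seed"):
            out = lat_segment(vol, np.ones(vol.shape, bool),
                              LATParams(t_low=115.0, t_high=6500.0), stats)
        assert not out.any()

    def test_growth_is_superset_of_high_threshold_mask(self, small_phantom):
        _, _, _, vol = small_phantom
        voi = np.ones(vol.shape, bool)
        stats = fit_soft_tissue(vol, voi)
        params = lat_thresholds(stats)
        lat = lat_segment(vol, voi, params, stats)
        gt = gt_segment(vol, voi, params.t_high)
        assert (gt & ~lat).sum() == 0


class TestVesselnessResponse:
    def test_dark_or_planar_structures_get_zero(self):
        assert vesselness_response(-1.0, 0.5, 0.2) == 0.0
        assert vesselness_response(0.0, 0.0, 0.0) == 0.0

    def test_perfect_bright_tube_without_multiplier(self):
        p = MSParams(use_lambda_c_multiplier=False)
        assert vesselness_response(0.0, -1.0, -1.0, p) == pytest.approx(1.0)

    def test_hand_computed_exponential_case(self):
        # λ1=λ2=λ3=−1, α1=0.5 → exp(−1/(2·0.25)) = e⁻²
        p = MSParams(use_lambda_c_multiplier=False)
        assert vesselness_response(-1.0, -1.0, -1.0, p) == pytest.approx(np.exp(-2.0))

    def test_multiplier_scales_by_lambda_c(self):
        without = vesselness_response(-1.0, -2.0, -3.0, MSParams(use_lambda_c_multiplier=False))
        with_mult = vesselness_response(-1.0, -2.0, -3.0, MSParams())
        assert with_mult == pytest.approx(2.0 * without)  # λc = min(2, 3) = 2

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_response_nonnegative_and_zero_without_tubular_signature(self, a, b, c):
        l1, l2, l3 = sorted((a, b, c), reverse=True)
        r = vesselness_response(l1, l2, l3)
        assert r >= 0.0
        if min(-l2, -l3) <= 0:
            assert r == 0.0


class TestEigenSolver:
    def test_matches_lapack_on_random_symmetric_matrices(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(500, 3, 3))
        m = m + np.swapaxes(m, 1, 2)
        ours = _eigvalsh3(m[:, 0, 0], m[:, 0, 1], m[:, 0, 2],
                          m[:, 1, 1], m[:, 1, 2], m[:, 2, 2])
        ref = np.linalg.eigvalsh(m)  # ascending
        np.testing.assert_allclose(ours[0], ref[:, 2], atol=1e-9)
        np.testing.assert_allclose(ours[1], ref[:, 1], atol=1e-9)
        np.testing.assert_allclose(ours[2], ref[:, 0], atol=1e-9)


def brute_force_enhance(volume, voi, params):
    """Per-voxel reference: explicit Hessian, explicit eigen-solve."""
    data = np.asarray(volume.data, dtype=np.float64)
    out = np.zeros(data.shape)
    scales = [s / volume.spacing for s in params.scales_um(volume.spacing)]
    for s in scales:
        sm = ndimage.gaussian_filter(data, s)
        h = np.stack(_hessian_central(sm))  # reuse only the padding definition
        h11, h12, h13, h22, h23, h33 = (s * s * c for c in h)
        for idx in np.ndindex(data.shape):
            if not voi[idx]:
                continue
            m = np.array([[h11[idx], h12[idx], h13[idx]],
                          [h12[idx], h22[idx], h23[idx]],
                          [h13[idx], h23[idx], h33[idx]]])
            w = np.linalg.eigvalsh(m)
            r = vesselness_response(w[2], w[1], w[0], params)
            out[idx] = max(out[idx], r)
    out[~voi] = 0.0
    return out


class TestMultiscaleEnhance:
    def test_constant_volume_gives_zero_response(self):
        vol = ScalarVolume(np.full((20, 20, 20), 5.0), 12.0)
        out = multiscale_enhance(vol, np.ones(vol.shape, bool))
        assert np.all(out.data == 0.0)

    def test_matches_brute_force_reference_on_small_volume(self):
        rng = np.random.default_rng(5)
        data = rng.normal(100.0, 10.0, size=(16, 16, 16))
        data[6:10, 6:10, :] += 300.0
        vol = ScalarVolume(data, 12.0)
        voi = np.ones(vol.shape, bool)
        params = MSParams(scales=(12.0, 24.0))
        fast = multiscale_enhance(vol, voi, params).data
        slow = brute_force_enhance(vol, voi, params)
        # atol relative to the response scale: near-zero λc sign flips
        # between the two eigen-solvers are numerically meaningless
        np.testing.assert_allclose(fast, slow, rtol=1e-6, atol=1e-6 * slow.max())

    def test_cylinder_response_peaks_on_axis_at_matching_scale(self):
        # radius 2 voxels: response maximal on the axis, not the boundary
        mask, vol = cylinder_volume((40, 40, 40), radius_um=24.0, voxel_size=12.0)
        data = ndimage.gaussian_filter(vol.data.astype(float), 1.0)
        out = multiscale_enhance(ScalarVolume(data, 12.0), np.ones(vol.shape, bool))
        mid = out.data[20]
        peak = np.unravel_index(np.argmax(mid), mid.shape)
        assert abs(peak[0] - 19) <= 1 and abs(peak[1] - 19) <= 1

    def test_rotation_equivariance_for_axis_swap(self):
        rng = np.random.default_rng(6)
        data = rng.normal(100.0, 5.0, size=(24, 24, 24))
        data[:, 11:13, 11:13] += 300.0
        vol = ScalarVolume(data, 12.0)
        out = multiscale_enhance(vol, np.ones(vol.shape, bool)).data
        rot = np.rot90(data, axes=(0, 1)).copy()
        out_rot = multiscale_enhance(ScalarVolume(rot, 12.0),
                                     np.ones(rot.shape, bool)).data
        np.testing.assert_allclose(np.rot90(out, axes=(0, 1)), out_rot,
                                   rtol=1e-6, atol=1e-6 * out.max())


class TestMSSegment:
    def test_rare_bimodal_response_selects_high_mode(self):
        rng = np.random.default_rng(7)
        resp = np.zeros((20, 20, 20))
        bright = rng.random(resp.shape) < 0.01
        resp[bright] = 1.0
        out = ms_segment(ScalarVolume(resp, 12.0), np.ones(resp.shape, bool))
        np.testing.assert_array_equal(out, bright)

    def test_flat_response_warns_and_returns_empty(self):
        resp = ScalarVolume(np.zeros((10, 10, 10)), 12.0)
        with pytest.warns(UserWarning, match="flat"):
            out = ms_segment(resp, np.ones((10, 10, 10), bool))
        assert not out.any()


class TestGTSegment:
    @pytest.mark.parametrize("threshold,expect", [(50.0, "all"), (600.0, "none")])
    def test_extreme_thresholds(self, threshold, expect):
        _, vol = cylinder_volume((20, 20, 20), 24.0, 12.0)
        voi = np.ones(vol.shape, bool)
        out = gt_segment(vol, voi, threshold)
        assert out.sum() == (voi.sum() if expect == "all" else 0)

    def test_noiseless_phantom_exact(self):
        mask, vol = cylinder_volume((20, 20, 20), 24.0, 12.0)
        np.testing.assert_array_equal(gt_segment(vol, np.ones(vol.shape, bool), 300.0), mask)


class TestMSLAT:
    def test_empty_voi2s_reduces_to_lat(self, small_phantom):
        _, _, _, vol = small_phantom
        voi = np.ones(vol.shape, bool)
        stats = fit_soft_tissue(vol, voi)
        params = lat_thresholds(stats)
        hybrid = mslat_segment(vol, voi, np.zeros(vol.shape, bool), stats, params)
        np.testing.assert_array_equal(hybrid, lat_segment(vol, voi, params, stats))

    def test_hybrid_reduces_false_positives_near_bone(self):
        # beam-hardening-like intensity halo next to bone defeats the
        # intensity-based LAT; the shape-based MS side of the hybrid
        # should produce far fewer near-bone false positives
        from scipy import ndimage

        from angioct import CTSimParams, TreeParams, make_phantom
        from angioct.phantom import BonePhantomParams, generate_bone_phantom
        from angioct.voi import build_voi_set

        shape = (96, 96, 96)
        tp = TreeParams(domain_shape=shape, voxel_size=15.0, min_radius=15.0,
                        root_radius=60.0, rng_seed=30)
        _, vessels, _ = make_phantom(tp, CTSimParams(rng_seed=30))
        params = BonePhantomParams(gap_voxels=16, body_radius_fraction=0.28,
                                   sim=CTSimParams(rng_seed=31, noise_sigma=20.0),
                                   artifact_amplitude=150.0, artifact_decay_voxels=4.0)
        _, _, vol = generate_bone_phantom(shape, 15.0, params, vessel_mask=vessels)
        vois = build_voi_set(vol, [(10, 48, 48)], [(85, 48, 48)],
                             closing_radius=12, band_width_voxels=6)
        stats = fit_soft_tissue(vol, vois.voi_capsule)
        params_lat = lat_thresholds(stats)
        lat = lat_segment(vol, vois.voi_capsule, params_lat, stats)
        hybrid = mslat_segment(vol, vois.voi_1s, vois.voi_2s, stats, params_lat)
        not_vessel = ~ndimage.binary_dilation(vessels, iterations=1)
        fp_lat = (lat & vois.voi_2s & not_vessel).sum()
        fp_hybrid = (hybrid & vois.voi_2s & not_vessel).sum()
        assert fp_hybrid < fp_lat

    def test_empty_voi1s_reduces_to_ms(self, small_phantom):
        _, _, _, vol = small_phantom
        voi = np.ones(vol.shape, bool)
        stats = fit_soft_tissue(vol, voi)
        hybrid = mslat_segment(vol, np.zeros(vol.shape, bool), voi, stats)
        ms = ms_segment(multiscale_enhance(vol, voi), voi)
        np.testing.assert_array_equal(hybrid, ms)


class TestCorrections:
    def test_empty_corrections_identity(self):
        m = np.random.default_rng(8).random((10, 10, 10)) < 0.3
        np.testing.assert_array_equal(apply_corrections(m), m)

    def test_remove_everything(self):
        m = np.ones((5, 5, 5), bool)
        assert not apply_corrections(m, remove=m).any()

    def test_disjoint_add_increases_count(self):
        m = np.zeros((5, 5, 5), bool)
        m[0, 0, 0] = True
        add = np.zeros_like(m)
        add[4, 4, 4] = True
        assert apply_corrections(m, add=add).sum() == 2

    def test_overlapping_add_remove_rejected(self):
        m = np.zeros((5, 5, 5), bool)
        both = np.ones_like(m)
        with pytest.raises(ValueError, match="overlap"):
            apply_corrections(m, add=both, remove=both)
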