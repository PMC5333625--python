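"""Similarity fit, difference vectors, distortion estimation/correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clpointer import (DistortionField, PointPairSet, SimilarityTransform,
                       default_ground_truth, difference_vectors,
                       estimate_distortion_field, fit_similarity,
                       make_distortion_field, register_with_distortion,
                       simulate_pointer_pool, PointerGridSpec)

finite = st.floats(allow_nan=False, allow_infinity=False)


class TestSimilarityTransform:
    def test_hand_computed_mapping(self):
        # s=2, 90 deg CCW (pixel frame), t=(3,4): (1,0) -> (3,6)
        t = SimilarityTransform(scale=2.0, rotation=np.pi / 2, tx=3.0, ty=4.0)
        assert np.allclose(t.apply(np.array([1.0, 0.0])), [3.0, 6.0])

    def test_identity_leaves_points_unchanged(self):
        pts = np.array([[0.0, 0.0], [5.5, -2.25], [1e3, 1e-3]])
        assert np.allclose(SimilarityTransform.identity().apply(pts), pts)

    @settings(deadline=None, derandomize=True)
    @given(s=st.floats(0.01, 100.0), th=st.floats(-np.pi, np.pi),
           tx=st.floats(-1e3, 1e3), ty=st.floats(-1e3, 1e3))
    def test_inverse_round_trip(self, s, th, tx, ty):
        t = SimilarityTransform(s, th, tx, ty)
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [-3.0, 0.5]])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts,
                           atol=1e-9 * max(1.0, abs(tx), abs(ty)))

    def test_reflection_unrepresentable(self):
        with pytest.raises(ValueError, match="scale"):
            SimilarityTransform(scale=-1.0, rotation=0.0)

    def test_compose_matches_sequential_application(self):
        t1 = SimilarityTransform(1.5, 0.3, 2.0, -1.0)
        t2 = SimilarityTransform(0.7, -1.1, -4.0, 5.0)
        pts = np.array([[1.0, 1.0], [-2.0, 3.0]])
        assert np.allclose(t2.compose(t1).apply(pts), t2.apply(t1.apply(pts)))


def _brute_force_similarity(em, fm, s_grid, th_grid):
    """Independent oracle: grid search over (s, theta), optimal translation."""
    em_c, fm_c = em.mean(axis=0), fm.mean(axis=0)
    best = None
    for s in s_grid:
        for th in th_grid:
            a, b = s * np.cos(th), s * np.sin(th)
            rot = np.column_stack([a * em[:, 0] - b * em[:, 1],
                                   b * em[:, 0] + a * em[:, 1]])
            t_vec = fm_c - rot.mean(axis=0)
            cost = np.sum((rot + t_vec - fm) ** 2)
            if best is None or cost < best[0]:
                best = (cost, s, th)
    return best[1], best[2]


class TestFitSimilarity:
    def test_identity_pairs(self):
        pts = np.array([[0.0, 0.0], [3.0, 1.0], [1.0, 4.0]])
        t = fit_similarity((pts, pts))
        assert np.allclose([t.scale, t.rotation, t.tx, t.ty], [1, 0, 0, 0],
                           atol=1e-12)

    def test_exact_recovery_forward_constructed(self):
        em = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        fm = np.array([[3.0, 4.0], [3.0, 6.0], [1.0, 4.0]])
        t = fit_similarity((em, fm))
        assert np.allclose([t.scale, np.rad2deg(t.rotation), t.tx, t.ty],
                           [2.0, 90.0, 3.0, 4.0], atol=1e-12)

    def test_two_pairs_unique_zero_residual(self):
        em = np.array([[0.0, 0.0], [2.0, 1.0]])
        true = SimilarityTransform(1.3, 0.4, -2.0, 7.0)
        fm = true.apply(em)
        t = fit_similarity((em, fm))
        assert np.allclose(t.apply(em), fm, atol=1e-12)
        assert np.isclose(t.scale, 1.3) and np.isclose(t.rotation, 0.4)

    def test_errors_on_degenerate_input(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_similarity((np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]])))
        coincident = np.tile([1.0, 1.0], (3, 1))
        with pytest.raises(ValueError, match="singular|coincide"):
            fit_similarity((coincident, np.random.default_rng(0).random((3, 2))))

    @settings(deadline=None, derandomize=True)
    @given(s=st.floats(0.1, 10.0), th=st.floats(-3.1, 3.1),
           tx=st.floats(-100, 100), ty=st.floats(-100, 100),
           seed=st.integers(0, 100))
    def test_recovery_property(self, s, th, tx, ty, seed):
        rng = np.random.default_rng(seed)
        em = rng.uniform(-10, 10, size=(6, 2))
        t_true = SimilarityTransform(s, th, tx, ty)
        t = fit_similarity((em, t_true.apply(em)))
        assert np.isclose(t.scale, s, rtol=1e-9)
        assert np.isclose(np.cos(t.rotation - th), 1.0, atol=1e-9)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        em = rng.uniform(0, 10, size=(8, 2))
        fm = SimilarityTransform(2.0, np.deg2rad(30), 5.0, -3.0).apply(em)
        fm += rng.normal(0, 0.1, fm.shape)
        t = fit_similarity((em, fm))
        s_o, th_o = _brute_force_similarity(
            em, fm, np.linspace(1.9, 2.1, 81), np.deg2rad(np.linspace(28, 32, 81)))
        assert abs(t.scale - s_o) <= (2.1 - 1.9) / 80
        assert abs(t.rotation - th_o) <= np.deg2rad(4 / 80)

    def test_rigid_motion_composes_predictably(self):
        rng = np.random.default_rng(5)
        em = rng.uniform(0, 10, size=(12, 2))
        fm = SimilarityTransform(1.7, 0.2, 1.0, 2.0).apply(em)
        fm += rng.normal(0, 0.05, fm.shape)
        t0 = fit_similarity((em, fm))
        motion = SimilarityTransform(1.0, 0.7, -4.0, 9.0)  # rigid: s = 1
        t1 = fit_similarity((em, motion.apply(fm)))
        assert np.isclose(t1.scale, t0.scale, rtol=1e-9)
        assert np.isclose(t1.rotation, t0.rotation + 0.7, atol=1e-9)
        expect = motion.compose(t0)
        assert np.allclose([t1.tx, t1.ty], [expect.tx, expect.ty], atol=1e-9)

    def test_parameter_errors_shrink_as_inverse_sqrt_n(self):
        """Scale-error spread over noisy refits follows N^(-1/2)."""
        rng = np.random.default_rng(8)
        true = SimilarityTransform(0.05, 0.03, 10.0, 20.0)
        n_values = np.array([4, 16, 64, 256])
        sds = []
        for n in n_values:
            errs = []
            for _ in range(200):
                em = rng.uniform(0, 2e4, size=(n, 2))
                fm = true.apply(em) + rng.normal(0, 0.12, (n, 2))
                errs.append(fit_similarity((em, fm)).scale - true.scale)
            sds.append(np.std(errs))
        slope = np.polyfit(np.log(n_values), np.log(sds), 1)[0]
        assert -0.6 <= slope <= -0.4


class TestDifferenceVectors:
    def test_zero_for_exact_pairs(self):
        em = np.random.default_rng(0).uniform(0, 10, size=(9, 2))
        t = SimilarityTransform(1.2, 0.1, 3.0, -1.0)
        pairs = PointPairSet(em, t.apply(em), np.arange(9))
        dvs = difference_vectors(pairs)
        assert np.abs(dvs.delta_px).max() < 1e-9

    def test_least_squares_orthogonality(self):
        """Sum of residuals and their scale/rotation projections vanish."""
        rng = np.random.default_rng(1)
        em = rng.uniform(0, 100, size=(50, 2))
        fm = SimilarityTransform(1.1, 0.05, 4.0, 2.0).apply(em)
        fm += rng.normal(0, 0.5, fm.shape)
        pairs = PointPairSet(em, fm, np.arange(50))
        d = difference_vectors(pairs).delta_px
        assert np.abs(d.sum(axis=0)).max() < 1e-6
        # projections on d/da = (x, y) and d/db = (-y, x)
        proj_a = np.sum(em[:, 0] * d[:, 0] + em[:, 1] * d[:, 1])
        proj_b = np.sum(-em[:, 1] * d[:, 0] + em[:, 0] * d[:, 1])
        assert abs(proj_a) < 1e-6 and abs(proj_b) < 1e-6

    def test_recovers_injected_distortion(self, calibration_grid):
        gt0 = default_ground_truth(seed=6, jitter_sigma_nm=0.0)
        lattice = gt0.true_transform.compose(
            SimilarityTransform(scale=calibration_grid.spacing_px, rotation=0.0))
        field = make_distortion_field((25, 25), seed=6, grid_to_fm=lattice)
        gt = default_ground_truth(seed=6, jitter_sigma_nm=0.0, distortion=field)
        pool = simulate_pointer_pool(calibration_grid, gt, 1)
        dvs = difference_vectors(pool.array(0), gt.true_transform,
                                 fm_pixel_size_nm=gt.fm_pixel_size_nm)
        assert np.allclose(dvs.delta_nm, field.vectors_nm.reshape(-1, 2),
                           atol=2.0)  # 0.02 px at 100 nm/px


class TestDistortionField:
    def test_bilinear_interpolation_at_and_between_nodes(self):
        field = make_distortion_field((5, 5), max_magnitude_nm=100.0, seed=1,
                                      anomaly_count=0, node_spacing_px=10.0)
        nodes = field.node_xy_px.reshape(-1, 2)
        assert np.allclose(field.evaluate(nodes),
                           field.vectors_nm.reshape(-1, 2), atol=1e-9)
        mid = (field.node_xy_px[0, 0] + field.node_xy_px[0, 1]) / 2
        expect = (field.vectors_nm[0, 0] + field.vectors_nm[0, 1]) / 2
        assert np.allclose(field.evaluate(mid), expect, atol=1e-9)

    def test_outside_coverage_warns_or_raises(self):
        field = make_distortion_field((5, 5), seed=1, node_spacing_px=10.0)
        far = np.array([[1e4, 1e4]])
        with pytest.warns(UserWarning, match="outside"):
            v = field.evaluate(far)
        assert np.allclose(v, field.vectors_nm[-1, -1])
        with pytest.raises(ValueError, match="outside"):
            field.evaluate(far, strict=True)

    def test_json_round_trip(self, tmp_path):
        from clpointer.io import read_field, write_field

        field = make_distortion_field((7, 7), seed=2)
        write_field(tmp_path / "f.json", field)
        back = read_field(tmp_path / "f.json")
        assert np.allclose(back.vectors_nm, field.vectors_nm)
        assert np.array_equal(back.anomaly, field.anomaly)


@pytest.fixture(scope="module")
def noisy_stack(calibration_grid):
    gt0 = default_ground_truth(seed=4)
    lattice = gt0.true_transform.compose(
        SimilarityTransform(scale=calibration_grid.spacing_px, rotation=0.0))
    field = make_distortion_field((25, 25), seed=4, grid_to_fm=lattice)
    gt = default_ground_truth(seed=4, jitter_sigma_nm=12.0, distortion=field)
    pool = simulate_pointer_pool(calibration_grid, gt, 50)
    stack = [difference_vectors(pool.array(i), fm_pixel_size_nm=100.0)
             for i in range(50)]
    return field, stack


class TestEstimateDistortionField:
    def test_mean_recovery_within_two_standard_errors(self, noisy_stack):
        field, stack = noisy_stack
        est = estimate_distortion_field(stack, (25, 25), 100.0)
        diff = (est.vectors_nm - field.vectors_nm).reshape(-1, 2)
        se_radial = np.sqrt(2.0) * (est.sd_nm / np.sqrt(est.counts)).reshape(-1)
        coverage = np.mean(np.linalg.norm(diff, axis=1) <= 2 * se_radial)
        assert coverage >= 0.95

    def test_injected_anomalies_flagged(self, noisy_stack):
        field, stack = noisy_stack
        est = estimate_distortion_field(stack, (25, 25), 100.0)
        assert (est.anomaly & field.anomaly).sum() == field.anomaly.sum() == 3

    def test_single_zero_noise_array_reproduced_exactly(self, calibration_grid):
        gt = default_ground_truth(seed=9, jitter_sigma_nm=0.0)
        pool = simulate_pointer_pool(calibration_grid, gt, 1)
        dvs = difference_vectors(pool.array(0), fm_pixel_size_nm=100.0)
        est = estimate_distortion_field([dvs], (25, 25), 100.0)
        assert np.allclose(est.vectors_nm.reshape(-1, 2), dvs.delta_nm, atol=1e-9)

    def test_standard_error_shrinks_as_inverse_sqrt_arrays(self, calibration_grid):
        gt = default_ground_truth(seed=4, jitter_sigma_nm=12.0)
        ms, ses = [], []
        for m in (4, 16, 64):
            pool = simulate_pointer_pool(calibration_grid, gt, m,
                                         rng=np.random.default_rng(11))
            stack = [difference_vectors(pool.array(i), fm_pixel_size_nm=100.0)
                     for i in range(m)]
            est = estimate_distortion_field(stack, (25, 25), 100.0)
            ms.append(m)
            ses.append(float((est.sd_nm / np.sqrt(est.counts)).mean()))
        slope = np.polyfit(np.log(ms), np.log(ses), 1)[0]
        assert -0.6 <= slope <= -0.4

    def test_mismatched_grid_rejected(self, calibration_grid):
        gt = default_ground_truth(seed=0)
        pool = simulate_pointer_pool(calibration_grid, gt, 1)
        dvs = difference_vectors(pool.array(0), fm_pixel_size_nm=100.0)
        with pytest.raises(ValueError, match="grid"):
            estimate_distortion_field([dvs], (5, 5), 100.0)


class TestRegisterWithDistortion:
    def test_none_field_equals_plain_fit(self):
        rng = np.random.default_rng(2)
        em = rng.uniform(0, 100, size=(16, 2))
        fm = SimilarityTransform(0.9, -0.2, 8.0, 1.0).apply(em)
        pairs = PointPairSet(em, fm, np.arange(16))
        t_plain = fit_similarity(pairs)
        t_corr, _ = register_with_distortion(pairs, None)
        assert np.allclose([t_corr.scale, t_corr.rotation, t_corr.tx, t_corr.ty],
                           [t_plain.scale, t_plain.rotation, t_plain.tx, t_plain.ty])

    def test_zero_noise_distorted_scene_fully_corrected(self, calibration_grid):
        gt0 = default_ground_truth(seed=3)
        lattice = gt0.true_transform.compose(
            SimilarityTransform(scale=calibration_grid.spacing_px, rotation=0.0))
        field = make_distortion_field((25, 25), seed=3, grid_to_fm=lattice)
        gt = default_ground_truth(seed=3, jitter_sigma_nm=0.0, distortion=field)
        pool = simulate_pointer_pool(calibration_grid, gt, 1)
        _, dvs = register_with_distortion(pool.array(0), field)
        assert np.abs(dvs.delta_px).max() < 0.02

    @pytest.mark.filterwarnings("ignore:.*outside the calibrated.*")
    def test_correction_reduces_residual_rms_under_noise(self):
        grid = PointerGridSpec(4, 4, spacing_px=6000.0)
        wins = 0
        for seed in range(20):
            gt0 = default_ground_truth(seed=seed)
            lattice = gt0.true_transform.compose(
                SimilarityTransform(scale=grid.spacing_px, rotation=0.0))
            field = make_distortion_field((4, 4), seed=seed, grid_to_fm=lattice)
            gt = default_ground_truth(seed=seed, jitter_sigma_nm=12.0,
                                      distortion=field)
            pool = simulate_pointer_pool(grid, gt, 1)
            pairs = pool.array(0)
            raw = difference_vectors(pairs).rms_px
            _, dvs = register_with_distortion(pairs, field)
            wins += dvs.rms_px < raw
        assert wins >= 18
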