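"""Artifact detection, interpolation, CompCor, high-pass, cleaning order."""

import numpy as np
import pytest

from movieloc.dataset_io import Parcel
from movieloc.preprocess import (ArtifactMask, build_nuisance_set,
                                 clean_voxel_timecourses, compute_compcor,
                                 detect_artifact_timepoints, erode_mask,
                                 highpass_filter, interpolate_artifacts,
                                 roi_mean_timecourse, subject_passes_qc)


def _flat_motion(T):
    return np.zeros((T, 6))


class TestArtifactDetection:
    def test_translation_jump_flags_only_that_tr(self):
        m = _flat_motion(20)
        m[10:, 0] = 2.5
        mask = detect_artifact_timepoints(m, np.zeros(20))
        assert list(mask.flagged_trs) == [10]

    def test_global_signal_excursion_flags_only_that_tr(self, rng):
        gs = rng.normal(0, 1, 200)
        gs[3] = gs.mean() + 10 * gs.std(ddof=1)
        mask = detect_artifact_timepoints(_flat_motion(200), gs)
        assert 3 in mask.flagged_trs
        # re-check the rule: every flagged TR really exceeds 3 SD
        sd = gs.std(ddof=1)
        for t in mask.flagged_trs:
            assert abs(gs[t] - gs.mean()) > 3 * sd

    def test_exactly_2mm_not_flagged(self):
        # the motion criterion is a strict inequality
        m = _flat_motion(10)
        m[5:, 1] = 2.0
        mask = detect_artifact_timepoints(m, np.zeros(10))
        assert mask.n_flagged == 0

    def test_rotation_converted_via_head_sphere(self):
        # 0.05 rad on a 65 mm sphere is a 3.25 mm arc -> flagged
        m = _flat_motion(10)
        m[4:, 3] = 0.05
        mask = detect_artifact_timepoints(m, np.zeros(10))
        assert list(mask.flagged_trs) == [4]


class TestQC:
    @pytest.mark.parametrize("n_flagged,expected", [(56, False), (55, True), (0, True)])
    def test_one_third_rule(self, n_flagged, expected):
        flags = np.zeros(168, dtype=bool)
        flags[:n_flagged] = True
        assert subject_passes_qc(ArtifactMask(flags)) is expected


class TestInterpolation:
    def test_nearest_neighbor_tie_breaks_earlier(self):
        mask = ArtifactMask(np.array([False, False, True, False]))
        out = interpolate_artifacts(np.array([1.0, 2.0, 9.0, 4.0]), mask)
        assert list(out) == [1.0, 2.0, 2.0, 4.0]

    def test_leading_artifact_takes_first_good_value(self):
        mask = ArtifactMask(np.array([True, True, False, False]))
        out = interpolate_artifacts(np.array([9.0, 9.0, 3.0, 4.0]), mask)
        assert list(out) == [3.0, 3.0, 3.0, 4.0]

    def test_empty_mask_is_identity(self, rng):
        v = rng.standard_normal(10)
        out = interpolate_artifacts(v, ArtifactMask(np.zeros(10, dtype=bool)))
        assert np.array_equal(out, v)

    def test_all_flagged_is_an_error(self):
        with pytest.raises(ValueError, match="all TRs flagged"):
            interpolate_artifacts(np.zeros(4), ArtifactMask(np.ones(4, dtype=bool)))


class TestErosion:
    def _cube(self, n):
        m = np.zeros((n + 4, n + 4, n + 4), dtype=bool)
        m[2:2 + n, 2:2 + n, 2:2 + n] = True
        return Parcel(m, "cube")

    def test_two_iterations_on_5cube_leaves_center(self):
        out = erode_mask(self._cube(5), 2)
        assert out.n_voxels == 1

    def test_one_iteration_on_5cube_leaves_3cube(self):
        out = erode_mask(self._cube(5), 1)
        assert out.n_voxels == 27

    def test_3cube_empties_with_error(self):
        with pytest.raises(ValueError, match="empty"):
            erode_mask(self._cube(3), 2)


class TestCompCor:
    def test_rank2_data_recovers_exact_factors(self, rng):
        T, V = 60, 30
        c1 = np.sin(np.linspace(0, 6 * np.pi, T))
        c2 = np.cos(np.linspace(0, 10 * np.pi, T))
        c1 -= c1.mean(); c2 -= c2.mean()
        load = rng.standard_normal((V, 2))
        wm = load @ np.vstack([5 * c1, 2 * c2])
        comps, degen = compute_compcor(wm, None, n_components=5)
        assert degen == [False, False, True, True, True]
        # recovered 2D subspace matches span{c1, c2}
        A = np.linalg.qr(np.column_stack([c1, c2]))[0]
        B = comps[:, :2]
        proj = A @ A.T @ B
        assert np.linalg.norm(proj - B) < 1e-6

    def test_components_orthogonal_zero_mean(self, rng):
        wm = rng.standard_normal((40, 80))
        comps, _ = compute_compcor(wm, None)
        G = comps.T @ comps
        assert np.all(np.abs(G - np.diag(np.diag(G))) < 1e-10)
        assert np.all(np.abs(comps.mean(axis=0)) < 1e-12)

    def test_matches_brute_force_eigendecomposition(self, rng):
        # independent oracle: eigenvectors of the T x T covariance of the
        # demeaned voxel matrix
        wm = rng.standard_normal((20, 50))
        comps, _ = compute_compcor(wm, None, n_components=5)
        X = wm - wm.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        for k in range(5):
            v = evecs[:, order[k]]
            if np.dot(v, comps[:, k]) < 0:
                v = -v
            assert np.max(np.abs(v - comps[:, k])) < 1e-8

    def test_scrubbing_before_decomposition(self, rng):
        wm = rng.standard_normal((10, 30))
        flags = np.zeros(30, dtype=bool)
        flags[7] = True
        comps_scrub, _ = compute_compcor(wm, ArtifactMask(flags))
        scrubbed = interpolate_artifacts(wm, ArtifactMask(flags))
        comps_manual, _ = compute_compcor(scrubbed, None)
        assert np.allclose(comps_scrub, comps_manual)


class TestHighpass:
    def test_constant_input_zeroed(self):
        out = highpass_filter(np.full(168, 3.7), tr_s=2.0)
        assert np.max(np.abs(out)) < 1e-10

    def test_slow_sinusoid_removed(self):
        t = np.arange(168) * 2.0
        slow = np.sin(2 * np.pi * t / 200.0)
        out = highpass_filter(slow, tr_s=2.0, cutoff_s=100.0)
        assert out.var() < 0.10 * slow.var()

    def test_fast_sinusoid_preserved(self):
        t = np.arange(168) * 2.0
        fast = np.sin(2 * np.pi * t / 20.0)
        out = highpass_filter(fast, tr_s=2.0, cutoff_s=100.0)
        assert out.var() > 0.95 * fast.var()

    def test_cutoff_below_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            highpass_filter(np.zeros(100), tr_s=2.0, cutoff_s=3.0)


class TestCleaning:
    def test_voxel_equal_to_component_is_annihilated(self, rng):
        T = 100
        comp = rng.standard_normal(T)
        comp -= comp.mean(); comp /= np.linalg.norm(comp)
        mask = ArtifactMask(np.zeros(T, dtype=bool))
        nuis = build_nuisance_set(mask, comp[:, None])
        out = clean_voxel_timecourses(comp[None, :], mask, nuis, tr_s=2.0,
                                      cutoff_s=1e9)
        assert np.max(np.abs(out)) < 1e-8

    def test_no_nuisance_reduces_to_highpass(self, rng):
        v = rng.standard_normal((3, 168))
        mask = ArtifactMask(np.zeros(168, dtype=bool))
        out = clean_voxel_timecourses(v, mask, None, tr_s=2.0)
        assert np.allclose(out, highpass_filter(v, tr_s=2.0))

    def test_spike_column_zeroes_artifact_tr(self, rng):
        T = 50
        v = rng.standard_normal(T)
        flags = np.zeros(T, dtype=bool)
        flags[17] = True
        mask = ArtifactMask(flags)
        nuis = build_nuisance_set(mask, np.empty((T, 0)))
        out = clean_voxel_timecourses(v[None, :], mask, nuis, tr_s=2.0,
                                      cutoff_s=1e9)
        assert abs(out[0, 17]) < 1e-10

    def test_residuals_orthogonal_to_nuisance(self, rng):
        T = 120
        comps = rng.standard_normal((T, 3))
        comps -= comps.mean(axis=0)
        comps, _ = np.linalg.qr(comps)
        flags = np.zeros(T, dtype=bool)
        flags[[5, 50]] = True
        mask = ArtifactMask(flags)
        nuis = build_nuisance_set(mask, comps)
        Y = rng.standard_normal((10, T))
        out = clean_voxel_timecourses(Y, mask, nuis, tr_s=2.0, cutoff_s=1e9)
        dots = np.abs(out @ nuis.matrix)
        scale = np.linalg.norm(out, axis=1)[:, None] * \
            np.linalg.norm(nuis.matrix, axis=0)[None, :]
        assert np.all(dots < 1e-8 * np.maximum(scale, 1))

    def test_cleaned_residuals_decorrelated_from_planted_components(self, rng):
        # statistical invariant at T=168: after the full clean (including
        # the high-pass), residual correlation with each planted component
        # stays small across seeds
        for seed in range(5):
            g = np.random.default_rng(seed)
            T = 168
            comps = g.standard_normal((T, 3))
            comps -= comps.mean(axis=0)
            comps, _ = np.linalg.qr(comps)
            mask = ArtifactMask(np.zeros(T, dtype=bool))
            nuis = build_nuisance_set(mask, comps)
            Y = g.standard_normal((20, T)) \
                + (comps @ np.array([2.0, 1.0, 1.5]))[None, :]
            out = clean_voxel_timecourses(Y, mask, nuis, tr_s=2.0)
            for j in range(3):
                r = np.corrcoef(out.mean(axis=0), comps[:, j])[0, 1]
                assert abs(r) < 0.05

    def test_regression_then_filter_differs_from_filter_then_regression(self, rng):
        # the prescribed stage order matters and is fixed
        T = 168
        comp = np.cumsum(rng.standard_normal(T))
        comp = comp - comp.mean()
        comp /= np.linalg.norm(comp)
        mask = ArtifactMask(np.zeros(T, dtype=bool))
        nuis = build_nuisance_set(mask, comp[:, None])
        Y = rng.standard_normal((1, T)) + 3 * comp[None, :]
        correct = clean_voxel_timecourses(Y, mask, nuis, tr_s=2.0)
        hp_first = highpass_filter(Y, tr_s=2.0)
        X = np.column_stack([np.ones(T), comp])
        swapped = (hp_first.T - X @ np.linalg.pinv(X) @ hp_first.T).T
        assert not np.allclose(correct, swapped, atol=1e-10)


class TestRoiMean:
    def test_identical_voxels_and_nan_rule(self, rng):
        v = rng.standard_normal(20)
        mat = np.vstack([v, v])
        flags = np.zeros(20, dtype=bool)
        flags[7] = True
        tc = roi_mean_timecourse(mat, np.array([0, 1]), ArtifactMask(flags))
        assert np.isnan(tc.values[7])
        good = ~np.isnan(tc.values)
        assert np.allclose(tc.values[good], v[good])

    def test_single_voxel_identity(self, rng):
        v = rng.standard_normal(10)
        tc = roi_mean_timecourse(v[None, :], np.array([0]), None)
        assert np.allclose(tc.values, v)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean_timecourse(np.zeros((2, 5)), np.array([], dtype=int), None)
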