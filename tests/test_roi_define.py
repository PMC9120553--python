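"""Top-k selection, predictor sets, movie ssROIs, split-half splice."""

import numpy as np
import pytest

from movieloc.dataset_io import Parcel
from movieloc.glm import TMap
from movieloc.roi_define import (PredictorSet, REGION_CONTRASTS,
                                 build_predictor_set, define_movie_ssroi,
                                 split_half_define_extract, top_k_voxels)
from movieloc.synthio import (REGIONS, CohortConfig, simulate_cohort)
from movieloc.timecourse import Timecourse


def _parcel(n, offset=0, shape=(10, 10, 10)):
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[offset:offset + n] = True
    return Parcel(mask, "P")


class TestTopK:
    def test_saturating_parcel_returns_everything(self, rng):
        parcel = _parcel(100)
        tmap = TMap(rng.standard_normal(100), df=50,
                    voxel_indices=parcel.linear_indices)
        for tail in ("top", "bottom"):
            roi = top_k_voxels(tmap, parcel, k=100, tail=tail)
            assert set(roi.voxels) == set(parcel.linear_indices)

    def test_top_and_bottom_disjoint(self, rng):
        parcel = _parcel(300)
        tmap = TMap(rng.standard_normal(300), df=50,
                    voxel_indices=parcel.linear_indices)
        top = top_k_voxels(tmap, parcel, k=100, tail="top")
        bottom = top_k_voxels(tmap, parcel, k=100, tail="bottom")
        assert not set(top.voxels) & set(bottom.voxels)

    def test_noiseless_planted_recovery(self, rng):
        parcel = _parcel(300)
        t = np.zeros(300)
        planted = rng.choice(300, 100, replace=False)
        t[planted] = 5.0
        tmap = TMap(t, df=50, voxel_indices=parcel.linear_indices)
        roi = top_k_voxels(tmap, parcel, k=100, tail="top")
        assert set(roi.voxels) == set(parcel.linear_indices[planted])

    def test_ties_break_by_ascending_index(self):
        parcel = _parcel(10)
        tmap = TMap(np.ones(10), df=5, voxel_indices=parcel.linear_indices)
        roi = top_k_voxels(tmap, parcel, k=4, tail="top")
        assert list(roi.voxels) == list(parcel.linear_indices[:4])

    def test_all_nan_rejected(self):
        parcel = _parcel(5)
        tmap = TMap(np.full(5, np.nan), df=5,
                    voxel_indices=parcel.linear_indices)
        with pytest.raises(ValueError, match="NaN"):
            top_k_voxels(tmap, parcel, k=3)


class TestPredictorSet:
    def _tcs(self, values):
        return {s: {"FFA": Timecourse(np.asarray(v, dtype=float))}
                for s, v in values.items()}

    def test_leave_one_out_of_two_equals_the_other(self):
        tcs = self._tcs({"s1": [1, 2, 3], "s2": [4, 5, 6]})
        ps = build_predictor_set(tcs, leave_out_id="s1")
        assert np.allclose(ps.predictors["FFA"].values, [4, 5, 6])
        assert ps.left_out == "s1" and ps.contributors == ["s2"]

    def test_identical_subjects_mean_equals_any(self):
        tcs = self._tcs({"s1": [1, 2, 3], "s2": [1, 2, 3]})
        ps = build_predictor_set(tcs)
        assert np.allclose(ps.predictors["FFA"].values, [1, 2, 3])

    def test_per_tr_missing_rule(self):
        tcs = self._tcs({"s1": [1, np.nan, 3], "s2": [3, 4, 5]})
        ps = build_predictor_set(tcs)
        assert np.allclose(ps.predictors["FFA"].values, [2, 4, 4])

    def test_all_missing_tr_stays_missing(self):
        tcs = self._tcs({"s1": [1, np.nan, 3], "s2": [3, np.nan, 5]})
        ps = build_predictor_set(tcs)
        assert np.isnan(ps.predictors["FFA"].values[1])


def _noiseless_cohort(seed=21):
    cfg = CohortConfig(groups={"adult": 1}, voxel_noise_sd=0.0,
                       shared_noise_sd=0.0,
                       artifact_rate={"adult": 0.0, "child": 0.0},
                       n_localizer_runs=0)
    return simulate_cohort(cfg, seed=seed)


def _latent_predictors(cohort, anti=-0.15):
    lat = {r: cohort.manifest.latent_array(r) for r in REGIONS}
    preds = {r: Timecourse(lat[r]) for r in REGIONS}
    preds.update({f"{r}_counter": Timecourse(anti * lat[r]) for r in REGIONS})
    return PredictorSet(preds, source="noiseless latents")


class TestMovieSsroi:
    def test_recovery_with_default_noise(self):
        cfg = CohortConfig(groups={"adult": 1}, voxel_noise_sd=0.5,
                           n_localizer_runs=0)
        cohort = simulate_cohort(cfg, seed=13)
        preds = _latent_predictors(cohort)
        sim = next(iter(cohort.subjects.values()))
        for region in ("FFA", "PPA"):
            roi = define_movie_ssroi(sim.movie_parcel_data[region], preds,
                                     cohort.geometry.parcels[region], region)
            planted = set(cohort.manifest.regions[region]["selective_voxels"])
            got = set(int(v) for v in roi.voxels)
            dice = 2 * len(planted & got) / (len(planted) + len(got))
            assert dice >= 0.9

    def test_voxel_tracking_negative_predictor_ranks_low(self):
        cfg = CohortConfig(groups={"adult": 1}, voxel_noise_sd=0.5,
                           n_localizer_runs=0)
        cohort = simulate_cohort(cfg, seed=8)
        preds = _latent_predictors(cohort)
        sim = next(iter(cohort.subjects.values()))
        data = sim.movie_parcel_data["FFA"].copy()
        data[0] = cohort.manifest.latent_array("LOC")  # voxel = LOC predictor
        from movieloc.roi_define import _movie_tmap
        tmap = _movie_tmap(data, preds, "FFA", REGION_CONTRASTS,
                           cohort.geometry.parcels["FFA"].linear_indices)
        assert tmap.values[0] < np.median(tmap.values)

    def test_invariant_to_predictor_order(self, rng):
        cfg = CohortConfig(groups={"adult": 1}, n_localizer_runs=0)
        cohort = simulate_cohort(cfg, seed=5)
        lat = {r: cohort.manifest.latent_array(r) for r in REGIONS}
        noise = {r: rng.standard_normal(168) * 0.05 for r in REGIONS}
        base = {**{r: Timecourse(lat[r]) for r in REGIONS},
                **{f"{r}_counter": Timecourse(-0.15 * lat[r] + noise[r])
                   for r in REGIONS}}
        shuffled_names = list(base)[::-1]
        sim = next(iter(cohort.subjects.values()))
        roi1 = define_movie_ssroi(sim.movie_parcel_data["FFA"],
                                  PredictorSet(dict(base)),
                                  cohort.geometry.parcels["FFA"], "FFA")
        roi2 = define_movie_ssroi(sim.movie_parcel_data["FFA"],
                                  PredictorSet({n: base[n] for n in shuffled_names}),
                                  cohort.geometry.parcels["FFA"], "FFA")
        assert np.array_equal(roi1.voxels, roi2.voxels)

    def test_exactly_collinear_counters_pruned_not_fatal(self):
        cohort = _noiseless_cohort()
        preds = _latent_predictors(cohort)  # counters exactly -0.15 x latent
        sim = next(iter(cohort.subjects.values()))
        roi = define_movie_ssroi(sim.movie_parcel_data["FFA"], preds,
                                 cohort.geometry.parcels["FFA"], "FFA")
        planted = set(cohort.manifest.regions["FFA"]["selective_voxels"])
        assert set(int(v) for v in roi.voxels) == planted


class TestSplitHalf:
    def test_splice_length_and_guard_exclusion(self):
        cohort = _noiseless_cohort()
        preds = _latent_predictors(cohort)
        sim = next(iter(cohort.subjects.values()))
        res = split_half_define_extract(sim.movie_parcel_data, preds,
                                        cohort.geometry.parcels)
        assert all(len(tc) == 165 for tc in res.spliced.values())
        # the 3 guard TRs (0-based 82..84) never contribute
        assert not set(res.kept_trs) & {82, 83, 84}
        assert res.kept_trs.size == 165

    def test_noiseless_splice_matches_latent(self):
        cohort = _noiseless_cohort()
        preds = _latent_predictors(cohort)
        sim = next(iter(cohort.subjects.values()))
        res = split_half_define_extract(sim.movie_parcel_data, preds,
                                        cohort.geometry.parcels)
        for region in REGIONS:
            latent = cohort.manifest.latent_array(region)[res.kept_trs]
            r = np.corrcoef(res.spliced[region].values, latent)[0, 1]
            assert r > 0.99

    def test_crossed_extraction(self):
        # half-A timecourse must come from half-B-defined ROIs: plant a
        # voxel set that only half B's data can select
        cohort = _noiseless_cohort()
        preds = _latent_predictors(cohort)
        sim = next(iter(cohort.subjects.values()))
        res = split_half_define_extract(sim.movie_parcel_data, preds,
                                        cohort.geometry.parcels)
        for region in REGIONS:
            assert res.rois_half_a[region].method == "movie_half_A"
            assert res.rois_half_b[region].method == "movie_half_B"

    def test_too_short_run_rejected(self):
        cohort = _noiseless_cohort()
        preds = _latent_predictors(cohort)
        sim = next(iter(cohort.subjects.values()))
        with pytest.raises(ValueError, match="too short"):
            split_half_define_extract(sim.movie_parcel_data, preds,
                                      cohort.geometry.parcels, split_tr=167)
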