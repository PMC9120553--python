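"""Generator contracts: latent structure, localizer timing, planted effects."""

import numpy as np
import pytest

from movieloc.preprocess import composite_displacement, detect_artifact_timepoints
from movieloc.synthio import (REGIONS, CohortConfig, default_latent_corr,
                              make_latent_timecourses, make_localizer_timing,
                              simulate_cohort)


class TestLatents:
    def test_identity_corr_gives_uncorrelated_latents(self):
        # Fisher-z sampling error at T=10000 keeps |r| under 0.05
        tcs = make_latent_timecourses(10000, ["a", "b", "c"], np.eye(3),
                                      smooth_fwhm_trs=3.0, seed=42)
        M = np.column_stack([tcs[k].values for k in ["a", "b", "c"]])
        C = np.corrcoef(M.T)
        off = C[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_planted_correlation_recovered(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        tcs = make_latent_timecourses(10000, ["FFA", "LOC"], corr, seed=7)
        r = np.corrcoef(tcs["FFA"].values, tcs["LOC"].values)[0, 1]
        assert 0.75 <= r <= 0.85

    def test_deterministic_under_fixed_seed(self):
        a = make_latent_timecourses(200, REGIONS, default_latent_corr(), seed=5)
        b = make_latent_timecourses(200, REGIONS, default_latent_corr(), seed=5)
        for r in REGIONS:
            assert np.array_equal(a[r].values, b[r].values)

    def test_standardized_output(self):
        tcs = make_latent_timecourses(168, ["x"], np.eye(1), seed=1)
        v = tcs["x"].values
        assert abs(v.mean()) < 1e-12 and abs(v.std(ddof=1) - 1) < 1e-12

    def test_non_psd_corr_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            make_latent_timecourses(100, ["a", "b"], bad)


class TestLocalizerTiming:
    def test_total_run_length(self):
        timing = make_localizer_timing(seed=0)
        # 16 stimulus + 5 fixation blocks of 19.8 s each
        assert timing.total_duration_s + 19.8 == pytest.approx(415.8)
        assert len(timing.table) == 16

    def test_each_palindrome_mirrors_its_first_half(self):
        timing = make_localizer_timing(seed=3)
        order = timing.table.sort_values("onset_s")["condition"].tolist()
        for p in range(2):
            palindrome = order[p * 8:(p + 1) * 8]
            assert palindrome[4:] == palindrome[:4][::-1]

    def test_seeds_vary_the_permutation(self):
        firsts = set()
        for seed in range(6):
            t = make_localizer_timing(seed=seed)
            order = tuple(t.table.sort_values("onset_s")["condition"][:4])
            firsts.add(order)
        assert len(firsts) > 1

    def test_fixation_slots_are_empty(self):
        # fixation occupies block slots 0, 5, 10, 15, 20 of the 21-block run
        timing = make_localizer_timing(seed=1)
        onsets = set(np.round(timing.table["onset_s"] / 19.8).astype(int))
        assert onsets == set(range(21)) - {0, 5, 10, 15, 20}


class TestPlantedGroundTruth:
    def test_noiseless_parcel_mean_equals_latent(self):
        cfg = CohortConfig(groups={"adult": 1}, voxel_noise_sd=0.0,
                           shared_noise_sd=0.0,
                           artifact_rate={"adult": 0.0, "child": 0.0},
                           selectivity_weight=1.0, n_localizer_runs=0)
        cohort = simulate_cohort(cfg, seed=2)
        sim = next(iter(cohort.subjects.values()))
        lin = cohort.geometry.parcels["FFA"].linear_indices
        sel = np.isin(lin, cohort.manifest.regions["FFA"]["selective_voxels"])
        mean_tc = sim.movie_parcel_data["FFA"][sel].mean(axis=0)
        latent = cohort.manifest.latent_array("FFA")
        assert np.allclose(mean_tc, latent, atol=1e-10)

    def test_child_psts_lag_peaks_at_planted_offset(self):
        cfg = CohortConfig(groups={"3yo": 1}, child_psts_mix=0.0,
                           child_lag_trs=1, voxel_noise_sd=0.2,
                           shared_noise_sd=0.1,
                           artifact_rate={"adult": 0.0, "child": 0.0})
        cohort = simulate_cohort(cfg, seed=9)
        sim = next(iter(cohort.subjects.values()))
        lin = cohort.geometry.parcels["pSTS"].linear_indices
        sel = np.isin(lin, cohort.manifest.regions["pSTS"]["selective_voxels"])
        child = sim.movie_parcel_data["pSTS"][sel].mean(axis=0)
        latent = cohort.manifest.latent_array("pSTS")
        # child response is delayed: child[t] tracks latent[t - lag]
        corrs = {}
        for lag in range(-3, 4):
            if lag > 0:
                corrs[lag] = np.corrcoef(child[lag:], latent[:-lag])[0, 1]
            elif lag < 0:
                corrs[lag] = np.corrcoef(child[:lag], latent[-lag:])[0, 1]
            else:
                corrs[lag] = np.corrcoef(child, latent)[0, 1]
        assert max(corrs, key=corrs.get) == 1

    def test_zero_artifact_rate_keeps_motion_below_threshold(self):
        cfg = CohortConfig(groups={"adult": 2},
                           artifact_rate={"adult": 0.0, "child": 0.0},
                           n_localizer_runs=0)
        cohort = simulate_cohort(cfg, seed=4)
        for sim in cohort.subjects.values():
            assert sim.movie_artifact_trs.size == 0
            assert composite_displacement(sim.movie_motion).max() < 2.0

    def test_planted_artifacts_recovered_exactly(self):
        # default thresholds recover the planted artifact TRs with no false
        # positives on background motion of 0.1 mm SD
        for seed in range(5):
            cfg = CohortConfig(groups={"adult": 1, "3yo": 1},
                               n_localizer_runs=0)
            cohort = simulate_cohort(cfg, seed=seed)
            for sim in cohort.subjects.values():
                brain = np.vstack([sim.movie_parcel_data[r] for r in REGIONS])
                mask = detect_artifact_timepoints(sim.movie_motion, brain.mean(0))
                assert set(mask.flagged_trs) == set(sim.movie_artifact_trs)

    def test_selective_voxels_separate_from_nonselective(self):
        # empirical contrast of planted vs non-planted voxel loadings is
        # positive for every region (sanity floor for recovery tests)
        cohort = simulate_cohort(CohortConfig(groups={"adult": 2},
                                              n_localizer_runs=0), seed=6)
        for sim in cohort.subjects.values():
            for region in REGIONS:
                lin = cohort.geometry.parcels[region].linear_indices
                sel = np.isin(lin, cohort.manifest.regions[region]["selective_voxels"])
                latent = cohort.manifest.latent_array(region)
                load = sim.movie_parcel_data[region] @ latent / latent.size
                assert load[sel].mean() > load[~sel].mean()

    def test_manifest_records_every_subject_and_seed(self, tiny_cohort):
        m = tiny_cohort.manifest
        assert set(m.subjects) == set(tiny_cohort.subjects)
        for sid, meta in m.subjects.items():
            assert "subject_index" in meta and "artifact_trs_movie" in meta
        for region in REGIONS:
            assert len(m.regions[region]["selective_voxels"]) == 100
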