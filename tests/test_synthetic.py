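"""Contracts of the synthetic-study generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import mtspread as mt
from mtspread.datatypes import EdgeMatrix
from mtspread.exceptions import (
    DegenerateGraphError,
    SizingError,
    ValidationError,
)
from mtspread.synthetic import (
    TauSuvrParams,
    simulate_amyloid_suvr,
    simulate_tau_suvr,
)


class TestGenerateAtlas:
    def test_parcels_present_and_sized(self):
        atlas = mt.generate_atlas(4, (20, 20, 20), seed=1)
        labels, counts = np.unique(atlas.label_volume, return_counts=True)
        assert set(labels) == {0, 1, 2, 3, 4}
        assert all(counts[labels > 0] >= 10)

    def test_small_grid_two_rois(self):
        atlas = mt.generate_atlas(2, (6, 6, 6), seed=7)
        assert set(np.unique(atlas.label_volume)) == {0, 1, 2}

    def test_seeded_determinism(self):
        a = mt.generate_atlas(5, (15, 15, 15), seed=3)
        b = mt.generate_atlas(5, (15, 15, 15), seed=3)
        assert np.array_equal(a.label_volume, b.label_volume)

    def test_impossible_tiling_raises(self):
        with pytest.raises(SizingError):
            mt.generate_atlas(100, (6, 6, 6), seed=0)

    def test_meta_roi_names_lead(self, small_atlas):
        atlas = mt.generate_atlas(8, (20, 20, 20), seed=2)
        assert atlas.roi_names[:6] == list(
            ("amygdala", "entorhinal", "fusiform", "parahippocampal",
             "inferior_temporal", "middle_temporal")
        )


class TestGenerateMwf:
    def test_range_contract(self, small_atlas):
        _, cortical = mt.generate_mwf(small_atlas, (0.05, 0.25), seed=2)
        assert (cortical >= 0.05 - 0.05).all() and (cortical <= 0.25 + 0.05).all()

    def test_zero_noise_exact_means(self, small_atlas):
        vol, cortical = mt.generate_mwf(small_atlas, (0.1, 0.3), seed=5, noise_sd=0.0)
        # with no voxel noise each parcel is constant at its drawn mean
        for k, roi in enumerate(small_atlas.roi_ids):
            vals = vol[small_atlas.label_volume == roi]
            assert np.allclose(vals, cortical[k])

    def test_round_trip_with_parcel_means(self, small_atlas):
        vol, cortical = mt.generate_mwf(small_atlas, (0.05, 0.25), seed=9)
        again = mt.parcel_means(vol, small_atlas)
        assert np.max(np.abs(again - cortical)) < 1e-10

    def test_invalid_range(self, small_atlas):
        with pytest.raises(ValidationError):
            mt.generate_mwf(small_atlas, (0.3, 0.2), seed=0)


class TestGenerateConnectome:
    def test_full_density_all_edges(self, rng):
        mwf = rng.uniform(0.05, 0.25, 5)
        fc, counts, fiber = mt.generate_connectome(5, 1.0, mwf, seed=1)
        iu, ju = np.triu_indices(5, 1)
        assert (counts.values[iu, ju] > 0).all()
        assert np.isfinite(fiber.values[iu, ju]).all()

    def test_zero_coupling_decorrelates(self, rng):
        mwf = rng.uniform(0.05, 0.25, 30)
        fc, counts, fiber = mt.generate_connectome(
            30, 0.6, mwf, mwf_coupling=0.0, seed=4
        )
        iu, ju = np.triu_indices(30, 1)
        present = counts.values[iu, ju] > 0
        assert present.sum() >= 100
        endpoint = (mwf[iu] + mwf[ju]) / 2.0
        r = np.corrcoef(fiber.values[iu, ju][present], endpoint[present])[0, 1]
        assert abs(r) < 0.2

    def test_fc_symmetric_zero_diagonal(self, rng):
        mwf = rng.uniform(0.05, 0.25, 8)
        fc, _, _ = mt.generate_connectome(8, 0.8, mwf, seed=2)
        assert np.array_equal(fc.values, fc.values.T)
        assert (np.diagonal(fc.values) == 0).all()

    def test_empty_graph_raises(self, rng):
        mwf = rng.uniform(0.05, 0.25, 5)
        with pytest.raises(DegenerateGraphError):
            mt.generate_connectome(5, 1e-12, mwf, seed=3)


class TestGenerateStreamlines:
    def test_counts_and_endpoints(self, small_atlas):
        mwf = np.random.default_rng(0).uniform(0.05, 0.25, 4)
        _, counts, _ = mt.generate_connectome(4, 1.0, mwf, seed=5)
        streams = mt.generate_streamlines(small_atlas, counts, n_points=8, seed=6)
        for (i, j), lst in streams.items():
            a = small_atlas.roi_ids.tolist().index(i)
            b = small_atlas.roi_ids.tolist().index(j)
            assert len(lst) == int(counts.values[a, b])
            for pts in lst:
                start = tuple(np.rint(pts[0]).astype(int))
                end = tuple(np.rint(pts[-1]).astype(int))
                assert small_atlas.label_volume[start] == i
                assert small_atlas.label_volume[end] == j
                assert (np.abs(np.diff(pts, axis=0)).sum(axis=1) > 0).all()

    def test_seeded_reruns_identical(self, small_atlas):
        mwf = np.random.default_rng(0).uniform(0.05, 0.25, 4)
        _, counts, _ = mt.generate_connectome(4, 0.9, mwf, seed=5)
        s1 = mt.generate_streamlines(small_atlas, counts, seed=9)
        s2 = mt.generate_streamlines(small_atlas, counts, seed=9)
        assert s1.keys() == s2.keys()
        for key in s1:
            for p1, p2 in zip(s1[key], s2[key]):
                assert np.array_equal(p1, p2)


class TestGenerateCohort:
    def test_group_counts(self):
        cohort = mt.generate_cohort({"CN_Abpos": 30, "AD_dementia": 46}, seed=1)
        assert len(cohort) == 76
        assert (cohort["group"].value_counts()["CN_Abpos"]) == 30
        assert (cohort["group"].value_counts()["AD_dementia"]) == 46

    def test_age_truncation(self):
        cohort = mt.generate_cohort({"AD_dementia": 200}, seed=2)
        assert cohort["age"].between(55, 95).all()
        assert cohort["education"].between(6, 22).all()

    def test_determinism(self):
        a = mt.generate_cohort({"CN_Abpos": 20, "MCI_Abpos": 10}, seed=3)
        b = mt.generate_cohort({"CN_Abpos": 20, "MCI_Abpos": 10}, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateTauSuvr:
    def test_abneg_all_off_target(self, rng):
        cohort = mt.generate_cohort({"CN_Abneg_Tauneg": 30}, seed=4)
        mwf = rng.uniform(0.05, 0.25, 20)
        table, truth = simulate_tau_suvr(cohort, mwf, seed=5)
        assert not truth.positivity_labels.to_numpy().any()

    def test_all_positive_values(self, study):
        assert (study.baseline.values.to_numpy() > 0).all()

    def test_planted_rank_correlation_exact(self, rng):
        cohort = mt.generate_cohort({"CN_Abpos": 25}, seed=6)
        mwf = rng.uniform(0.05, 0.25, 150)
        _, truth = simulate_tau_suvr(cohort, mwf, seed=7)
        rho = spearmanr(mwf, truth.on_target_probability)[0]
        assert abs(rho - (-0.30)) < 1e-3

    def test_bad_params_raise(self):
        with pytest.raises(ValidationError):
            TauSuvrParams(off_mean=1.5, on_mean=1.2)


class TestTargetChangeCorrelation:
    def test_null_coefficients_identity(self, rng):
        mwf = rng.uniform(0.05, 0.25, 10)
        fc, counts, fiber = mt.generate_connectome(10, 0.7, mwf, seed=8)
        corr, n_clip = mt.build_target_change_correlation(fc, fiber, 0.0, 0.0, 0.0)
        assert np.allclose(corr, np.eye(10), atol=1e-9)
        assert n_clip == 0

    def test_psd_contract(self, study):
        corr = study.truth.target_change_correlation
        assert np.linalg.eigvalsh(corr).min() >= -1e-10

    def test_negative_interaction_attenuates_high_mwf_edges(self, study):
        """With c < 0, the covariance-FC slope is flatter among edges
        whose fiber MWF is above the median (median-split check on the
        generated output)."""
        corr = study.truth.target_change_correlation
        z = np.arctanh(np.clip(corr, -1 + 1e-7, 1 - 1e-7))
        iu, ju = np.triu_indices(study.fc.n, 1)
        fiber = study.fiber_mwf.values[iu, ju]
        ok = ~np.isnan(fiber)
        fcv = study.fc.values[iu, ju][ok]
        zv = z[iu, ju][ok]
        fib = fiber[ok]
        lo = fib <= np.median(fib)
        slope_lo = np.polyfit(fcv[lo], zv[lo], 1)[0]
        slope_hi = np.polyfit(fcv[~lo], zv[~lo], 1)[0]
        assert slope_hi < slope_lo


class TestSimulateLongitudinalChange:
    def test_zero_change_reproduces_baseline(self, rng):
        cohort = mt.generate_cohort({"CN_Abpos": 25}, seed=1)
        mwf = rng.uniform(0.05, 0.25, 6)
        baseline, _ = simulate_tau_suvr(cohort, mwf, seed=2)
        followup, _ = mt.simulate_longitudinal_change(
            cohort, baseline, np.eye(6), change_mean=0.0, change_sd=1e-12, seed=3
        )
        diff = (followup.values - baseline.values).abs().to_numpy().max()
        assert diff < 1e-8

    def test_intervals_within_range(self, study):
        lo, hi = study.config.interval_range
        assert study.intervals.between(lo, hi).all()

    def test_high_target_edge_recovered(self):
        """An edge planted at rho = 0.8 yields a sample change
        correlation in [0.7, 0.9] across 200 subjects."""
        cohort = mt.generate_cohort({"CN_Abpos": 200}, seed=4)
        mwf = np.random.default_rng(5).uniform(0.05, 0.25, 4)
        baseline, _ = simulate_tau_suvr(cohort, mwf, seed=6)
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.8
        followup, intervals = mt.simulate_longitudinal_change(
            cohort, baseline, corr, seed=7
        )
        change = (followup.values - baseline.values).div(intervals, axis=0)
        r = np.corrcoef(change[1], change[2])[0, 1]
        assert 0.7 <= r <= 0.9

    def test_non_psd_rejected(self, rng):
        cohort = mt.generate_cohort({"CN_Abpos": 25}, seed=1)
        mwf = rng.uniform(0.05, 0.25, 3)
        baseline, _ = simulate_tau_suvr(cohort, mwf, seed=2)
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValidationError):
            mt.simulate_longitudinal_change(cohort, baseline, bad, seed=3)


class TestStudyBundle:
    def test_bit_identical_reruns(self, study):
        again = mt.synthesize_study(study.config, seed=study.seed)
        assert np.array_equal(again.atlas.label_volume, study.atlas.label_volume)
        pd.testing.assert_frame_equal(again.baseline.values, study.baseline.values)
        pd.testing.assert_frame_equal(again.followup.values, study.followup.values)
        assert np.array_equal(
            again.truth.target_change_correlation,
            study.truth.target_change_correlation,
        )

    def test_edge_matrix_invariants(self, study):
        # missing fiber MWF only where the structural graph has no edge
        missing = study.fiber_mwf.missing_mask.copy()
        np.fill_diagonal(missing, False)
        no_edge = study.structural_counts.values == 0
        np.fill_diagonal(no_edge, False)
        assert (~missing | no_edge).all()

    def test_amyloid_status_matches_groups(self, study):
        glob = study.amyloid_global
        cohort = study.cohort.set_index("subject_id")
        for subj, v in glob.items():
            status = mt.classify_amyloid_status(float(v), "florbetapir")
            expected = (
                "positive" if cohort.loc[subj, "group"] != "CN_Abneg_Tauneg"
                else "negative"
            )
            assert status == expected
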