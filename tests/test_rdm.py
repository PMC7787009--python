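import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from repsim import (
    NeuroArray,
    SearchlightGrid,
    WindowSpec,
    ZeroVarianceError,
    behavioral_rdms,
    eeg_rdms,
    fmri_roi_rdm,
    fmri_searchlight_rdms,
    rdm_from_patterns,
)

from _oracles import correlation_rdm_bf


class TestRdmFromPatterns:
    def test_perfectly_correlated_rows_give_zero_distance(self):
        rdm = rdm_from_patterns(np.array([[1.0, 2, 3], [2, 4, 6]]))
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_give_distance_two(self):
        rdm = rdm_from_patterns(np.array([[1.0, 2, 3], [3, 2, 1]]))
        assert rdm.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_euclidean_3_4_5_triangle(self):
        rdm = rdm_from_patterns(np.array([[0.0, 0], [3, 4]]), "euclidean")
        assert rdm.values[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_zero_variance_row_is_a_flagged_error(self):
        with pytest.raises(ZeroVarianceError, match=r"\[1\]"):
            rdm_from_patterns(np.array([[1.0, 2, 3], [5, 5, 5]]))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rdm_from_patterns(np.array([[1.0, np.nan], [0, 1]]), "euclidean")

    def test_single_feature_correlation_rejected(self):
        with pytest.raises(ValueError, match="at least 2 features"):
            rdm_from_patterns(np.array([[1.0], [2.0]]))

    def test_mahalanobis_is_valid_and_tracks_euclidean_for_isotropic_data(self, rng):
        """With many conditions of isotropic features the shrunk covariance
        is near-spherical, so Mahalanobis ordering agrees with Euclidean."""
        from scipy.stats import spearmanr

        from repsim import vectorize_offdiag

        patterns = rng.normal(size=(30, 4))
        maha = rdm_from_patterns(patterns, "mahalanobis")
        maha.validate()
        eucl = rdm_from_patterns(patterns, "euclidean")
        rho = spearmanr(vectorize_offdiag(maha), vectorize_offdiag(eucl)).statistic
        assert rho > 0.95

    def test_matches_brute_force_pairwise_pearson(self, rng):
        for _ in range(20):
            patterns = rng.normal(size=(5, 7))
            rdm = rdm_from_patterns(patterns)
            assert np.allclose(rdm.values, correlation_rdm_bf(patterns), atol=1e-12)

    @given(arrays(float, (4, 6), elements=st.floats(-10, 10)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_condition_permutation_permutes_rows_and_columns(self, patterns):
        sd = patterns.std(axis=1)
        if (sd == 0).any():
            return
        order = np.array([2, 0, 3, 1])
        direct = rdm_from_patterns(patterns[order]).values
        permuted = rdm_from_patterns(patterns).permute_conditions(order).values
        assert np.allclose(direct, permuted, atol=1e-10)

    def test_rdm_invariants_hold(self, rng):
        for measure in ("correlation", "euclidean", "mahalanobis"):
            rdm = rdm_from_patterns(rng.normal(size=(6, 9)), measure)
            rdm.validate()


class TestBehavioralRdms:
    def test_per_subject_shape(self, behavior_data):
        rdms = behavioral_rdms(behavior_data)
        assert rdms.values.shape == (3, 4, 4)
        assert rdms.axes == ("subject",)

    def test_pooled_shape(self, behavior_data):
        rdms = behavioral_rdms(behavior_data, per_subject=False)
        assert rdms.values.shape == (4, 4)
        assert rdms.axes == ()

    def test_identical_trial_vectors_give_zero_euclidean_distance(self):
        data = np.zeros((2, 1, 3))
        data[0, 0] = data[1, 0] = [1.0, 2.0, 3.0]
        rdms = behavioral_rdms(NeuroArray.behavior(data), measure="euclidean")
        assert rdms.rdm((0,)).values[0, 1] == 0.0

    def test_constant_shifted_trials_give_sqrt3(self):
        data = np.zeros((2, 1, 3))
        data[0, 0] = [1.0, 1.0, 1.0]
        data[1, 0] = [2.0, 2.0, 2.0]
        rdms = behavioral_rdms(NeuroArray.behavior(data), measure="euclidean")
        assert rdms.rdm((0,)).values[0, 1] == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_nan_trials_rejected(self):
        data = np.zeros((2, 1, 3))
        data[0, 0, 2] = np.nan
        with pytest.raises(ValueError, match="trial counts"):
            behavioral_rdms(NeuroArray.behavior(data))


class TestEegRdms:
    def test_per_subject_per_channel_shape(self):
        d = np.random.default_rng(0).normal(size=(4, 2, 5, 3, 10))
        rdms = eeg_rdms(NeuroArray.eeg(d), per_subject=True, per_channel=True)
        assert rdms.values.shape == (2, 3, 4, 4)
        assert rdms.axes == ("subject", "channel")

    def test_window_count(self):
        d = np.random.default_rng(0).normal(size=(3, 1, 2, 2, 100))
        rdms = eeg_rdms(
            NeuroArray.eeg(d), per_window=True, window=WindowSpec(5, 5)
        )
        assert rdms.values.shape == (1, 20, 3, 3)
        assert rdms.axes == ("subject", "window")

    def test_identical_conditions_give_zero_distance(self):
        d = np.random.default_rng(0).normal(size=(3, 1, 2, 2, 6))
        d[1] = d[0]
        for measure in ("euclidean", "correlation"):
            rdms = eeg_rdms(NeuroArray.eeg(d), measure=measure)
            assert rdms.rdm((0,)).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_channel_subset_rejected(self, eeg_data):
        with pytest.raises(ValueError, match="empty channel subset"):
            eeg_rdms(eeg_data, channels=[])

    def test_window_longer_than_series_rejected(self, eeg_data):
        with pytest.raises(ValueError, match="longer"):
            eeg_rdms(eeg_data, per_window=True, window=WindowSpec(999, 1))

    def test_trials_averaged_before_distance(self):
        """Computing on trial-averaged data by hand gives the same RDMs."""
        rng = np.random.default_rng(3)
        d = rng.normal(size=(3, 1, 4, 2, 5))
        rdms = eeg_rdms(NeuroArray.eeg(d), measure="euclidean")
        avg = d.mean(axis=2)[:, 0].reshape(3, -1)
        expected = np.linalg.norm(avg[0] - avg[1])
        assert rdms.rdm((0,)).values[0, 1] == pytest.approx(expected, abs=1e-12)


class TestFmriRoi:
    def test_two_voxel_mask_euclidean(self):
        data = np.zeros((2, 1, 2, 1, 1))
        data[1, 0, 0, 0, 0] = 3.0
        data[1, 0, 1, 0, 0] = 4.0
        mask = np.ones((2, 1, 1), dtype=bool)
        rdms = fmri_roi_rdm(NeuroArray.fmri(data), mask, measure="euclidean")
        assert rdms.rdm((0,)).values[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_single_voxel_mask_correlation_is_degenerate(self, fmri_data):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            fmri_roi_rdm(fmri_data, mask, measure="correlation")

    def test_equal_conditions_in_mask_give_zero(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 1, 3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, :, :] = True
        data[1, :, 0] = data[0, :, 0]  # equal inside the mask only
        rdms = fmri_roi_rdm(NeuroArray.fmri(data), mask, measure="euclidean")
        assert rdms.rdm((0,)).values[0, 1] == 0.0

    def test_nan_voxels_dropped_from_all_conditions(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 1, 2, 2, 2))
        data[0, 0, 0, 0, 0] = np.nan
        mask = np.ones((2, 2, 2), dtype=bool)
        rdms = fmri_roi_rdm(NeuroArray.fmri(data), mask, measure="euclidean")
        keep = np.ones((2, 2, 2), dtype=bool)
        keep[0, 0, 0] = False
        expected = np.linalg.norm(data[0, 0][keep] - data[1, 0][keep])
        assert rdms.rdm((0,)).values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_all_nan_roi_rejected(self):
        data = np.full((2, 1, 2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="empty"):
            fmri_roi_rdm(NeuroArray.fmri(data), np.ones((2, 2, 2), dtype=bool))

    def test_mask_shape_mismatch_rejected(self, fmri_data):
        with pytest.raises(ValueError, match="mask shape"):
            fmri_roi_rdm(fmri_data, np.ones((2, 2, 2), dtype=bool))


class TestSearchlight:
    def test_unit_grid_shape(self, fmri_data):
        grid = SearchlightGrid((6, 6, 6), (3, 3, 3), (1, 1, 1))
        rdms = fmri_searchlight_rdms(fmri_data, grid)
        assert rdms.values.shape == (3, 4, 4, 4, 4, 4)
        assert rdms.axes == ("subject", "x", "y", "z")

    def test_whole_image_kernel_equals_roi_with_full_mask(self, fmri_data):
        grid = SearchlightGrid((6, 6, 6), (6, 6, 6), (1, 1, 1))
        sl = fmri_searchlight_rdms(fmri_data, grid)
        roi = fmri_roi_rdm(fmri_data, np.ones((6, 6, 6), dtype=bool))
        assert sl.values.shape == (3, 1, 1, 1, 4, 4)
        for s in range(3):
            assert np.allclose(sl.values[s, 0, 0, 0], roi.values[s], atol=1e-10)

    def test_stride_equal_kernel_tiles_every_voxel_once(self):
        grid = SearchlightGrid((6, 6, 6), (2, 2, 2), (2, 2, 2))
        covered = np.zeros((6, 6, 6), dtype=int)
        for idx in np.ndindex(*grid.n_units):
            ox, oy, oz = grid.unit_origin(idx)
            covered[ox : ox + 2, oy : oy + 2, oz : oz + 2] += 1
        assert (covered == 1).all()

    def test_nan_unit_yields_missing_marker_only_there(self, fmri_data):
        vals = fmri_data.values.copy()
        vals[0, 0, 0, 0, 0] = np.nan
        data = NeuroArray.fmri(vals)
        grid = SearchlightGrid((6, 6, 6), (3, 3, 3), (3, 3, 3))
        rdms = fmri_searchlight_rdms(data, grid)
        missing = rdms.missing_mask()
        assert missing[0, 0, 0, 0]
        assert missing.sum() == 1  # neighbors and other subjects unaffected

    def test_vectorized_correlation_matches_direct_computation(self, fmri_data):
        from repsim import rdm_from_patterns

        grid = SearchlightGrid((6, 6, 6), (3, 3, 3), (2, 2, 2))
        rdms = fmri_searchlight_rdms(fmri_data, grid)
        vals = fmri_data.values
        s, ux, uy, uz = 1, 1, 0, 1
        block = vals[:, s, 2:5, 0:3, 2:5]
        patterns = np.moveaxis(block, (1, 2, 3), (3, 2, 1)).reshape(4, -1)
        expected = rdm_from_patterns(patterns).values
        assert np.allclose(rdms.values[s, ux, uy, uz], expected, atol=1e-10)

    def test_every_emitted_rdm_is_valid(self, fmri_data):
        grid = SearchlightGrid((6, 6, 6), (3, 3, 3), (2, 2, 2))
        for measure in ("correlation", "euclidean"):
            rdms = fmri_searchlight_rdms(fmri_data, grid, measure)
            for idx in rdms.indices():
                rdms.rdm(idx).validate()
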