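"""Labeling, splitting, class weights, and normalization contracts."""

import numpy as np
import pytest

import preictal as p
from preictal.exceptions import ConfigurationError, DataError, PatientExclusionError


class TestLabelWindows:
    def test_preictal_interval_boundaries(self):
        # onset 7200 s, SPH 10 min, SOP 30 min: preictal starts at 4800 s
        times = np.array([4795.0, 4800.0, 6000.0, 7195.0, 7200.0])
        labels = p.label_windows(times, np.array([7200.0]), sop_min=30, sph_min=10)
        assert labels.tolist() == [0, 1, 1, 1, -1]  # onset window itself is ictal

    def test_ictal_and_blackout_excluded(self):
        times = np.arange(0.0, 400.0, 5.0)
        labels = p.label_windows(times, np.array([100.0]), sop_min=10, sph_min=10,
                                 offsets=np.array([130.0]), ictal_blackout=120.0)
        assert (labels[(times >= 100.0) & (times < 250.0)] == -1).all()
        assert (labels[times >= 250.0] == 0).all()

    def test_truncation_at_recording_start(self):
        # onset at 1000 s with a 2400 s span: only [0, 1000) windows exist
        times = np.arange(0.0, 1000.0, 5.0)
        labels = p.label_windows(times, np.array([1000.0]), sop_min=30, sph_min=10)
        assert (labels == 1).all()

    def test_label_mass_per_fully_observed_seizure(self):
        times = np.arange(0.0, 20000.0, 5.0)
        labels = p.label_windows(times, np.array([10000.0]), sop_min=30, sph_min=10)
        assert (labels == 1).sum() == (30 + 10) * 60 // 5


class TestChronologicalSplit:
    def _data(self, n_seiz, gap=3000.0):
        onsets = np.array([5000.0 + gap * i for i in range(n_seiz)])
        times = np.arange(0.0, onsets[-1] + 600.0, 5.0)
        X = np.arange(times.size, dtype=float)[:, None]
        return X, times, onsets

    def test_three_train_two_test(self):
        X, times, onsets = self._data(5)
        split = p.chronological_split(X, times, onsets, 3, sop_min=30)
        assert split.train_seizure_ids == [0, 1, 2]
        assert split.test_seizure_ids == [3, 4]
        assert split.test_onsets.tolist() == onsets[3:].tolist()

    def test_fewer_than_four_seizures_excluded(self):
        X, times, onsets = self._data(3)
        with pytest.raises(PatientExclusionError):
            p.chronological_split(X, times, onsets, 2, sop_min=30)

    def test_no_temporal_leakage(self):
        X, times, onsets = self._data(6)
        split = p.chronological_split(X, times, onsets, 3, sop_min=30)
        assert split.t_train.max() < split.t_test.min()
        assert split.t_train.size + split.t_test.size == times.size

    def test_cut_point_one_hour_after_last_training_seizure(self):
        X, times, onsets = self._data(5, gap=7200.0)
        split = p.chronological_split(X, times, onsets, 3, sop_min=30)
        assert split.cut_time == onsets[2] + 3600.0
        assert split.t_test.min() >= split.cut_time


class TestSegmentedSplit:
    def _dataset(self, n_groups=10, files_per_group=2, n_inter=40):
        rng = np.random.default_rng(0)
        segs = []
        for g in range(n_groups):
            for _ in range(files_per_group):
                segs.append(p.Segment(rng.standard_normal((1, 2560)), "preictal", g))
        for b in range(n_inter):
            segs.append(p.Segment(rng.standard_normal((1, 2560)), "interictal", b))
        ds = p.SegmentedDataset(segs, fs=256.0, segment_duration=10.0)
        ws, labels, groups = p.windows_from_segments(ds, 5.0)
        X = np.arange(ws.n_windows, dtype=float)[:, None]
        return ds, X, ws.keys

    def test_seventy_thirty_group_assignment(self):
        ds, X, keys = self._dataset(n_groups=10)
        split = p.segmented_split(ds, X, keys)
        assert len(split.train_seizure_ids) == 7
        assert len(split.test_seizure_ids) == 3

    def test_no_group_spans_both_sets(self):
        ds, X, keys = self._dataset()
        split = p.segmented_split(ds, X, keys)
        assert not set(split.train_seizure_ids) & set(split.test_seizure_ids)
        # and at window level: train preictal groups never appear in the test side
        test_pre_groups = set(split.test_groups[split.y_test == 1])
        assert not test_pre_groups & set(split.train_seizure_ids)

    def test_training_file_counts_balanced(self):
        ds, X, keys = self._dataset(n_groups=10, files_per_group=2, n_inter=40)
        split = p.segmented_split(ds, X, keys)
        # equal file counts -> equal window counts (all files have equal length)
        assert (split.y_train == 1).sum() == (split.y_train == 0).sum()

    def test_deterministic_given_seed(self):
        ds, X, keys = self._dataset()
        a = p.segmented_split(ds, X, keys, seed=3)
        b = p.segmented_split(ds, X, keys, seed=3)
        assert a.train_seizure_ids == b.train_seizure_ids
        np.testing.assert_array_equal(a.X_train, b.X_train)

    def test_single_group_rejected(self):
        ds, X, keys = self._dataset(n_groups=1)
        with pytest.raises(DataError):
            p.segmented_split(ds, X, keys)


class TestClassWeights:
    def test_imbalanced_example(self):
        y = np.array([0] * 900 + [1] * 100)
        w = p.compute_class_weights(y)
        assert w.weight_interictal == pytest.approx(1000 / 1800)
        assert w.weight_preictal == pytest.approx(5.0)

    def test_balanced_gives_unit_weights(self):
        w = p.compute_class_weights(np.array([0, 1] * 50))
        assert w.weight_interictal == w.weight_preictal == 1.0

    def test_weighted_masses_equal(self):
        y = np.array([0] * 37 + [1] * 13)
        w = p.compute_class_weights(y)
        assert 37 * w.weight_interictal == pytest.approx(13 * w.weight_preictal)

    def test_duplication_invariance(self):
        y = np.array([0] * 30 + [1] * 10)
        a, b = p.compute_class_weights(y), p.compute_class_weights(np.tile(y, 3))
        assert (a.weight_interictal, a.weight_preictal) == (b.weight_interictal, b.weight_preictal)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            p.compute_class_weights(np.zeros(10, dtype=int))


class TestZscore:
    def test_transformed_training_columns_standardized(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5.0, 3.0, size=(200, 4))
        params = p.zscore_fit(X)
        Z = p.zscore_apply(params, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-10)

    def test_test_value_at_train_mean_maps_to_zero(self):
        X = np.array([[1.0], [2.0], [3.0]])
        params = p.zscore_fit(X)
        assert p.zscore_apply(params, np.array([[2.0]]))[0, 0] == 0.0

    def test_constant_column_flagged_and_zeroed(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        params = p.zscore_fit(X)
        assert params.zero_variance.tolist() == [False, True]
        Z = p.zscore_apply(params, X + 1.0)
        assert (Z[:, 1] == 0.0).all()
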