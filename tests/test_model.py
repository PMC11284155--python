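"""Ranking, grid-search, and classifier contracts."""

import numpy as np
import pytest

import preictal as p
from preictal.exceptions import DataError
from preictal.model import _fold_objective


def _toy_training(n=400, n_feat=20, seed=0):
    """One informative column (the labels plus small noise), rest pure noise."""
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=n) < 0.3).astype(int)
    X = rng.standard_normal((n, n_feat))
    X[:, 7] = y + 0.1 * rng.standard_normal(n)
    return X, y


class TestRankFeatures:
    def test_informative_feature_ranked_first(self):
        for seed in range(5):
            X, y = _toy_training(seed=seed)
            assert p.rank_features(X, y)[0] == 7

    def test_identical_features_tie_break_by_index(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(100)
        X = np.tile(col[:, None], (1, 5))
        y = (rng.uniform(size=100) < 0.5).astype(int)
        assert p.rank_features(X, y).tolist() == [0, 1, 2, 3, 4]

    def test_affine_rescaling_does_not_change_order(self):
        X, y = _toy_training()
        base = p.rank_features(X, y)
        X2 = X * 3.0 + 11.0
        np.testing.assert_array_equal(p.rank_features(X2, y), base)

    def test_zero_variance_column_ranked_last(self):
        X, y = _toy_training()
        X[:, 2] = 4.2
        assert p.rank_features(X, y)[-1] == 2

    def test_single_class_rejected(self):
        X, _ = _toy_training()
        with pytest.raises(DataError):
            p.rank_features(X, np.ones(X.shape[0], dtype=int))


class TestClassifier:
    def test_linearly_separable_training_accuracy_one(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 0.3, (50, 2)), rng.normal(3, 0.3, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        norm = p.zscore_fit(X)
        Xn = p.zscore_apply(norm, X)
        spec = p.train_classifier(Xn, y, np.array([0, 1]), norm)
        _, binary = p.predict(spec, Xn)
        assert (binary == y).mean() == 1.0

    def test_null_features_give_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        X = rng.standard_normal((1000, 10))
        y = (rng.uniform(size=1000) < 0.5).astype(int)
        norm = p.zscore_fit(X[:600])
        spec = p.train_classifier(p.zscore_apply(norm, X[:600]), y[:600], np.arange(10), norm)
        proba, _ = p.predict(spec, p.zscore_apply(norm, X[600:]))
        assert roc_auc_score(y[600:], proba) == pytest.approx(0.5, abs=0.1)

    def test_zero_model_outputs_half(self):
        norm = p.NormalizationParams(mean=np.zeros(2), std=np.ones(2), zero_variance=np.zeros(2, bool))
        spec = p.ModelSpec(feature_indices=np.array([0, 1]), coef=np.zeros(2), intercept=0.0,
                           normalization=norm, class_weights=p.ClassWeights(1.0, 1.0))
        proba, binary = p.predict(spec, np.zeros((3, 2)))
        assert (proba == 0.5).all() and (binary == 1).all()

    def test_probability_monotone_in_positive_weight(self):
        norm = p.NormalizationParams(mean=np.zeros(1), std=np.ones(1), zero_variance=np.zeros(1, bool))
        spec = p.ModelSpec(feature_indices=np.array([0]), coef=np.array([2.0]), intercept=-0.3,
                           normalization=norm, class_weights=p.ClassWeights(1.0, 1.0))
        proba, _ = p.predict(spec, np.linspace(-3, 3, 50)[:, None])
        assert (np.diff(proba) > 0).all()

    def test_feature_dimension_mismatch_rejected(self):
        norm = p.NormalizationParams(mean=np.zeros(5), std=np.ones(5), zero_variance=np.zeros(5, bool))
        spec = p.ModelSpec(feature_indices=np.array([4]), coef=np.array([1.0]), intercept=0.0,
                           normalization=norm, class_weights=p.ClassWeights(1.0, 1.0))
        with pytest.raises(DataError):
            p.predict(spec, np.zeros((2, 3)))

    def test_weights_stabilize_fit_under_interictal_duplication(self):
        """Doubling the interictal windows while recomputing the inverse-
        frequency weights leaves the weighted class masses, and hence the
        decision boundary, essentially unchanged."""
        rng = np.random.default_rng(4)
        X1 = np.vstack([rng.normal(-1, 1, (300, 2)), rng.normal(1, 1, (100, 2))])
        y1 = np.array([0] * 300 + [1] * 100)
        X2 = np.vstack([X1[y1 == 0], X1])
        y2 = np.concatenate([np.zeros(300, int), y1])

        def fit(X, y):
            norm = p.zscore_fit(X)
            w = p.compute_class_weights(y)
            return p.train_classifier(p.zscore_apply(norm, X), y, np.array([0, 1]), norm, w), norm

        spec1, norm1 = fit(X1, y1)
        spec2, norm2 = fit(X2, y2)
        probe = rng.normal(0, 1.5, (500, 2))
        p1, b1 = p.predict(spec1, p.zscore_apply(norm1, probe))
        p2, b2 = p.predict(spec2, p.zscore_apply(norm2, probe))
        assert (b1 == b2).mean() >= 0.95

    def test_fold_objective_is_sensitivity_times_specificity(self):
        """A fold scoring SS=0.8 and SP=0.5 contributes objective 0.40."""
        rng = np.random.default_rng(5)
        X_tr = np.vstack([rng.normal(-2, 0.2, (50, 1)), rng.normal(2, 0.2, (50, 1))])
        y_tr = np.array([0] * 50 + [1] * 50)
        # validation placed so the trained boundary (near 0) yields 4/5 and 3/6
        X_va = np.array([[3.0]] * 4 + [[-3.0]] + [[-3.0]] * 3 + [[3.0]] * 3)
        y_va = np.array([1] * 5 + [0] * 6)
        obj = _fold_objective(X_tr, y_tr, X_va, y_va, (1,))
        assert obj[1] == pytest.approx(0.8 * 0.5)


class TestGridSearch:
    def _timeline(self, informative_span_s=1500.0, seed=0, n_noise=6):
        """Synthetic training block: 3 seizures, one feature ramps inside the
        true preictal span, the rest are noise."""
        rng = np.random.default_rng(seed)
        onsets = np.array([5000.0, 10000.0, 15000.0])
        times = np.arange(0.0, 15600.0, 5.0)
        X = rng.standard_normal((times.size, n_noise + 1))
        signal = np.zeros(times.size)
        for onset in onsets:
            in_span = (times >= onset - informative_span_s) & (times < onset)
            ramp = (times[in_span] - (onset - informative_span_s)) / informative_span_s
            signal[in_span] = 3.0 * ramp
        X[:, 3] += signal
        return X, times, onsets

    def test_recovers_true_preictal_span(self):
        """True span 1500 s = (SOP 15 + SPH 10) min: the grid should pick
        SOP 15 (or a neighbour) by maximizing SS*SP."""
        hits = 0
        for seed in range(5):
            X, times, onsets = self._timeline(seed=seed)
            cv = p.cv_grid_search(X, times, onsets, sop_grid=(10.0, 15.0, 20.0, 25.0, 30.0),
                                  k_grid=(1, 3), sph_min=10.0)
            hits += cv.sop_star in (10.0, 15.0, 20.0)
        assert hits >= 4

    def test_objective_bounded_and_deterministic(self):
        X, times, onsets = self._timeline()
        kwargs = dict(sop_grid=(10.0, 20.0), k_grid=(1, 3), sph_min=10.0)
        a = p.cv_grid_search(X, times, onsets, **kwargs)
        b = p.cv_grid_search(X, times, onsets, **kwargs)
        assert ((a.table.objective >= 0) & (a.table.objective <= 1)).all()
        assert a.table.equals(b.table)
        assert (a.sop_star, a.k_star) == (b.sop_star, b.k_star)

    def test_needs_three_training_seizures(self):
        X, times, _ = self._timeline()
        with pytest.raises(DataError):
            p.cv_grid_search(X, times, np.array([5000.0, 10000.0]), sop_grid=(10.0,), k_grid=(1,))

    def test_segmented_k_selection(self):
        rng = np.random.default_rng(6)
        groups = np.repeat(np.arange(10), 30)
        y = np.where(groups < 5, 1, 0)
        X = rng.standard_normal((300, 8))
        X[:, 2] += 2.0 * y
        cv = p.cv_select_k(X, y, groups, k_grid=(1, 4), seed=1)
        assert cv.sop_star is None
        assert cv.k_star in (1, 4)
        assert ((cv.table.objective >= 0) & (cv.table.objective <= 1)).all()
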