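"""SMOTE oversampling, k-NN posteriors, majority voting, model persistence."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from era3d import classifier as clf
from era3d.annotator import CONTROL, PAF
from era3d.features import DegenerateDataError, NormalizationParams


def _model(x, y, k=3):
    norm = NormalizationParams(mean=np.zeros(x.shape[1]), sd=np.ones(x.shape[1]))
    return clf.knn_fit(x, y, k, norm, "RR_QT" if x.shape[1] == 2 else "RR_QT_TQ")


def brute_force_posterior(x_train, y_train, query, k):
    """Independent oracle: full stable sort of squared distances."""
    d2 = ((x_train - query) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    return float(np.mean(y_train[order[:k]] == PAF))


class TestSmote:
    def test_two_points_interpolate_on_segment(self, rng):
        a, b = np.array([0.0, 0.0]), np.array([1.0, 2.0])
        synth = clf.smote_oversample(np.vstack([a, b]), 50, k_smote=1, rng_seed=rng)
        t = synth[:, 1] / 2.0
        np.testing.assert_allclose(synth[:, 0], t, atol=1e-12)
        assert np.all((t >= 0) & (t <= 1))

    def test_zero_request_empty(self, rng):
        out = clf.smote_oversample(np.zeros((10, 2)) + np.arange(10)[:, None], 0)
        assert out.shape == (0, 2)

    def test_synthetic_points_inside_convex_hull(self, rng):
        minority = rng.normal(size=(30, 2))
        synth = clf.smote_oversample(minority, 200, rng_seed=17)
        tri = Delaunay(minority)
        assert np.all(tri.find_simplex(synth) >= 0)

    def test_seed_determinism_and_divergence(self):
        minority = np.random.default_rng(0).normal(size=(20, 3))
        a = clf.smote_oversample(minority, 40, rng_seed=5)
        b = clf.smote_oversample(minority, 40, rng_seed=5)
        c = clf.smote_oversample(minority, 40, rng_seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_few_minority_rows(self):
        with pytest.raises(DegenerateDataError):
            clf.smote_oversample(np.zeros((4, 2)), 10, k_smote=5)


class TestBalanceClasses:
    def test_counts_equalized(self, rng):
        x = np.vstack([rng.normal(size=(100, 2)), rng.normal(3, 1, size=(25, 2))])
        y = np.array([CONTROL] * 100 + [PAF] * 25, dtype=object)
        xb, yb = clf.balance_classes(x, y, rng_seed=1)
        assert (yb == PAF).sum() == (yb == CONTROL).sum() == 100
        np.testing.assert_array_equal(xb[:125], x)  # originals untouched
        assert np.all(yb[125:] == PAF)  # synthetic rows carry minority label

    def test_already_balanced_unchanged(self, rng):
        x = rng.normal(size=(20, 2))
        y = np.array([CONTROL] * 10 + [PAF] * 10, dtype=object)
        xb, yb = clf.balance_classes(x, y, rng_seed=1)
        np.testing.assert_array_equal(xb, x)
        np.testing.assert_array_equal(yb, y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            clf.balance_classes(rng.normal(size=(5, 2)), np.array([PAF] * 5, dtype=object))


class TestKnnFit:
    def test_even_k_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        y = np.array([CONTROL, PAF] * 5, dtype=object)
        with pytest.raises(ValueError, match="odd"):
            _model(x, y, k=4)

    def test_k_beyond_rows_rejected(self, rng):
        x = rng.normal(size=(4, 2))
        y = np.array([CONTROL, PAF] * 2, dtype=object)
        with pytest.raises(ValueError):
            _model(x, y, k=5)

    def test_k_equal_rows_allowed(self, rng):
        x = rng.normal(size=(5, 2))
        y = np.array([CONTROL, PAF, CONTROL, PAF, CONTROL], dtype=object)
        model = _model(x, y, k=5)
        pred = clf.knn_posterior(model, np.zeros(2))
        assert pred.posterior_paf == pytest.approx(2 / 5)


class TestKnnPosterior:
    def test_vote_two_of_three(self):
        x = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [5.0, 5.0]])
        y = np.array([PAF, PAF, CONTROL, CONTROL], dtype=object)
        pred = clf.knn_posterior(_model(x, y, k=3), np.array([0.02, 0.02]))
        assert pred.posterior_paf == pytest.approx(2 / 3)
        assert pred.predicted_label == PAF

    def test_query_on_training_row_k1(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.array([CONTROL, PAF] * 10, dtype=object)
        model = _model(x, y, k=1)
        for i in (0, 7, 13):
            pred = clf.knn_posterior(model, x[i])
            assert pred.posterior_paf == float(y[i] == PAF)

    def test_dimension_mismatch(self, rng):
        x = rng.normal(size=(10, 3))
        y = np.array([CONTROL, PAF] * 5, dtype=object)
        with pytest.raises(ValueError):
            clf.knn_posterior(_model(x, y, k=3), np.zeros(2))

    def test_distance_tie_prefers_earlier_rows(self):
        # four equidistant corners; k=3 must take the three earliest rows
        x = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        y = np.array([PAF, PAF, CONTROL, CONTROL], dtype=object)
        pred = clf.knn_posterior(_model(x, y, k=3), np.zeros(2))
        assert pred.posterior_paf == pytest.approx(2 / 3)

    @pytest.mark.parametrize("k", [1, 3, 7, 15])
    def test_matches_bruteforce_oracle(self, k, rng):
        for _ in range(10):
            n = int(rng.integers(k, 120))
            x = rng.normal(size=(n, 3))
            y = rng.choice(np.array([CONTROL, PAF], dtype=object), size=n)
            if k > n or len(np.unique(y)) < 2:
                continue
            model = _model(x, y, k=k)
            queries = rng.normal(size=(30, 3))
            batch = clf.knn_posterior_batch(model, queries)
            for q, p_batch in zip(queries, batch):
                expected = brute_force_posterior(x, y, q, k)
                assert clf.knn_posterior(model, q).posterior_paf == pytest.approx(expected)
                assert p_batch == pytest.approx(expected)

    def test_training_row_permutation_invariance(self, rng):
        x = rng.normal(size=(50, 3))
        y = rng.choice(np.array([CONTROL, PAF], dtype=object), size=50)
        perm = rng.permutation(50)
        queries = rng.normal(size=(20, 3))
        a = clf.knn_posterior_batch(_model(x, y, k=5), queries)
        b = clf.knn_posterior_batch(_model(x[perm], y[perm], k=5), queries)
        np.testing.assert_allclose(a, b)


class TestPredictSubject:
    def _simple_model(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        y = np.array([CONTROL, CONTROL, PAF, PAF], dtype=object)
        return clf.knn_fit(
            x, y, 1, NormalizationParams(mean=np.zeros(1), sd=np.ones(1)), "RR_QT"
        )

    def test_majority_three_of_five(self):
        model = self._simple_model()
        beats = np.array([[0.0], [0.05], [9.9], [10.0], [10.2]])
        pred = clf.predict_subject(model, beats, "h1")
        assert pred.vote_fraction_paf == pytest.approx(0.6)
        assert pred.final_label == PAF

    def test_exact_tie_goes_to_paf(self):
        model = self._simple_model()
        beats = np.array([[0.0], [0.05], [10.0], [10.2]])
        pred = clf.predict_subject(model, beats, "h2")
        assert pred.vote_fraction_paf == pytest.approx(0.5)
        assert pred.final_label == PAF

    def test_final_label_is_modal_beat_label(self, rng):
        model = self._simple_model()
        beats = rng.choice([0.0, 10.0], size=(25, 1)) + rng.normal(0, 0.01, (25, 1))
        pred = clf.predict_subject(model, beats, "h3")
        modal = PAF if (beats > 5).mean() > 0.5 else CONTROL
        assert pred.final_label == modal

    def test_no_beats_flagged(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            clf.predict_subject(self._simple_model(), np.empty((0, 1)), "empty")


class TestPersistence:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        x = rng.normal(size=(30, 3))
        y = rng.choice(np.array([CONTROL, PAF], dtype=object), size=30)
        norm = NormalizationParams(
            mean=rng.normal(size=3), sd=np.abs(rng.normal(size=3)) + 0.1
        )
        model = clf.knn_fit(x, y, 5, norm, "RR_QT_TQ")
        path = tmp_path / "model.json"
        clf.save_model(model, path)
        back = clf.load_model(path)
        np.testing.assert_array_equal(back.matrix, model.matrix)
        np.testing.assert_array_equal(back.labels, model.labels)
        np.testing.assert_array_equal(back.normalization.mean, norm.mean)
        np.testing.assert_array_equal(back.normalization.sd, norm.sd)
        assert back.k == 5 and back.feature_set.name == "RR_QT_TQ"
        q = rng.normal(size=3)
        assert (
            clf.knn_posterior(back, q).posterior_paf
            == clf.knn_posterior(model, q).posterior_paf
        )

    def test_version_checked(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="version"):
            clf.load_model(path)
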