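"""Trust scores: distance-ratio oracle, PCA projection, subsampling scheme."""

import numpy as np
import pytest

import seizedefer as sd
from seizedefer.simulate import PatientData, SegmentSeries
from seizedefer.trust import _candidate_windows


def brute_force_trust(Z_train, y_train, z, predicted):
    """All-pairs nearest-neighbour oracle in the projected space."""
    d0 = min(np.linalg.norm(z - p) for p in Z_train[y_train == 0])
    d1 = min(np.linalg.norm(z - p) for p in Z_train[y_train == 1])
    d_pred, d_other = (d1, d0) if predicted == 1 else (d0, d1)
    if d_pred == 0:
        return np.inf if d_other > 0 else 1.0
    return d_other / d_pred


class TestTrustScore:
    def _toy_model(self):
        X = np.array([[0.0], [10.0]])
        y = np.array([0, 1])
        return sd.fit_trust_model(X, y, n_components=1)

    def test_1d_toy_predicted_zero(self):
        assert sd.trust_score(self._toy_model(), [2.0], 0) == pytest.approx(4.0)

    def test_1d_toy_predicted_one_is_reciprocal(self):
        assert sd.trust_score(self._toy_model(), [2.0], 1) == pytest.approx(0.25)

    def test_equidistant_point_scores_one(self):
        assert sd.trust_score(self._toy_model(), [5.0], 0) == pytest.approx(1.0)

    def test_duplicate_of_reference_point(self):
        m = self._toy_model()
        assert sd.trust_score(m, [0.0], 0) == np.inf  # d_other>0, d_pred=0
        assert sd.trust_score(m, [0.0], 1) == pytest.approx(0.0)

    def test_matches_brute_force_oracle_on_random_points(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 8))
        y = (rng.random(60) > 0.5).astype(int)
        y[:2] = [0, 1]  # both classes guaranteed
        model = sd.fit_trust_model(X, y, n_components=8)
        Z_train = model.pca_.transform(X)
        pts = rng.normal(size=(200, 8))
        preds = (rng.random(200) > 0.5).astype(int)
        scores = model.score_samples(pts, preds)
        Z = model.pca_.transform(pts)
        expected = [
            brute_force_trust(Z_train, y, z, p) for z, p in zip(Z, preds)
        ]
        np.testing.assert_allclose(scores, expected, rtol=1e-10)

    def test_class_flip_reciprocal_property(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        y = np.repeat([0, 1], 20)
        model = sd.fit_trust_model(X, y, n_components=5)
        pts = rng.normal(size=(50, 5)) + 10  # away from refs: nonzero distances
        s0 = model.score_samples(pts, np.zeros(50, int))
        s1 = model.score_samples(pts, np.ones(50, int))
        np.testing.assert_allclose(s0, 1.0 / s1, rtol=1e-12)

    def test_score_above_one_iff_closer_to_predicted_class(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(-3, 1, (30, 4)), rng.normal(3, 1, (30, 4))])
        y = np.repeat([0, 1], 30)
        model = sd.fit_trust_model(X, y, n_components=4)
        pts = rng.normal(0, 4, (100, 4))
        Z = model.pca_.transform(pts)
        d0 = np.min(
            np.linalg.norm(Z[:, None] - model.class0_points_[None], axis=2), axis=1
        )
        d1 = np.min(
            np.linalg.norm(Z[:, None] - model.class1_points_[None], axis=2), axis=1
        )
        s = model.score_samples(pts, np.zeros(100, int))
        np.testing.assert_array_equal(s > 1, d0 < d1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sd.fit_trust_model(np.zeros((5, 2)), np.zeros(5, int))


class TestProjection:
    def test_projection_dim_capped_at_feature_dim(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 10))
        y = np.repeat([0, 1], 25)
        model = sd.fit_trust_model(X, y, n_components=20)
        assert model.pca_.n_components_ == 10

    def test_reference_set_sizes(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array([0, 0, 0, 1, 1, 1])
        model = sd.fit_trust_model(X, y)
        assert len(model.class0_points_) == len(model.class1_points_) == 3

    def test_projected_distances_match_eigendecomposition_oracle(self):
        """Full-rank PCA is a rotation: pairwise distances must match an
        independent eigendecomposition of the covariance."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
        y = np.repeat([0, 1], 20)
        model = sd.fit_trust_model(X, y, n_components=6)
        Z = model.pca_.transform(X)

        Xc = X - X.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        Z_oracle = Xc @ vecs  # distances invariant to order/sign of axes
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(Z), pdist(Z_oracle), atol=1e-8)


def _patient_without_events(duration_s, pid="p00", dim=4):
    n = duration_s - 1
    feats = np.random.default_rng(0).normal(size=(n, dim))
    return PatientData(pid, duration_s, SegmentSeries(feats), [])


class TestSubsample:
    def test_25h_recording_has_100_candidates_all_drawn(self):
        p = _patient_without_events(25 * 3600)
        labels = {p.patient_id: np.zeros(p.segments.n_segments, dtype=np.int8)}
        cand = _candidate_windows(labels[p.patient_id], [], p.duration_s, 900)
        assert len(cand) == 100
        X, y = sd.subsample_training_set([p], labels, seed=0)
        assert X.shape[0] == 100 * 30 and (y == 0).all()

    def test_6h_recording_falls_back_to_5min_grid(self):
        p = _patient_without_events(6 * 3600)
        labels = {p.patient_id: np.zeros(p.segments.n_segments, dtype=np.int8)}
        assert len(_candidate_windows(labels[p.patient_id], [], p.duration_s, 900)) == 24
        assert len(_candidate_windows(labels[p.patient_id], [], p.duration_s, 300)) == 72
        X, _ = sd.subsample_training_set([p], labels, seed=0)
        assert X.shape[0] == 72 * 30  # min(100, 72) windows

    def test_deterministic_given_seed(self, small_cohort, fs_labels):
        X1, y1 = sd.subsample_training_set(small_cohort, fs_labels, seed=5)
        X2, y2 = sd.subsample_training_set(small_cohort, fs_labels, seed=5)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_includes_all_seizure_segments(self, small_cohort, fs_labels):
        _, y = sd.subsample_training_set(small_cohort, fs_labels, seed=0)
        total_seiz = sum(int(v.sum()) for v in fs_labels.values())
        assert int(y.sum()) == total_seiz

    def test_windows_avoid_seizures(self, small_cohort, fs_labels):
        for p in small_cohort:
            cand = _candidate_windows(
                fs_labels[p.patient_id], p.events, p.duration_s, 300
            )
            for s in cand:
                for e in p.events:
                    assert s + 60 <= e.onset_s or s >= e.end_s

    def test_zero_candidates_is_an_error(self):
        p = _patient_without_events(700)
        labels = {p.patient_id: np.ones(p.segments.n_segments, dtype=np.int8)}
        with pytest.raises(ValueError, match="candidate"):
            sd.subsample_training_set([p], labels, seed=0)
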