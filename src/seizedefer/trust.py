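"""Trust scores: nearest-neighbour distance ratios in a PCA-reduced space.

A prediction's trust score is computed by projecting the segment's feature
vector to (at most) 20 principal components and taking

    score = dist(x, nearest reference point of the OTHER class)
          / dist(x, nearest reference point of the PREDICTED class).

A score > 1 means the segment looks typical for its predicted class; a low
score marks an atypical (potentially artifactual) prediction.  The reference
sets are the full projected classes of a per-patient subsample — no
density-based filtering of the reference sets is applied, which removes the
two hyper-parameters such filtering would introduce.

The subsampling scheme keeps trust fitting and scoring fast on multi-day
recordings: all seizure-labelled segments are kept, and per patient 100
one-minute non-seizure windows (30 non-overlapping 2-s segments each) are
drawn from a 15-min-spaced candidate grid, falling back to a 5-min grid when
fewer than 100 candidates exist.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances_argmin_min
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "TrustScorer",
    "fit_trust_model",
    "trust_score",
    "score_series",
    "subsample_training_set",
]


class TrustScorer(BaseEstimator):
    """Distance-ratio trust model: linear projection + per-class reference sets.

    Parameters
    ----------
    n_components : dimensionality of the PCA projection (capped at the
        feature dimension).
    regime : "ci" or "fs"; which label regime the reference labels came from.
        Informational only.

    Attributes
    ----------
    pca_ : fitted :class:`~sklearn.decomposition.PCA`.
    class0_points_, class1_points_ : projected reference sets.
    """

    def __init__(self, n_components: int = 20, regime: str = "fs"):
        self.n_components = n_components
        self.regime = regime

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y).astype(int)
        if not ((y == 0).any() and (y == 1).any()):
            raise ValueError("both classes must be present to fit a trust model")
        n_comp = min(self.n_components, X.shape[1])
        self.pca_ = PCA(n_components=n_comp).fit(X)
        Z = self.pca_.transform(X)
        self.class0_points_ = Z[y == 0]
        self.class1_points_ = Z[y == 1]
        return self

    def score_samples(self, X, predicted) -> np.ndarray:
        """Trust score of each row of ``X`` given its predicted class (0/1).

        Zero-denominator convention: if a point coincides with a reference
        point of its predicted class, the score is ``inf`` when the distance
        to the other class is positive and 1 when it is also zero.
        """
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        predicted = np.asarray(predicted).astype(int)
        if predicted.shape[0] != X.shape[0]:
            raise ValueError("predictions and features have mismatched lengths")
        Z = self.pca_.transform(X)
        # brute-force exact nearest neighbour (BLAS-backed); tree indices
        # degrade badly at 20 dimensions
        d0 = pairwise_distances_argmin_min(Z, self.class0_points_)[1]
        d1 = pairwise_distances_argmin_min(Z, self.class1_points_)[1]
        d_pred = np.where(predicted == 1, d1, d0)
        d_other = np.where(predicted == 1, d0, d1)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = d_other / d_pred
        score[(d_pred == 0) & (d_other > 0)] = np.inf
        score[(d_pred == 0) & (d_other == 0)] = 1.0
        return score


def fit_trust_model(X, y, n_components: int = 20, regime: str = "fs") -> TrustScorer:
    """Fit a :class:`TrustScorer` on a (subsampled) training set."""
    return TrustScorer(n_components=n_components, regime=regime).fit(X, y)


def trust_score(model: TrustScorer, x, predicted: int) -> float:
    """Trust score of a single feature vector under its predicted class."""
    return float(model.score_samples(np.atleast_2d(x), [predicted])[0])


def score_series(model: TrustScorer, segments, predictions) -> np.ndarray:
    """Vectorised trust scores for a whole segment grid.

    ``segments`` may be a :class:`~seizedefer.simulate.SegmentSeries` or a
    plain feature matrix.
    """
    X = getattr(segments, "features", segments)
    return model.score_samples(X, predictions)


def _candidate_windows(
    labels: np.ndarray, events, duration_s: float, spacing_s: int, artifacts=()
):
    """Starts of fully non-seizure 1-min windows on a ``spacing_s`` grid.

    ``artifacts`` holds intervals to avoid as well (used when curating a
    classifier training set; trust models keep artifact windows)."""
    out = []
    for s in range(0, int(duration_s) - 59, spacing_s):
        seg_starts = range(s, s + 59, 2)  # 30 non-overlapping 2-s segments
        if any(labels[t] for t in seg_starts):
            continue
        if any(s < e.end_s and s + 60 > e.onset_s for e in events):
            continue
        if any(s < b1 and s + 60 > b0 for b0, b1 in artifacts):
            continue
        out.append(s)
    return out


def subsample_training_set(
    patients,
    labels: dict,
    seed: int,
    n_windows: int = 100,
    spacing_s: int = 900,
    fallback_spacing_s: int = 300,
    exclude_artifacts: bool = False,
):
    """Per-patient subsample used to fit trust models (and pooled classifiers).

    All seizure-labelled segments are included.  Non-seizure segments come
    from one-minute windows on a ``spacing_s``-spaced grid (default 15 min),
    each contributing 30 non-overlapping 2-s segments; ``n_windows`` windows
    are drawn uniformly without replacement per patient.  When the grid
    yields fewer than ``n_windows`` candidates the spacing falls back to
    ``fallback_spacing_s`` (default 5 min), and if even that grid is short
    all its windows are taken.  Deterministic given ``seed``.

    Parameters
    ----------
    patients : list of :class:`~seizedefer.simulate.PatientData`.
    labels : mapping patient_id -> per-segment binary labels (the regime the
        trust model is being fitted under).
    seed : int seed; one independent substream per patient.
    exclude_artifacts : avoid windows overlapping known artifact bursts.
        Classifier training sets are curated this way (routine artifact
        rejection); trust reference sets are not — randomly drawn windows
        keep whatever artifacts they contain, which is what lets trust
        scores recognise artifactual predictions.

    Returns
    -------
    X, y : pooled feature matrix and labels of the subsample.
    """
    children = np.random.SeedSequence(seed).spawn(len(patients))
    X_parts, y_parts = [], []
    for patient, child in zip(patients, children):
        lab = np.asarray(labels[patient.patient_id])
        feats = patient.segments.features
        rng = np.random.default_rng(child)

        avoid = patient.artifacts if exclude_artifacts else ()
        cand = _candidate_windows(
            lab, patient.events, patient.duration_s, spacing_s, avoid
        )
        if len(cand) < n_windows:
            cand = _candidate_windows(
                lab, patient.events, patient.duration_s, fallback_spacing_s, avoid
            )
        if not cand:
            raise ValueError(
                f"patient {patient.patient_id} has no non-seizure candidate windows"
            )
        take = min(n_windows, len(cand))
        chosen = rng.choice(len(cand), size=take, replace=False)
        nonseiz_idx = np.concatenate(
            [np.arange(cand[i], cand[i] + 59, 2) for i in sorted(chosen)]
        )
        seiz_idx = np.flatnonzero(lab == 1)
        idx = np.concatenate([seiz_idx, nonseiz_idx])
        X_parts.append(feats[idx])
        y_parts.append(lab[idx])
    return np.concatenate(X_parts), np.concatenate(y_parts)
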