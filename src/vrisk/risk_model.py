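"""Radial-kernel maximum-margin risk classifier and operating point.

Document vectors are z-scored with statistics fit on the training fold only,
then fed to an RBF support vector machine; the continuous decision score is
the signed distance to the margin boundary. The dichotomizing threshold is
chosen on pooled out-of-fold scores to balance false positives against false
negatives (minimize |FP - FN|), the operating point that trades the two error
types evenly at single-digit prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class ClassifierConfig:
    """RBF-SVM settings: ``cost`` is the margin-violation penalty C,
    ``kernel_width`` the RBF scale gamma ("scale" = 1 / (dim * feature
    variance), fit on training data)."""

    cost: float = 1.0
    kernel_width: float | str = "scale"
    seed: int = 0

    def validate(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if not isinstance(self.kernel_width, str) and self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")


class RiskClassifier:
    """Standardizer + RBF-SVM producing real-valued risk scores."""

    def __init__(self, config: ClassifierConfig):
        config.validate()
        self.config = config
        self.scaler_: StandardScaler | None = None
        self.svm_: SVC | None = None

    def fit(self, vectors: np.ndarray, labels: np.ndarray) -> "RiskClassifier":
        vectors = np.asarray(vectors, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if vectors.ndim != 2 or len(vectors) != len(labels):
            raise ValueError("vectors must be 2-D and aligned with labels")
        if len(np.unique(labels)) < 2:
            raise ValueError("training labels contain a single class; need both outcomes")
        self.scaler_ = StandardScaler().fit(vectors)
        self.svm_ = SVC(
            C=self.config.cost,
            kernel="rbf",
            gamma=self.config.kernel_width,
            random_state=self.config.seed,
        ).fit(self.scaler_.transform(vectors), labels)
        return self

    def decision_scores(self, vectors: np.ndarray) -> np.ndarray:
        """One finite signed score per vector; rows independent."""
        if self.svm_ is None:
            raise ValueError("classifier is not fitted")
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[1] != self.scaler_.mean_.shape[0]:
            raise ValueError(
                f"vector dimension {vectors.shape} does not match training "
                f"dimension {self.scaler_.mean_.shape[0]}"
            )
        return self.svm_.decision_function(self.scaler_.transform(vectors))


def fit_classifier(
    vectors: np.ndarray, labels: np.ndarray, config: ClassifierConfig
) -> RiskClassifier:
    return RiskClassifier(config).fit(vectors, labels)


def predict_scores(classifier: RiskClassifier, vectors: np.ndarray) -> np.ndarray:
    return classifier.decision_scores(vectors)


def confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float):
    """(TN, FN, TP, FP) with predicted class = 1 iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tn, fn, tp, fp


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold minimizing |FP - FN| over all distinct cut-points.

    Candidate cuts sit below the minimum score, between consecutive distinct
    scores, and above the maximum. Ties on |FP - FN| are broken toward the
    smaller FP (i.e. the higher threshold); remaining ties toward the larger
    threshold, for determinism.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection needs both outcome classes")
    uniq = np.unique(scores)
    # cut c means predict 1 iff score >= c
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    n_pos = int((labels == 1).sum())
    order = np.argsort(scores, kind="mergesort")
    s_sorted, l_sorted = scores[order], labels[order]
    # for each cut, number predicted positive = n - (first index with s >= cut)
    idx = np.searchsorted(s_sorted, cuts, side="left")
    pos_below = np.concatenate([[0], np.cumsum(l_sorted)])[idx]  # positives with s < cut
    fn = pos_below
    tp = n_pos - fn
    pred_pos = len(scores) - idx
    fp = pred_pos - tp
    gap = np.abs(fp - fn)
    best = np.flatnonzero(gap == gap.min())
    best = best[fp[best] == fp[best].min()]
    return float(cuts[best[-1]])
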