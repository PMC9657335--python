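"""k-nearest-neighbors classification of the 4-feature EMG vectors.

Lazy learner: fitting stores the training rows verbatim; prediction is an
exhaustive Euclidean-distance search (exact at these dataset sizes).  The
default k = 9 is odd, so binary majority votes cannot tie.  Distance ties
are broken in favour of the lower training-row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix

__all__ = ["KnnModel", "knn_fit", "knn_predict"]


@dataclass
class KnnModel:
    train_points: np.ndarray  # (n, d)
    train_labels: np.ndarray  # (n,)
    k: int = 9
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.train_points = np.asarray(self.train_points, dtype=float)
        self.train_labels = np.asarray(self.train_labels, dtype=int)
        if not 1 <= self.k <= len(self.train_points):
            raise ValueError(f"k={self.k} must satisfy 1 <= k <= n={len(self.train_points)}")
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")


def knn_fit(features, labels, k: int = 9) -> KnnModel:
    """Store the training feature rows and labels (no computation)."""
    if isinstance(features, FeatureMatrix):
        points = features.values
        if labels is None:
            labels = features.labels
    else:
        points = np.asarray(features, dtype=float)
    return KnnModel(train_points=points, train_labels=np.asarray(labels, dtype=int), k=k)


def knn_predict(model: KnnModel, queries: np.ndarray) -> np.ndarray:
    """Majority label among the k nearest training rows, per query.

    Exhaustive squared-Euclidean distances; stable argsort breaks distance
    ties by lower training-row index; a tied binary vote (even k only)
    resolves to class 0.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.train_points.shape[1]:
        raise ValueError(
            f"query dimension {queries.shape[1]} != "
            f"training dimension {model.train_points.shape[1]}"
        )
    # squared distances via the expansion ||q||^2 - 2 q.t + ||t||^2
    d2 = (
        (queries**2).sum(axis=1, keepdims=True)
        - 2.0 * queries @ model.train_points.T
        + (model.train_points**2).sum(axis=1)
    )
    order = np.argsort(d2, axis=1, kind="stable")[:, : model.k]
    votes = model.train_labels[order].sum(axis=1)
    return (2 * votes > model.k).astype(int)
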