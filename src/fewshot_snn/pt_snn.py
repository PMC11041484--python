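"""PT-SNN: nearest-class-mean classification by mean cosine similarity.

Frozen first-order embeddings are classified without any training: a test
sample is scored against every support sample by cosine similarity, the
similarities are averaged per class, and the class with the largest mean
wins (if the means for classes C1 and C2 are 0.2 and 0.6, the sample is
assigned C2).  This is a class-mean variant of k-nearest-neighbours in
cosine space.

The computation is fully vectorized.  With ``T`` the row-L2-normalized test
matrix and ``S`` the row-L2-normalized support matrix, the similarity table
is ``T @ S.T`` (n_test x n_train).  A per-class one-hot label table over the
support rows, L1-normalized per class row, turns the matrix product
``sim_table @ label_table.T`` into exactly the per-class arithmetic means.
Predictions are the row argmax.  A sigmoid adds nothing at test time — it is
monotone, so the argmax is unchanged — and is therefore omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingSet, l2_normalize
from .exceptions import DataError

__all__ = ["ClassScoreTable", "class_scores", "classify", "PTSNNClassifier"]


@dataclass(frozen=True)
class ClassScoreTable:
    """``n_test x N`` mean per-class cosine similarities.

    ``values[t, c]`` is the arithmetic mean of test sample ``t``'s cosine
    similarities to every support sample of class ``class_order[c]``.
    """

    values: np.ndarray
    class_order: list[str]

    def predicted_labels(self) -> list[str]:
        # np.argmax keeps the lowest index on ties -> deterministic tie rule:
        # first class in class_order wins.
        idx = np.argmax(self.values, axis=1)
        return [self.class_order[k] for k in idx]


def class_scores(train: EmbeddingSet, test_vectors: np.ndarray) -> ClassScoreTable:
    """Mean cosine similarity of every test row to every support class.

    Parameters
    ----------
    train
        Support set; every class in ``train.class_order`` must have at least
        one row (guaranteed since classes are derived from the labels).
    test_vectors
        ``n_test x d`` matrix, same ``d`` as the support set.
    """
    test_vectors = np.atleast_2d(np.asarray(test_vectors, dtype=np.float64))
    if test_vectors.shape[1] != train.dim:
        raise DataError(
            f"dimension mismatch: train is {train.vectors.shape}, "
            f"test is {test_vectors.shape}"
        )
    order = train.class_order
    if len(order) < 2:
        raise DataError(f"need >= 2 classes to classify, got {order}")

    sim_table = l2_normalize(test_vectors) @ l2_normalize(train.vectors).T

    # One-hot class membership over support rows, L1-normalized per class row,
    # so the matmul below averages rather than sums.
    n_train = train.n_samples
    label_table = np.zeros((len(order), n_train), dtype=np.float64)
    class_idx = {c: k for k, c in enumerate(order)}
    for row, lab in enumerate(train.labels):
        label_table[class_idx[lab], row] = 1.0
    label_table /= label_table.sum(axis=1, keepdims=True)

    return ClassScoreTable(sim_table @ label_table.T, order)


def classify(train: EmbeddingSet, test_vectors: np.ndarray) -> list[str]:
    """Predict per test row the class with maximal mean cosine similarity.

    Ties break to the earliest class in ``train.class_order``.
    """
    return class_scores(train, test_vectors).predicted_labels()


class PTSNNClassifier:
    """Handle object used by the episodic evaluator; no training state."""

    name = "pt-snn"

    def fit(self, train: EmbeddingSet) -> "PTSNNClassifier":
        self._train = train
        return self

    def predict(self, test_vectors: np.ndarray) -> list[str]:
        return classify(self._train, test_vectors)

    def scores(self, test_vectors: np.ndarray) -> ClassScoreTable:
        return class_scores(self._train, test_vectors)
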