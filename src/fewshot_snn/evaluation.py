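"""N-way-K-shot episodic evaluation with M-iteration averaging.

Few-shot metrics computed on one tiny support sample are unstable, so each
experiment draws M independent episodes (seeded by the iteration index, so
iteration ``Idx`` uses seed ``base_seed + Idx``), evaluates the classifier
on each, and reports the arithmetic mean:

    Metric = (sum_i Metric_i) / M,    with M = 3 by default.

Two episode modes are provided.  ``complement`` treats everything not drawn
into the support set as the test set (with n = 444 samples and N = 4
classes this yields the train/test sizes 16/428, 32/412 and 64/380 for
K = 4/8/16).  ``fixed_test`` evaluates every episode against one held-out
set supplied by the caller.

Precision, recall and F score are multi-class with configurable averaging
(macro by default — the conservative choice under heavy class imbalance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .embeddings import EmbeddingSet
from .exceptions import ConfigurationError, DataError

__all__ = [
    "Episode",
    "MetricsRecord",
    "sample_episode",
    "compute_metrics",
    "evaluate_averaged",
]

_AVERAGING = ("macro", "weighted", "micro")


@dataclass(frozen=True)
class Episode:
    """One seeded K-shot support/test split."""

    k_shots: int
    n_classes: int
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    @property
    def train_size(self) -> int:
        return self.train_idx.shape[0]

    @property
    def test_size(self) -> int:
        return self.test_idx.shape[0]


@dataclass(frozen=True)
class MetricsRecord:
    """Per-iteration (precision, recall, F) rows and their arithmetic mean."""

    per_iteration: np.ndarray  # (M, 3)
    mean: tuple[float, float, float]
    m_iterations: int

    @classmethod
    def from_rows(cls, rows: np.ndarray) -> "MetricsRecord":
        rows = np.asarray(rows, dtype=np.float64)
        mu = rows.mean(axis=0)
        return cls(rows, (float(mu[0]), float(mu[1]), float(mu[2])), rows.shape[0])


def sample_episode(
    data: EmbeddingSet,
    k_shots: int,
    seed: int,
    mode: str = "complement",
    fixed_test: EmbeddingSet | None = None,
) -> Episode:
    """Draw K samples per class without replacement, seeded.

    ``complement`` mode: the test indices are every sample not drawn.
    ``fixed_test`` mode: the caller provides the test set; test indices
    refer to it.
    """
    if mode not in ("complement", "fixed_test"):
        raise ConfigurationError(f"unknown episode mode {mode!r}")
    if mode == "fixed_test" and fixed_test is None:
        raise ConfigurationError("fixed_test mode requires a fixed_test set")
    if k_shots < 1:
        raise DataError(f"k_shots must be >= 1, got {k_shots}")

    rng = np.random.default_rng(seed)
    classes = data.class_order
    need = k_shots + (1 if mode == "complement" else 0)
    train_idx: list[int] = []
    for cls in classes:
        cls_idx = np.flatnonzero(data.labels == cls)
        if cls_idx.size < need:
            raise DataError(
                f"class {cls!r} has {cls_idx.size} samples; "
                f"needs >= {need} for a {k_shots}-shot episode in {mode} mode"
            )
        chosen = rng.choice(cls_idx, size=k_shots, replace=False)
        train_idx.extend(sorted(chosen.tolist()))
    train_arr = np.asarray(train_idx, dtype=int)

    if mode == "complement":
        mask = np.ones(data.n_samples, dtype=bool)
        mask[train_arr] = False
        test_arr = np.flatnonzero(mask)
        test_ids = tuple(data.ids[i] for i in test_arr)
    else:
        test_arr = np.arange(fixed_test.n_samples)
        test_ids = tuple(fixed_test.ids)

    return Episode(
        k_shots=k_shots,
        n_classes=len(classes),
        seed=seed,
        train_idx=train_arr,
        test_idx=test_arr,
        train_ids=tuple(data.ids[i] for i in train_arr),
        test_ids=test_ids,
    )


def compute_metrics(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    averaging: str = "macro",
) -> tuple[float, float, float]:
    """Multi-class precision, recall and F1 under the chosen averaging."""
    if averaging not in _AVERAGING:
        raise ConfigurationError(
            f"unknown averaging {averaging!r}; choose from {_AVERAGING}"
        )
    true_labels = [str(l) for l in true_labels]
    predicted_labels = [str(l) for l in predicted_labels]
    if len(true_labels) == 0:
        raise DataError("empty label sequences")
    if len(true_labels) != len(predicted_labels):
        raise DataError(
            f"{len(true_labels)} true labels but {len(predicted_labels)} predictions"
        )
    labels = sorted(set(true_labels) | set(predicted_labels))
    p, r, f, _ = precision_recall_fscore_support(
        true_labels,
        predicted_labels,
        labels=labels,
        average=averaging,
        zero_division=0,
    )
    return float(p), float(r), float(f)


def evaluate_averaged(
    data: EmbeddingSet,
    method: Callable[[], object],
    k_shots: int,
    m_iterations: int = 3,
    mode: str = "complement",
    fixed_test: EmbeddingSet | None = None,
    averaging: str = "macro",
    base_seed: int = 0,
) -> MetricsRecord:
    """Run M seeded episodes of ``method`` and average the metrics.

    Parameters
    ----------
    method
        Zero-argument factory returning a fresh classifier handle with
        ``fit(train: EmbeddingSet)`` and ``predict(test_vectors)`` — e.g.
        ``PTSNNClassifier`` or ``lambda: SOESNNClassifier(cfg)``.
    base_seed
        Episode ``Idx`` (0-based) uses seed ``base_seed + Idx``; the default
        0 reproduces the canonical seeds 0..M-1.
    """
    if m_iterations < 1:
        raise ConfigurationError(f"m_iterations must be >= 1, got {m_iterations}")
    rows = np.zeros((m_iterations, 3), dtype=np.float64)
    for idx in range(m_iterations):
        ep = sample_episode(data, k_shots, base_seed + idx, mode, fixed_test)
        train = data.subset(ep.train_idx)
        if mode == "complement":
            test_vectors = data.vectors[ep.test_idx]
            true = data.labels[ep.test_idx].tolist()
        else:
            test_vectors = fixed_test.vectors
            true = fixed_test.labels.tolist()
        clf = method()
        predicted = clf.fit(train).predict(test_vectors)
        rows[idx] = compute_metrics(true, predicted, averaging)
    return MetricsRecord.from_rows(rows)
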