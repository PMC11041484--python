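"""Siamese-style pair augmentation.

A support set of ``NK`` labeled samples is replaced by all unique unordered
sample pairs, each flagged 1 if both members share a class and 0 otherwise:

    D_pairs = {(x_i, x_j) | i < j},    |D_pairs| = ((NK)^2 - NK) / 2

so 8 samples yield 28 pairs (a 3.5-fold augmentation) and 16 yield 120
(7.5-fold).  The pair set is the training data of the second-order encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingSet
from .exceptions import DataError

__all__ = ["PairSet", "make_pairs", "pair_count", "augmentation_factor"]


@dataclass(frozen=True)
class PairSet:
    """Unique index pairs with same/different-class flags.

    ``i``, ``j`` and ``same_class`` are aligned 1-D integer arrays with
    ``i < j`` everywhere, ordered lexicographically by ``(i, j)``.
    ``source_size`` is the number of samples the pairs were drawn from.
    """

    i: np.ndarray
    j: np.ndarray
    same_class: np.ndarray
    source_size: int

    def __len__(self) -> int:
        return self.i.shape[0]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("i\tj\tsame_class\n")
            for a, b, s in zip(self.i, self.j, self.same_class):
                fh.write(f"{a}\t{b}\t{s}\n")

    @classmethod
    def from_tsv(cls, path, source_size: int | None = None) -> "PairSet":
        rows = np.loadtxt(path, dtype=int, skiprows=1, ndmin=2)
        if rows.size == 0:
            rows = rows.reshape(0, 3)
        src = source_size if source_size is not None else int(rows[:, 1].max()) + 1
        return cls(rows[:, 0].copy(), rows[:, 1].copy(), rows[:, 2].copy(), src)


def make_pairs(data: EmbeddingSet) -> PairSet:
    """Enumerate every unique unordered pair of samples in ``data``.

    Pairs are emitted in lexicographic ``(i, j)`` order so the downstream
    training pipeline is reproducible; any shuffling happens there, under
    the training seed.
    """
    n = data.n_samples
    if n < 2:
        raise DataError(f"need >= 2 samples to build pairs, got {n}")
    ii, jj = np.triu_indices(n, k=1)
    same = (data.labels[ii] == data.labels[jj]).astype(np.int64)
    return PairSet(ii.astype(np.int64), jj.astype(np.int64), same, n)


def pair_count(n_classes: int, k_shots: int) -> int:
    """Number of unique pairs from an N-way-K-shot support set: ((NK)^2 - NK)/2."""
    if n_classes < 1 or k_shots < 1:
        raise DataError(
            f"n_classes and k_shots must be >= 1, got {n_classes}, {k_shots}"
        )
    nk = n_classes * k_shots
    return (nk * nk - nk) // 2


def augmentation_factor(n_classes: int, k_shots: int) -> float:
    """Pairs per original sample: (NK - 1) / 2 (e.g. 3.5 at NK=8, 7.5 at NK=16)."""
    nk = n_classes * k_shots
    return pair_count(n_classes, k_shots) / nk
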