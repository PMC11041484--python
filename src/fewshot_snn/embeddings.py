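"""First-order sentence embeddings and cosine-similarity primitives.

A :class:`LabeledCorpus` (texts + class labels) is mapped to an
:class:`EmbeddingSet` (an ``n x d`` real matrix with aligned labels) by a
pluggable sentence-embedding backend.  Real pretrained-transformer adapters
(BERT-family sentence encoders) can be registered behind the same
:class:`EmbeddingBackend` interface; the bundled default is a deterministic
hashed character-n-gram backend so that every downstream algorithm is
exercisable offline.  The classifiers in this package are backend-agnostic:
they only consume the embedding matrix.

Cosine similarity between two embeddings ``A`` and ``B`` is

    cos(A, B) = (A . B) / (||A||_2 ||B||_2)

and is the single geometric primitive behind both the nearest-class-mean
classifier and the Siamese pair loss.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .exceptions import ConfigurationError, DataError

__all__ = [
    "LabeledCorpus",
    "EmbeddingSet",
    "EmbeddingBackend",
    "HashedNgramBackend",
    "get_backend",
    "register_backend",
    "available_backends",
    "embed_corpus",
    "l2_normalize",
    "cosine_similarity_matrix",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class LabeledCorpus:
    """Texts with class labels; the raw-input role.

    Parameters
    ----------
    texts
        Sentence strings, one per sample.
    labels
        Class label per text, aligned 1:1.
    ids
        Stable sample identifiers; generated as ``s0000, s0001, ...`` when
        not provided.
    """

    texts: tuple[str, ...]
    labels: tuple[str, ...]
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        texts = tuple(self.texts)
        labels = tuple(str(l) for l in self.labels)
        if len(texts) == 0:
            raise DataError("corpus is empty")
        if len(texts) != len(labels):
            raise DataError(
                f"{len(texts)} texts but {len(labels)} labels"
            )
        ids = tuple(self.ids) or tuple(f"s{i:04d}" for i in range(len(texts)))
        if len(ids) != len(texts):
            raise DataError(f"{len(texts)} texts but {len(ids)} ids")
        object.__setattr__(self, "texts", texts)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.texts)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(zip(self.ids, self.texts, self.labels))


class EmbeddingSet:
    """``n x d`` matrix of finite reals with aligned class labels and ids.

    The latent-space role: both the episode support set and the test set are
    carried in this container.  Rows are samples; ``labels[i]`` is the class
    of row ``i``.
    """

    def __init__(
        self,
        vectors: np.ndarray,
        labels: Sequence[str],
        ids: Sequence[str] | None = None,
    ) -> None:
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2:
            raise DataError(f"vectors must be 2-D, got shape {vectors.shape}")
        n, d = vectors.shape
        if n < 1 or d < 1:
            raise DataError(f"need n >= 1 and d >= 1, got shape {vectors.shape}")
        if not np.all(np.isfinite(vectors)):
            raise DataError("vectors contain NaN or Inf entries")
        labels = np.asarray([str(l) for l in labels], dtype=object)
        if labels.shape[0] != n:
            raise DataError(f"{n} rows but {labels.shape[0]} labels")
        if ids is None:
            ids = [f"s{i:04d}" for i in range(n)]
        ids = tuple(str(i) for i in ids)
        if len(ids) != n:
            raise DataError(f"{n} rows but {len(ids)} ids")
        self.vectors = vectors
        self.labels = labels
        self.ids = ids

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def class_order(self) -> list[str]:
        """Sorted distinct labels — the canonical class ordering."""
        return sorted(set(self.labels.tolist()))

    def subset(self, indices: Sequence[int]) -> "EmbeddingSet":
        idx = np.asarray(indices, dtype=int)
        return EmbeddingSet(
            self.vectors[idx],
            self.labels[idx],
            [self.ids[i] for i in idx],
        )

    def __len__(self) -> int:
        return self.n_samples

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EmbeddingSet(n={self.n_samples}, d={self.dim}, "
            f"classes={self.class_order})"
        )


# ---------------------------------------------------------------------------
# backends


class EmbeddingBackend:
    """Interface every sentence-embedding backend implements.

    Attributes
    ----------
    name : str
        Registry identifier.
    dimension : int
        Output dimensionality, fixed for the backend's lifetime.
    deterministic : bool
        Whether the same text always maps to the same vector.
    """

    name: str = "abstract"
    dimension: int = 0
    deterministic: bool = False

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        raise NotImplementedError


class HashedNgramBackend(EmbeddingBackend):
    """Deterministic offline backend: signed hashed bag of word unigrams and
    character trigrams.

    Each feature (a word, or a character 3-gram of the whitespace-collapsed
    text) is hashed with BLAKE2b to a bucket in ``[0, dimension)`` and a sign
    in {-1, +1}; the embedding is the signed count vector.  Two texts sharing
    vocabulary land near each other in cosine space, which is all the
    downstream algorithms require.  No model download, no random state.
    """

    deterministic = True

    def __init__(self, dimension: int = 256, name: str = "hashed-ngram"):
        if dimension < 2:
            raise ConfigurationError(f"backend dimension must be >= 2, got {dimension}")
        self.dimension = int(dimension)
        self.name = name

    @staticmethod
    def _features(text: str) -> list[str]:
        toks = text.lower().split()
        feats = [f"w:{t}" for t in toks]
        joined = " ".join(toks)
        feats.extend(f"c:{joined[i:i + 3]}" for i in range(len(joined) - 2))
        return feats

    def _hash(self, feature: str) -> tuple[int, int]:
        h = hashlib.blake2b(feature.encode("utf-8"), digest_size=8).digest()
        v = int.from_bytes(h, "little")
        return (v >> 1) % self.dimension, 1 - 2 * (v & 1)

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension), dtype=np.float64)
        for row, text in enumerate(texts):
            for feat in self._features(text):
                bucket, sign = self._hash(feat)
                out[row, bucket] += sign
        return out


_REGISTRY: dict[str, Callable[..., EmbeddingBackend]] = {
    "hashed-ngram": HashedNgramBackend,
}


def register_backend(name: str, factory: Callable[..., EmbeddingBackend]) -> None:
    """Register a backend factory (e.g. a sentence-transformer adapter)."""
    _REGISTRY[name] = factory


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown backend {name!r}; available: {available_backends()}"
        ) from None
    return factory(**kwargs)


# ---------------------------------------------------------------------------
# operations


def embed_corpus(corpus: LabeledCorpus, backend: EmbeddingBackend) -> EmbeddingSet:
    """Embed every text of ``corpus`` with ``backend``, order preserved.

    Raises
    ------
    DataError
        If the corpus contains an empty/whitespace-only text (reported with
        its sample id).
    """
    for sid, text, _ in corpus:
        if not text.strip():
            raise DataError(f"empty text for sample {sid!r}")
    vectors = backend.embed(corpus.texts)
    return EmbeddingSet(vectors, corpus.labels, corpus.ids)


def l2_normalize(m: np.ndarray) -> np.ndarray:
    """Scale every row of ``m`` to unit Euclidean norm.

    Zero rows are rejected: cosine similarity is undefined for them, and a
    silent mapping would corrupt every downstream score.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim == 1:
        m = m[None, :]
    norms = np.linalg.norm(m, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise DataError(f"cannot L2-normalize zero row(s) at index {zero.tolist()}")
    return m / norms[:, None]


def cosine_similarity_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities: entry ``(i, j)`` is ``cos(a[i], b[j])``.

    Computed as the inner products of the L2-normalized rows, the identity
    the vectorized classifier exploits.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise DataError(
            f"dimension mismatch: a has shape {a.shape}, b has shape {b.shape}"
        )
    return l2_normalize(a) @ l2_normalize(b).T
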