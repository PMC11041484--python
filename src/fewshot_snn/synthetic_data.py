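"""Synthetic labeled embedding sets and toy corpora.

The real benchmark corpus — 444 clinical sentences in 4 heavily imbalanced
classes (55.2 / 26.4 / 10.8 / 7.7 %) — sits behind a data-use agreement, so
this module generates stand-ins with the statistical structure the methods
assume: class-conditional clusters in R^d whose centroids lie on the unit
hypersphere (cosine geometry carries the class signal, matching the scale
invariance of cosine similarity) with isotropic within-class noise, and
class counts obtained from the target proportions by largest-remainder
rounding so printed totals are hit exactly (444 -> 245/117/48/34).

``generate_toy_corpus`` additionally emits plain-text sentences drawn from
class-specific token pools, so the full text -> embedding -> classification
pipeline can be exercised end to end with the offline hash backend.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingSet, LabeledCorpus
from .exceptions import ConfigurationError, DataError

__all__ = [
    "TABLE_PROPORTIONS",
    "SyntheticConfig",
    "largest_remainder_counts",
    "generate",
    "generate_toy_corpus",
]

#: Class proportions of the emulated clinical benchmark (majority first).
TABLE_PROPORTIONS = (0.552, 0.264, 0.108, 0.077)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults: 444 samples, 4 classes, imbalance as above.

    ``within_class_noise`` is the standard deviation of the isotropic
    Gaussian noise added to each unit-norm class centroid; 0 collapses every
    sample onto its centroid, values around 1 drown the class signal.
    ``min_centroid_angle`` (degrees) is the smallest pairwise angle between
    class centroids, enforced by rejection sampling.
    """

    n_classes: int = 4
    dim: int = 32
    total_samples: int = 444
    class_proportions: tuple[float, ...] = TABLE_PROPORTIONS
    within_class_noise: float = 0.3
    min_centroid_angle: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.dim < 2:
            raise ConfigurationError(f"dim must be >= 2, got {self.dim}")
        if self.total_samples < self.n_classes:
            raise ConfigurationError("total_samples must be >= n_classes")
        props = tuple(float(p) for p in self.class_proportions)
        if len(props) != self.n_classes:
            raise ConfigurationError(
                f"{len(props)} proportions for {self.n_classes} classes"
            )
        if any(p <= 0 for p in props):
            raise ConfigurationError("class proportions must be positive")
        total = sum(props)
        # tolerate printed rounded percentages (e.g. summing to 1.001)
        props = tuple(p / total for p in props)
        if self.within_class_noise < 0:
            raise ConfigurationError("within_class_noise must be >= 0")
        object.__setattr__(self, "class_proportions", props)

    @property
    def class_names(self) -> list[str]:
        return [f"class{i}" for i in range(self.n_classes)]


def largest_remainder_counts(total: int, proportions) -> np.ndarray:
    """Integer counts summing to ``total``, closest to ``total * proportions``.

    Floors every quota, then hands the remaining units to the largest
    fractional remainders (ties to the lower class index).
    """
    props = np.asarray(proportions, dtype=np.float64)
    props = props / props.sum()
    quotas = total * props
    counts = np.floor(quotas).astype(int)
    short = total - int(counts.sum())
    # stable sort => ties resolved toward the lower index
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _sample_centroids(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm centroids with pairwise angle >= min_centroid_angle."""
    max_cos = np.cos(np.deg2rad(config.min_centroid_angle))
    for _ in range(1000):
        c = rng.standard_normal((config.n_classes, config.dim))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        gram = c @ c.T
        off_diag = gram[~np.eye(config.n_classes, dtype=bool)]
        if off_diag.size == 0 or off_diag.max() <= max_cos + 1e-12:
            return c
    raise DataError(
        f"could not place {config.n_classes} centroids in {config.dim} dims "
        f"with pairwise angle >= {config.min_centroid_angle} deg"
    )


def generate(config: SyntheticConfig) -> EmbeddingSet:
    """Class-conditional Gaussian clusters around well-separated unit centroids."""
    rng = np.random.default_rng(config.seed)
    counts = largest_remainder_counts(config.total_samples, config.class_proportions)
    centroids = _sample_centroids(config, rng)
    vectors = []
    labels = []
    for cls, (count, centroid) in enumerate(zip(counts, centroids)):
        noise = config.within_class_noise * rng.standard_normal((count, config.dim))
        vectors.append(centroid[None, :] + noise)
        labels.extend([config.class_names[cls]] * count)
    return EmbeddingSet(np.vstack(vectors), labels)


def generate_toy_corpus(
    config: SyntheticConfig, vocabulary_per_class: int = 20
) -> LabeledCorpus:
    """Plain-text corpus whose classes use disjoint token pools.

    Texts of 5-10 tokens are drawn from a per-class vocabulary
    (``class<i>tok<j>`` words), so the deterministic hash backend maps the
    classes to separable embedding clusters.
    """
    if vocabulary_per_class < 1:
        raise ConfigurationError("vocabulary_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    counts = largest_remainder_counts(config.total_samples, config.class_proportions)
    texts: list[str] = []
    labels: list[str] = []
    for cls, count in enumerate(counts):
        vocab = [f"class{cls}tok{j}" for j in range(vocabulary_per_class)]
        for _ in range(count):
            length = int(rng.integers(5, 11))
            words = rng.choice(vocab, size=length, replace=True)
            texts.append(" ".join(words.tolist()))
            labels.append(config.class_names[cls])
    return LabeledCorpus(tuple(texts), tuple(labels))
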