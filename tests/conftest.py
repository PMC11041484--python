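import numpy as np
import pytest

from fewshot_snn import EmbeddingSet, SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_two_class() -> EmbeddingSet:
    """Two orthogonal one-sample classes in the plane."""
    return EmbeddingSet(np.array([[1.0, 0.0], [0.0, 1.0]]), ["A", "B"])


@pytest.fixture
def clean_clusters() -> EmbeddingSet:
    """Noise-free 4-class clusters: every sample sits on its class centroid."""
    return generate(SyntheticConfig(within_class_noise=0.0, seed=7))


@pytest.fixture
def small_clusters() -> EmbeddingSet:
    """Well-separated 2-class clusters, 4 samples each, for encoder training."""
    return generate(
        SyntheticConfig(
            n_classes=2,
            class_proportions=(0.5, 0.5),
            total_samples=8,
            dim=32,
            within_class_noise=0.05,
            seed=11,
        )
    )


def scalar_mean_cosine_scores(train_vectors, train_labels, test_vectors, class_order):
    """Independent scalar oracle: per-sample, per-class mean cosine similarity.

    Plain double loop over test samples and support samples using the scalar
    cosine formula; deliberately shares no code with the vectorized path.
    """
    import math

    def cos(u, v):
        dot = sum(x * y for x, y in zip(u, v))
        nu = math.sqrt(sum(x * x for x in u))
        nv = math.sqrt(sum(x * x for x in v))
        return dot / (nu * nv)

    scores = []
    for t in test_vectors:
        row = []
        for cls in class_order:
            sims = [
                cos(t, tr)
                for tr, lab in zip(train_vectors, train_labels)
                if lab == cls
            ]
            row.append(sum(sims) / len(sims))
        scores.append(row)
    return np.array(scores)
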