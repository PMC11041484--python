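"""SOE-SNN: a trainable Siamese second-order encoder over frozen embeddings.

A bidirectional LSTM is stacked on top of the frozen first-order sentence
embeddings and trained as a Siamese network: two samples pass through the
same (weight-shared) encoder, their second-order embeddings are compared by
a distance function, and the sigmoid of that distance,

    out = sigmoid(distance(emb_1, emb_2)),

is fit with binary cross-entropy against the pair's same-class flag (1 for
same class, 0 for different), over the exhaustive unique-pair augmentation
of the encoder half of the support set.  AdamW is the optimizer.  The
first-order backend is never updated.  At test time the remaining (support)
half and the test set are pushed through the trained encoder and classified
with the nearest-class-mean cosine rule — no sigmoid needed there.

A first-order embedding is a single vector, not a sequence; to give the
recurrent encoder a genuine sequence the d-vector is viewed as
``chunk_length`` consecutive segments of size ``d / chunk_length``.  This
preserves all information and is configurable.

The encoder, its backpropagation and AdamW are implemented directly in
numpy; gradients are exact (the test suite checks them against central
finite differences).  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingSet
from .exceptions import ConfigurationError, DataError
from .pairs import PairSet, make_pairs
from . import pt_snn

__all__ = [
    "EncoderConfig",
    "EncoderModel",
    "IdentityEncoder",
    "split_for_soe",
    "train_encoder",
    "encode",
    "pair_similarity",
    "soe_classify",
    "SOESNNClassifier",
]

_DISTANCES = ("cosine_similarity", "negative_euclidean")
_EPS = 1e-12


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the second-order encoder.

    Parameters
    ----------
    input_dim
        First-order embedding dimensionality d.
    hidden_dim
        LSTM hidden size per direction.
    output_dim
        Second-order embedding size; defaults to ``input_dim``.
    chunk_length
        Number of segments the d-vector is split into to form the input
        sequence; must divide ``input_dim``.
    epochs, learning_rate, batch_size, weight_decay
        Training schedule.  ``batch_size=None`` uses all pairs per step
        (full batch — the natural choice at few-shot pair counts).
    seed
        Controls weight initialization and any minibatch shuffling.
    distance
        Pair-comparison function inside the sigmoid: ``cosine_similarity``
        (default, matching the geometry of the classifier) or
        ``negative_euclidean``.
    """

    input_dim: int
    hidden_dim: int = 32
    output_dim: int | None = None
    chunk_length: int = 16
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int | None = None
    weight_decay: float = 0.01
    seed: int = 0
    distance: str = "cosine_similarity"

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ConfigurationError(f"input_dim must be >= 1, got {self.input_dim}")
        if self.chunk_length < 1 or self.input_dim % self.chunk_length != 0:
            raise ConfigurationError(
                f"chunk_length ({self.chunk_length}) must divide "
                f"input_dim ({self.input_dim})"
            )
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.distance not in _DISTANCES:
            raise ConfigurationError(
                f"unknown distance {self.distance!r}; choose from {_DISTANCES}"
            )
        if self.output_dim is None:
            object.__setattr__(self, "output_dim", self.input_dim)

    @property
    def step_dim(self) -> int:
        """Size of each sequence element fed to the LSTM."""
        return self.input_dim // self.chunk_length


# ---------------------------------------------------------------------------
# LSTM forward/backward (batched, float64)
#
# Gate layout along the last axis: [i | f | g | o], each of width H.
#   z_t = x_t @ W + h_{t-1} @ U + b
#   c_t = sigmoid(f) * c_{t-1} + sigmoid(i) * tanh(g)
#   h_t = sigmoid(o) * tanh(c_t)
# Only the final hidden state is consumed, so backward propagates d h_T
# through time; input gradients are never needed (the first-order
# embeddings are frozen).


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_forward(X: np.ndarray, W: np.ndarray, U: np.ndarray, b: np.ndarray):
    """Run the LSTM over X (n, T, k); return final hidden state and caches."""
    n, T, _ = X.shape
    H = U.shape[0]
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    caches = []
    for t in range(T):
        z = X[:, t] @ W + h @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        caches.append((X[:, t], h, c, i, f, g, o, tanh_c))
        h, c = h_new, c_new
    return h, caches


def _lstm_backward(dh_T: np.ndarray, caches, W: np.ndarray, U: np.ndarray):
    """Backpropagate d(final hidden) through time; return dW, dU, db."""
    H = U.shape[0]
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H)
    dh = dh_T
    dc = np.zeros_like(dh_T)
    for x_t, h_prev, c_prev, i, f, g, o, tanh_c in reversed(caches):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += x_t.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ U.T
        dc = dc * f
    return dW, dU, db


def _init_params(config: EncoderConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    k, H, out = config.step_dim, config.hidden_dim, config.output_dim
    params: dict[str, np.ndarray] = {}
    for d in ("fw", "bw"):
        scale = 1.0 / math.sqrt(k + H)
        params[f"W_{d}"] = rng.standard_normal((k, 4 * H)) * scale
        params[f"U_{d}"] = rng.standard_normal((H, 4 * H)) * scale
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias: remember by default
        params[f"b_{d}"] = b
    params["W_out"] = rng.standard_normal((2 * H, out)) / math.sqrt(2 * H)
    params["b_out"] = np.zeros(out)
    return params


def _encode_forward(params: dict, config: EncoderConfig, vectors: np.ndarray):
    n = vectors.shape[0]
    X = vectors.reshape(n, config.chunk_length, config.step_dim)
    h_fw, cache_fw = _lstm_forward(X, params["W_fw"], params["U_fw"], params["b_fw"])
    h_bw, cache_bw = _lstm_forward(
        X[:, ::-1], params["W_bw"], params["U_bw"], params["b_bw"]
    )
    h_cat = np.concatenate([h_fw, h_bw], axis=1)
    emb = h_cat @ params["W_out"] + params["b_out"]
    return emb, (h_cat, cache_fw, cache_bw)


def _encode_backward(d_emb: np.ndarray, cache, params: dict, config: EncoderConfig):
    h_cat, cache_fw, cache_bw = cache
    H = config.hidden_dim
    grads = {
        "W_out": h_cat.T @ d_emb,
        "b_out": d_emb.sum(axis=0),
    }
    dh_cat = d_emb @ params["W_out"].T
    grads["W_fw"], grads["U_fw"], grads["b_fw"] = _lstm_backward(
        dh_cat[:, :H], cache_fw, params["W_fw"], params["U_fw"]
    )
    grads["W_bw"], grads["U_bw"], grads["b_bw"] = _lstm_backward(
        dh_cat[:, H:], cache_bw, params["W_bw"], params["U_bw"]
    )
    return grads


# ---------------------------------------------------------------------------
# pair loss


def _pair_forward(emb1: np.ndarray, emb2: np.ndarray, distance: str):
    """Similarity-in-(0,1) per pair plus what backward needs."""
    if distance == "cosine_similarity":
        n1 = np.maximum(np.linalg.norm(emb1, axis=1), _EPS)
        n2 = np.maximum(np.linalg.norm(emb2, axis=1), _EPS)
        s = np.sum(emb1 * emb2, axis=1) / (n1 * n2)
        aux = (n1, n2, s)
    else:  # negative_euclidean
        diff = emb1 - emb2
        dist = np.maximum(np.linalg.norm(diff, axis=1), _EPS)
        s = -dist
        aux = (diff, dist)
    return _sigmoid(s), aux


def _pair_backward(ds: np.ndarray, emb1, emb2, aux, distance: str):
    """d loss / d emb1, d emb2 given d loss / d s (s = raw distance score)."""
    if distance == "cosine_similarity":
        n1, n2, s = aux
        d1 = ds[:, None] * (emb2 / (n1 * n2)[:, None] - (s / n1 ** 2)[:, None] * emb1)
        d2 = ds[:, None] * (emb1 / (n1 * n2)[:, None] - (s / n2 ** 2)[:, None] * emb2)
    else:
        diff, dist = aux
        d1 = ds[:, None] * (-diff / dist[:, None])
        d2 = -d1
    return d1, d2


def pair_loss_and_grads(
    params: dict,
    config: EncoderConfig,
    vectors: np.ndarray,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    targets: np.ndarray,
):
    """Mean binary cross-entropy over pairs, plus gradients w.r.t. params.

    Exposed for gradient-checking; training uses it internally.
    """
    emb, cache = _encode_forward(params, config, vectors)
    out, aux = _pair_forward(emb[pair_i], emb[pair_j], config.distance)
    p = np.clip(out, 1e-12, 1.0 - 1e-12)
    loss = float(np.mean(-targets * np.log(p) - (1.0 - targets) * np.log(1.0 - p)))
    # d BCE / d s with out = sigmoid(s) collapses to (out - y) / n_pairs
    ds = (out - targets) / targets.shape[0]
    d1, d2 = _pair_backward(ds, emb[pair_i], emb[pair_j], aux, config.distance)
    d_emb = np.zeros_like(emb)
    np.add.at(d_emb, pair_i, d1)
    np.add.at(d_emb, pair_j, d2)
    return loss, _encode_backward(d_emb, cache, params, config)


class _AdamW:
    """Decoupled-weight-decay Adam; decay applies to matrices, not biases."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g ** 2
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if k.startswith(("W_", "U_")):
                update = update + self.wd * params[k]
            params[k] -= self.lr * update


# ---------------------------------------------------------------------------
# public surface


class EncoderModel:
    """A trained (or freshly initialized) second-order encoder."""

    def __init__(self, params: dict, config: EncoderConfig,
                 loss_history: Sequence[float] = ()):
        self.params = params
        self.config = config
        self.loss_history = list(loss_history)

    def encode(self, vectors: np.ndarray) -> np.ndarray:
        return encode(self, vectors)

    @classmethod
    def initialized(cls, config: EncoderConfig) -> "EncoderModel":
        """Untrained model with seeded initial weights (for determinism tests)."""
        return cls(_init_params(config), config)


class IdentityEncoder:
    """Pass-through encoder: second-order embedding == first-order embedding.

    Makes the SOE classification path reduce exactly to PT-SNN; useful as a
    null model and in reduction tests.
    """

    config = None

    def encode(self, vectors: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(vectors, dtype=np.float64))


def split_for_soe(train: EmbeddingSet, seed: int) -> tuple[EmbeddingSet, EmbeddingSet]:
    """Stratified halving of the support set.

    Half of each class trains the encoder; the other half is the
    classification support set.  With an odd per-class count the encoder
    side gets the larger half.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    enc_idx: list[int] = []
    sup_idx: list[int] = []
    labels = train.labels
    for cls in train.class_order:
        cls_idx = np.flatnonzero(labels == cls)
        if cls_idx.size < 2:
            raise DataError(
                f"class {cls!r} has {cls_idx.size} sample(s); "
                "need >= 2 to split for SOE training"
            )
        perm = rng.permutation(cls_idx)
        half = (cls_idx.size + 1) // 2  # odd count -> encoder side larger
        enc_idx.extend(perm[:half].tolist())
        sup_idx.extend(perm[half:].tolist())
    return train.subset(sorted(enc_idx)), train.subset(sorted(sup_idx))


def train_encoder(encoder_half: EmbeddingSet, config: EncoderConfig) -> EncoderModel:
    """Fit the Siamese encoder on the exhaustive pair set of ``encoder_half``.

    Minimizes mean binary cross-entropy between ``sigmoid(distance(.,.))``
    and the same-class flags with AdamW.  The first-order embeddings are
    inputs only — never updated.  Fully deterministic given ``config.seed``.
    """
    if encoder_half.n_samples < 2:
        raise DataError("encoder half needs >= 2 samples")
    if len(encoder_half.class_order) < 2:
        raise DataError(
            "encoder half has a single class; the contrastive pair loss is "
            "degenerate without different-class pairs"
        )
    if encoder_half.dim != config.input_dim:
        raise DataError(
            f"config.input_dim={config.input_dim} but data dim={encoder_half.dim}"
        )
    pairs: PairSet = make_pairs(encoder_half)
    targets = pairs.same_class.astype(np.float64)
    params = _init_params(config)
    opt = _AdamW(params, config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    n_pairs = len(pairs)
    history: list[float] = []
    for _ in range(config.epochs):
        if config.batch_size is None or config.batch_size >= n_pairs:
            loss, grads = pair_loss_and_grads(
                params, config, encoder_half.vectors, pairs.i, pairs.j, targets
            )
            opt.step(params, grads)
            history.append(loss)
        else:
            order = rng.permutation(n_pairs)
            epoch_loss = 0.0
            for start in range(0, n_pairs, config.batch_size):
                sel = order[start:start + config.batch_size]
                loss, grads = pair_loss_and_grads(
                    params, config, encoder_half.vectors,
                    pairs.i[sel], pairs.j[sel], targets[sel],
                )
                opt.step(params, grads)
                epoch_loss += loss * sel.size
            history.append(epoch_loss / n_pairs)
    return EncoderModel(params, config, history)


def encode(model: EncoderModel, vectors: np.ndarray) -> np.ndarray:
    """Second-order embeddings for ``vectors`` (n x input_dim -> n x output_dim)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    cfg = model.config
    if vectors.shape[1] != cfg.input_dim:
        raise DataError(
            f"expected {cfg.input_dim} columns, got shape {vectors.shape}"
        )
    emb, _ = _encode_forward(model.params, cfg, vectors)
    return emb


def pair_similarity(model: EncoderModel, v1: np.ndarray, v2: np.ndarray) -> float:
    """``sigmoid(distance(enc(v1), enc(v2)))`` — in (0, 1), symmetric."""
    v1 = np.asarray(v1, dtype=np.float64).ravel()
    v2 = np.asarray(v2, dtype=np.float64).ravel()
    cfg = model.config
    if v1.shape[0] != cfg.input_dim or v2.shape[0] != cfg.input_dim:
        raise DataError(
            f"expected vectors of length {cfg.input_dim}, "
            f"got {v1.shape[0]} and {v2.shape[0]}"
        )
    emb = encode(model, np.stack([v1, v2]))
    out, _ = _pair_forward(emb[:1], emb[1:], cfg.distance)
    return float(out[0])


def soe_classify(
    model, support_half: EmbeddingSet, test_vectors: np.ndarray
) -> list[str]:
    """Nearest-class-mean cosine classification in second-order space.

    Identical to the PT-SNN rule, applied to the encoder's outputs for both
    the support half and the test vectors.
    """
    support2 = EmbeddingSet(
        model.encode(support_half.vectors), support_half.labels, support_half.ids
    )
    return pt_snn.classify(support2, model.encode(np.atleast_2d(test_vectors)))


class SOESNNClassifier:
    """Episodic handle: split support set, train encoder, classify.

    ``fit`` splits the episode's support set in stratified halves (seeded by
    ``split_seed``, default the config seed), trains the encoder on the
    exhaustive pairs of one half, and keeps the other half for
    classification.
    """

    name = "soe-snn"

    def __init__(self, config: EncoderConfig, split_seed: int | None = None):
        self.config = config
        self.split_seed = config.seed if split_seed is None else split_seed
        self.model: EncoderModel | None = None

    def fit(self, train: EmbeddingSet) -> "SOESNNClassifier":
        if train.dim != self.config.input_dim:
            self.config = replace(self.config, input_dim=train.dim,
                                  output_dim=None)
        encoder_half, support_half = split_for_soe(train, self.split_seed)
        self.model = train_encoder(encoder_half, self.config)
        self.support_half = support_half
        return self

    def predict(self, test_vectors: np.ndarray) -> list[str]:
        if self.model is None:
            raise DataError("classifier is not fitted")
        return soe_classify(self.model, self.support_half, test_vectors)
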