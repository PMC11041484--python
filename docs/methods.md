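# Methods

## Problem setting

N-way-K-shot sentence classification: N classes, K labeled support
sentences per class (K ∈ {4, 8, 16} throughout), and a much larger
unlabeled test pool. Sentences are represented by frozen sentence
embeddings; the classifiers below never update the embedding model.

## PT-SNN: nearest class mean in cosine space

For support embeddings `E_train` (labels `L_train`) and test embeddings
`E_test`, both matrices are row-L2-normalized, so the similarity table
`T S'` holds all pairwise cosine similarities. A one-hot class-membership
matrix over the support rows, L1-normalized per class row, converts the
second matmul into per-class arithmetic means; the row argmax is the
prediction. Two sources describing this computation disagree internally
about which matrix is normalized into which variable; the implementation
follows the only reading under which the downstream shapes are consistent
(the similarity table is n_test × n_train). The test suite pins the
vectorized path to a scalar double-loop oracle at 1e-8 on random instances.

Numerical choices:

- Zero embedding rows are rejected, never silently mapped — cosine
  similarity is undefined for them.
- Argmax ties break to the earliest class in sorted label order. Ties are
  measure-zero for continuous embeddings but must be deterministic for
  reproducible tests.
- No sigmoid at classification time: sigmoid is monotone, so it cannot
  change an argmax.

## Pair augmentation

A support set of NK samples yields ((NK)² − NK)/2 unique unordered pairs,
each flagged same-class (1) or different-class (0). Pairs are enumerated in
lexicographic (i, j) order with strict i < j (no self-pairs); any shuffling
happens downstream under the training seed. Exhaustive pairs are used as
given — no balancing or hard-negative mining.

## SOE-SNN: the trainable second-order encoder

Architecture. A d-dimensional first-order embedding is not a sequence, so
the vector is viewed as `chunk_length` consecutive segments of size
d/chunk_length (default 16 segments; chunk_length must divide d). A
bidirectional LSTM (hidden size 32 per direction by default) reads the
segment sequence; the concatenated final hidden states of both directions
pass through a linear layer to the second-order embedding (output_dim
defaults to d). This is the least-assumptive way to give a recurrent unit
a genuine sequence while preserving all information; it is configurable.

Training. The episode's support set is halved per class (stratified, so
every class is represented on both sides — required for the classification
half to work at all; with an odd class count the encoder side gets the
extra sample). The encoder half's exhaustive pair set is fit with binary
cross-entropy on `sigmoid(distance(emb₁, emb₂))` against the same-class
flags, using AdamW. The distance is a hyperparameter: cosine similarity
(default, matching the geometry of the classifier) or negative Euclidean.
Both Siamese branches share all weights by construction, so pair
similarity is exactly symmetric.

Defaults where the procedure is otherwise unspecified: learning rate 1e-3,
50 epochs, full-batch steps (few-shot pair counts are tiny; full batch is
also what makes training bit-reproducible), AdamW weight decay 0.01
applied to weight matrices only, forget-gate bias initialized to 1,
Glorot-style scaled Gaussian initialization from the config seed. All are
surfaced in `EncoderConfig`.

Implementation. Forward, backpropagation-through-time and AdamW are
written directly in numpy (float64). Gradients are exact; the suite checks
them against central finite differences at 1e-4 relative tolerance for
both distance options. Sigmoid uses the numerically stable split form, the
BCE probability is clipped at 1e-12 for the loss value only (the gradient
uses the exact σ − y form), and cosine norms are floored at 1e-12.

Classification reuses the PT-SNN rule on the encoded support half and
encoded test set. An `IdentityEncoder` reduces the path to plain PT-SNN,
which the tests exploit.

## Episodic evaluation

Episode `Idx` (0-based) samples K support sentences per class without
replacement with seed `base_seed + Idx` (base 0 by default, so the
canonical seeds are 0..M−1). Two test-set modes: `complement` (default;
test = everything not sampled, reproducing the 16/428, 32/412, 64/380
splits at n = 444) and `fixed_test` (one held-out set across episodes).
Both are exposed because the protocol is legitimately readable either way.
Metrics are multi-class precision/recall/F via scikit-learn with
configurable averaging; macro is the default as the conservative choice
under heavy imbalance (a majority-class guesser gets macro recall 1/N).
Published benchmark scores are not used as numeric targets anywhere: they
require the restricted-access clinical corpus and specific pretrained
backends, and the averaging behind them is unstated. M defaults to 3; the
mean row is the exact column mean of the per-iteration rows.

## Synthetic data

The generator emulates the statistical structure the methods assume:
class centroids drawn uniformly on the unit hypersphere, rejection-sampled
until all pairwise angles are ≥ `min_centroid_angle` (default 60°; at most
1000 restarts, then an error — e.g. four centroids at ≥ 120° cannot fit in
the plane), plus isotropic Gaussian within-class noise (default standard
deviation 0.3, chosen as a moderate-overlap regime where the classifiers
are clearly above chance but imperfect). Centroids on the sphere make the
class signal purely directional, matching the scale invariance of cosine
similarity. Class counts come from largest-remainder rounding of the
target proportions (default 55.2/26.4/10.8/7.7 % — the emulated
benchmark's imbalance), which reproduces printed totals exactly
(444 → 245/117/48/34). The toy-corpus generator draws 5–10 tokens per
sentence from disjoint per-class vocabularies so the hashed-n-gram backend
yields separable clusters.

What passing on synthetic data does not show: real clinical sentences
produce anisotropic, heavy-tailed embedding clouds with correlated classes
and annotation noise; absolute scores here say nothing about scores on
real corpora. The synthetic results validate the algorithms' mechanics
(vectorization, training dynamics, protocol determinism), not clinical
performance.

## Embedding backends

The bundled backend hashes word unigrams and character trigrams (BLAKE2b)
into a signed count vector of fixed dimension — deterministic, offline,
dependency-free. Pretrained sentence-encoder adapters can be registered
behind the same interface; pooling is left to the adapter, since it varies
by model family. The hash backend is what the tests and examples use.

## Prompt baseline

The prefix prompt is `{text}. options are <labels>. type of disease`, with
the completion point at the end. If the token count exceeds the context
budget (default 1024), the text is trimmed word-by-word from its end until
the prompt fits; the option list and trailing cue are never cut. Token
counting is pluggable (default: whitespace tokens) because subword
counting requires a model download; a real tokenizer can be passed as a
callable. Running a generative model and mapping its free-text output to
classes are out of scope.

## Problem sizes

Tests and the acceptance script run at the emulated study scale: 444
samples (544 for the chance-level check, so every episode has ≥ 500 test
samples), embedding dimension 32, encoder training on ≤ 120 pairs for ≤ 50
epochs. The whole suite completes in a few seconds on one CPU.

## Known limitations

- Only the half/half encoder-vs-support split is implemented; other ratios
  are plausible but out of scope.
- No GRU variant beyond the architecture being confined to one module;
  no triplet losses; no hard-negative mining.
- The CLI's `evaluate` grid runs one method × backend per invocation;
  multi-backend sweeps are shell loops.
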