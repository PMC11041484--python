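import math

import numpy as np
import pytest

from fewshot_snn import (
    ConfigurationError,
    DataError,
    EmbeddingSet,
    EncoderConfig,
    EncoderModel,
    IdentityEncoder,
    SOESNNClassifier,
    SyntheticConfig,
    classify,
    encode,
    generate,
    make_pairs,
    pair_similarity,
    sample_episode,
    soe_classify,
    split_for_soe,
    train_encoder,
)
from fewshot_snn.soe_snn import _init_params, pair_loss_and_grads

TINY = dict(input_dim=8, hidden_dim=3, output_dim=4, chunk_length=4, epochs=1, seed=0)


class TestConfigValidation:
    def test_chunk_length_must_divide_input_dim(self):
        with pytest.raises(ConfigurationError, match="chunk_length"):
            EncoderConfig(input_dim=10, chunk_length=4)

    def test_epochs_at_least_one(self):
        with pytest.raises(ConfigurationError, match="epochs"):
            EncoderConfig(input_dim=8, chunk_length=4, epochs=0)

    def test_unknown_distance(self):
        with pytest.raises(ConfigurationError, match="distance"):
            EncoderConfig(input_dim=8, chunk_length=4, distance="manhattan")

    def test_output_dim_defaults_to_input_dim(self):
        assert EncoderConfig(input_dim=8, chunk_length=4).output_dim == 8


class TestSplit:
    def test_stratified_halves_4x8(self, rng):
        labels = [f"c{c}" for c in range(4) for _ in range(8)]
        data = EmbeddingSet(rng.standard_normal((32, 8)), labels)
        enc, sup = split_for_soe(data, seed=0)
        assert enc.n_samples == sup.n_samples == 16
        for part in (enc, sup):
            values, counts = np.unique(part.labels, return_counts=True)
            assert counts.tolist() == [4, 4, 4, 4]
        assert set(enc.ids).isdisjoint(sup.ids)
        assert set(enc.ids) | set(sup.ids) == set(data.ids)

    def test_two_sample_class_gets_one_each(self, rng):
        data = EmbeddingSet(rng.standard_normal((4, 4)), ["a", "a", "b", "b"])
        enc, sup = split_for_soe(data, seed=5)
        for part in (enc, sup):
            assert sorted(set(part.labels)) == ["a", "b"]

    def test_odd_class_count_favors_encoder_side(self, rng):
        data = EmbeddingSet(rng.standard_normal((5, 4)), ["a"] * 3 + ["b"] * 2)
        enc, sup = split_for_soe(data, seed=1)
        assert (enc.labels == "a").sum() == 2
        assert (sup.labels == "a").sum() == 1

    def test_deterministic_given_seed(self, rng):
        data = EmbeddingSet(rng.standard_normal((12, 4)), list("aabbcc") * 2)
        first = split_for_soe(data, seed=9)
        second = split_for_soe(data, seed=9)
        assert first[0].ids == second[0].ids and first[1].ids == second[1].ids

    def test_singleton_class_rejected(self, rng):
        data = EmbeddingSet(rng.standard_normal((3, 4)), ["a", "a", "b"])
        with pytest.raises(DataError, match="'b'"):
            split_for_soe(data, seed=0)


class TestPairSimilarity:
    def test_identical_inputs_cosine_gives_sigmoid_of_one(self):
        model = EncoderModel.initialized(EncoderConfig(**TINY))
        v = np.arange(8.0)
        expected = 1.0 / (1.0 + math.exp(-1.0))
        assert pair_similarity(model, v, v) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        model = EncoderModel.initialized(EncoderConfig(**TINY))
        v1, v2 = rng.standard_normal((2, 8))
        assert pair_similarity(model, v1, v2) == pair_similarity(model, v2, v1)

    def test_untrained_model_deterministic_given_seed(self, rng):
        v1, v2 = rng.standard_normal((2, 8))
        a = pair_similarity(EncoderModel.initialized(EncoderConfig(**TINY)), v1, v2)
        b = pair_similarity(EncoderModel.initialized(EncoderConfig(**TINY)), v1, v2)
        assert a == b
        assert 0.0 < a < 1.0

    def test_dimension_mismatch(self):
        model = EncoderModel.initialized(EncoderConfig(**TINY))
        with pytest.raises(DataError):
            pair_similarity(model, np.ones(8), np.ones(5))


class TestGradients:
    @pytest.mark.parametrize("distance", ["cosine_similarity", "negative_euclidean"])
    def test_backprop_matches_finite_differences(self, distance, rng):
        cfg = EncoderConfig(**{**TINY, "distance": distance})
        vectors = rng.standard_normal((5, 8))
        es = EmbeddingSet(vectors, ["a", "a", "b", "b", "a"])
        ps = make_pairs(es)
        targets = ps.same_class.astype(float)
        params = _init_params(cfg)
        _, grads = pair_loss_and_grads(params, cfg, vectors, ps.i, ps.j, targets)
        eps = 1e-6
        for key, value in params.items():
            flat = value.ravel()
            for pos in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[pos]
                flat[pos] = orig + eps
                lp, _ = pair_loss_and_grads(params, cfg, vectors, ps.i, ps.j, targets)
                flat[pos] = orig - eps
                lm, _ = pair_loss_and_grads(params, cfg, vectors, ps.i, ps.j, targets)
                flat[pos] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[pos] == pytest.approx(
                    numeric, abs=1e-7, rel=1e-4
                ), f"gradient mismatch in {key}"

    def test_bce_is_ln2_when_embeddings_coincide(self, rng):
        # Duplicate rows -> zero euclidean distance -> sigmoid(0) = 0.5 for
        # every pair, so the mean binary cross-entropy is ln 2 regardless of
        # the same/different targets.
        cfg = EncoderConfig(**{**TINY, "distance": "negative_euclidean"})
        row = rng.standard_normal(8)
        vectors = np.tile(row, (4, 1))
        es = EmbeddingSet(vectors, ["a", "b", "a", "b"])
        ps = make_pairs(es)
        loss, _ = pair_loss_and_grads(
            _init_params(cfg), cfg, vectors, ps.i, ps.j, ps.same_class.astype(float)
        )
        assert loss == pytest.approx(math.log(2.0), abs=1e-12)


class TestTraining:
    def test_separates_same_from_different_pairs(self, small_clusters):
        cfg = EncoderConfig(input_dim=32, hidden_dim=16, chunk_length=16,
                            epochs=50, seed=0)
        model = train_encoder(small_clusters, cfg)
        ps = make_pairs(small_clusters)
        sims = np.array(
            [
                pair_similarity(model, small_clusters.vectors[i],
                                small_clusters.vectors[j])
                for i, j in zip(ps.i, ps.j)
            ]
        )
        assert sims[ps.same_class == 1].mean() > sims[ps.same_class == 0].mean()

    def test_loss_decreases_on_separable_data(self, small_clusters):
        cfg = EncoderConfig(input_dim=32, hidden_dim=16, chunk_length=16,
                            epochs=50, seed=0)
        model = train_encoder(small_clusters, cfg)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_deterministic_given_seed(self, small_clusters):
        cfg = EncoderConfig(input_dim=32, hidden_dim=8, chunk_length=16,
                            epochs=10, seed=4)
        a = train_encoder(small_clusters, cfg)
        b = train_encoder(small_clusters, cfg)
        for key in a.params:
            np.testing.assert_allclose(a.params[key], b.params[key], atol=1e-6)

    def test_minibatch_training_runs_and_is_deterministic(self, small_clusters):
        cfg = EncoderConfig(input_dim=32, hidden_dim=8, chunk_length=16,
                            epochs=5, batch_size=7, seed=2)
        a = train_encoder(small_clusters, cfg)
        b = train_encoder(small_clusters, cfg)
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_single_class_rejected(self, rng):
        data = EmbeddingSet(rng.standard_normal((4, 8)), ["a"] * 4)
        with pytest.raises(DataError, match="single class"):
            train_encoder(data, EncoderConfig(**TINY))

    def test_frozen_inputs_never_modified(self, small_clusters):
        before = small_clusters.vectors.copy()
        cfg = EncoderConfig(input_dim=32, hidden_dim=4, chunk_length=16,
                            epochs=3, seed=0)
        train_encoder(small_clusters, cfg)
        np.testing.assert_array_equal(small_clusters.vectors, before)


class TestEncode:
    def test_shape_contract(self, rng):
        model = EncoderModel.initialized(EncoderConfig(**TINY))
        out = encode(model, rng.standard_normal((10, 8)))
        assert out.shape == (10, 4)

    def test_deterministic(self, rng):
        model = EncoderModel.initialized(EncoderConfig(**TINY))
        m = rng.standard_normal((6, 8))
        np.testing.assert_array_equal(encode(model, m), encode(model, m))

    def test_dimension_mismatch(self):
        model = EncoderModel.initialized(EncoderConfig(**TINY))
        with pytest.raises(DataError, match="columns"):
            encode(model, np.ones((2, 9)))


class TestClassification:
    def test_identity_encoder_reduces_to_pt_snn(self, clean_clusters):
        ep = sample_episode(clean_clusters, k_shots=4, seed=1)
        support = clean_clusters.subset(ep.train_idx)
        test = clean_clusters.vectors[ep.test_idx]
        assert soe_classify(IdentityEncoder(), support, test) == classify(
            support, test
        )

    def test_noise_free_end_to_end_accuracy_one(self, clean_clusters):
        cfg = EncoderConfig(input_dim=32, hidden_dim=16, chunk_length=16,
                            epochs=40, seed=0)
        ep = sample_episode(clean_clusters, k_shots=4, seed=0)
        clf = SOESNNClassifier(cfg).fit(clean_clusters.subset(ep.train_idx))
        pred = clf.predict(clean_clusters.vectors[ep.test_idx])
        truth = clean_clusters.labels[ep.test_idx]
        assert np.mean(np.asarray(pred, dtype=object) == truth) == 1.0

    def test_above_chance_across_seeds_on_4_way_task(self):
        # mildly noisy 4-way task; mean accuracy over 5 seeds must beat 1/4
        accs = []
        for seed in range(5):
            data = generate(
                SyntheticConfig(total_samples=80, dim=32,
                                within_class_noise=0.4, seed=seed)
            )
            ep = sample_episode(data, k_shots=4, seed=seed)
            cfg = EncoderConfig(input_dim=32, hidden_dim=16, chunk_length=16,
                                epochs=30, seed=seed)
            clf = SOESNNClassifier(cfg).fit(data.subset(ep.train_idx))
            pred = clf.predict(data.vectors[ep.test_idx])
            truth = data.labels[ep.test_idx]
            accs.append(float(np.mean(np.asarray(pred, dtype=object) == truth)))
        assert np.mean(accs) > 0.25
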