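import numpy as np
import pytest

from triplexpot.cnn import (
    CNNConfig,
    ConfigError,
    TrainedModel,
    build_model,
    classify,
    export_feature_maps,
    load_model,
    predict_proba,
    save_model,
    train_network,
)
from triplexpot.features import featurize_dataset, fit_class_means
from triplexpot.io import Dataset, SequenceRecord

FAST = dict(epochs=15, dropout_rate=0.0)


def separable_features(n_per_class, seed, gap=3.0):
    """Synthetic 90-dim features with a large planted mean shift."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, 90))
    X1 = rng.normal(0.0, 1.0, size=(n_per_class, 90)) + gap
    X = np.vstack([X1, X0])
    y = np.concatenate([np.ones(n_per_class), np.zeros(n_per_class)])
    return X, y


class TestConfig:
    def test_default_final_map_length_is_15(self):
        cfg = CNNConfig()
        assert cfg.stage_lengths()[-1] == 15

    def test_single_layer_ablation_valid(self):
        cfg = CNNConfig(n_conv_layers=1, filters_per_layer=(16,), kernel_sizes=(5,),
                        pool_sizes=(6,), conv_output_length=15)
        assert cfg.stage_lengths() == [90, 15]

    def test_unreachable_length_reports_computed(self):
        with pytest.raises(ConfigError, match=r"\[90, 45, 22\]"):
            CNNConfig(pool_sizes=(2, 2), conv_output_length=15)

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ConfigError):
            CNNConfig(filters_per_layer=(32,))


class TestNetwork:
    def test_seeded_init_identical(self):
        a, b = build_model(CNNConfig(seed=4)), build_model(CNNConfig(seed=4))
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_different_seed_different_init(self):
        a, b = build_model(CNNConfig(seed=4)), build_model(CNNConfig(seed=5))
        assert not np.array_equal(a.params["W0"], b.params["W0"])

    def test_forward_probability_range_and_shape(self):
        net = build_model(CNNConfig())
        X = np.random.default_rng(0).normal(size=(7, 90))
        prob, _ = net.forward(X)
        assert prob.shape == (7,)
        assert ((prob >= 0) & (prob <= 1)).all()

    def test_gradients_match_finite_differences(self):
        """Backprop oracle: numerical gradient on a tiny network."""
        cfg = CNNConfig(n_conv_layers=1, filters_per_layer=(2,), kernel_sizes=(5,),
                        pool_sizes=(6,), conv_output_length=15, dense_units=3,
                        dropout_rate=0.0, seed=0)
        net = build_model(cfg)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 90))
        y = np.array([1.0, 0.0, 1.0, 0.0])

        def loss():
            prob, _ = net.forward(X)
            eps = 1e-12
            return -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))

        prob, cache = net.forward(X)
        grads = net.backward(X, y, prob, cache)
        for key in ("W0", "b0", "Wd", "Wo", "bo"):
            p = net.params[key]
            flat_idx = [(0,) * p.ndim, tuple(d - 1 for d in p.shape)]
            for idx in flat_idx:
                h = 1e-6
                orig = p[idx]
                p[idx] = orig + h
                lp = loss()
                p[idx] = orig - h
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * h)
                assert grads[key][idx] == pytest.approx(num, abs=1e-5), key

    def test_training_deterministic(self):
        X, y = separable_features(20, seed=2)
        runs = []
        for _ in range(2):
            net = build_model(CNNConfig(seed=3, **FAST))
            train_network(net, X, y)
            runs.append(net)
        for k in runs[0].params:
            assert np.array_equal(runs[0].params[k], runs[1].params[k])
        assert runs[0].loss_history == runs[1].loss_history

    def test_loss_decreases_on_separable_data(self):
        X, y = separable_features(30, seed=6)
        net = build_model(CNNConfig(seed=1, **FAST))
        train_network(net, X, y)
        assert net.loss_history[-1] < net.loss_history[0]

    def test_separable_training_accuracy(self):
        X, y = separable_features(40, seed=8)
        net = build_model(CNNConfig(seed=1, epochs=50, dropout_rate=0.0))
        train_network(net, X, y)
        prob, _ = net.forward(X)
        assert ((prob >= 0.5) == y.astype(bool)).mean() >= 0.99

    def test_single_class_labels_error(self):
        X, _ = separable_features(5, seed=0)
        net = build_model(CNNConfig(**FAST))
        with pytest.raises(ValueError, match="single class"):
            train_network(net, X, np.ones(10))

    def test_nonfinite_features_error(self):
        X, y = separable_features(5, seed=0)
        X[3, 7] = np.nan
        net = build_model(CNNConfig(**FAST))
        with pytest.raises(ValueError, match="3"):
            train_network(net, X, y)


@pytest.fixture
def fitted(tiny_pos, tiny_neg, tiny_profile):
    X = np.vstack([
        featurize_dataset(tiny_pos, tiny_profile),
        featurize_dataset(tiny_neg, tiny_profile),
    ])
    y = np.concatenate([np.ones(len(tiny_pos)), np.zeros(len(tiny_neg))])
    net = build_model(CNNConfig(seed=0, epochs=20, dropout_rate=0.0))
    train_network(net, X, y)
    return TrainedModel(config=net.cfg, net=net, profile=tiny_profile)


class TestTrainedModel:
    def test_predict_proba_aligned_and_bounded(self, fitted, tiny_pos):
        probs = predict_proba(fitted, tiny_pos)
        assert probs.shape == (len(tiny_pos),)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_duplicate_sequence_same_probability(self, fitted):
        d = Dataset([SequenceRecord("a", "ACGGCGTAGCGC"),
                     SequenceRecord("b", "ACGGCGTAGCGC")])
        p = predict_proba(fitted, d)
        assert p[0] == p[1]

    def test_class_separation_on_held_out(self, fitted):
        from conftest import random_dataset
        pos = random_dataset(15, 60, (0.1, 0.4, 0.4, 0.1), seed=21, prefix="hp")
        neg = random_dataset(15, 60, (0.4, 0.1, 0.1, 0.4), seed=22, prefix="hn")
        assert np.median(predict_proba(fitted, pos)) > np.median(predict_proba(fitted, neg))

    def test_threshold_monotonicity(self, fitted, tiny_pos):
        fitted.threshold = 0.2
        many = classify(fitted, tiny_pos).sum()
        fitted.threshold = 0.8
        few = classify(fitted, tiny_pos).sum()
        assert many >= few

    def test_boundary_probability_maps_positive(self, fitted):
        assert (np.array([0.5]) >= fitted.threshold).astype(int)[0] == 1

    def test_save_load_roundtrip(self, fitted, tiny_pos, tmp_path):
        before = predict_proba(fitted, tiny_pos)
        save_model(fitted, tmp_path / "m")
        again = load_model(tmp_path / "m")
        assert again.model_role == fitted.model_role
        assert np.array_equal(predict_proba(again, tiny_pos), before)

    def test_load_empty_dir_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path)


class TestFeatureMaps:
    def test_layer0_mean_equals_feature_vector_for_identical_positives(
            self, fitted, tiny_neg):
        pos = Dataset([SequenceRecord(f"p{i}", "ACGGCGTAGCGC", label="positive")
                       for i in range(3)])
        data = Dataset(pos.records + tiny_neg.records)
        maps = export_feature_maps(fitted, data, layer=0)
        from triplexpot.features import featurize
        assert np.allclose(maps["positive"], featurize("ACGGCGTAGCGC", fitted.profile))

    def test_conv_layer_shapes(self, fitted, tiny_pos, tiny_neg, tmp_path):
        data = Dataset(tiny_pos.records + tiny_neg.records)
        m1 = export_feature_maps(fitted, data, layer=1, out_dir=tmp_path)
        m2 = export_feature_maps(fitted, data, layer=2)
        assert m1["positive"].shape == (30, 32)
        assert m2["positive"].shape == (15, 32)  # final maps have length 15
        assert (tmp_path / "layer1_positive.tsv").exists()

    def test_identical_classes_identical_maps(self, fitted):
        recs_p = [SequenceRecord(f"p{i}", "ACGGCGTAGCGC", label="positive") for i in range(2)]
        recs_n = [SequenceRecord(f"n{i}", "ACGGCGTAGCGC", label="negative") for i in range(2)]
        maps = export_feature_maps(fitted, Dataset(recs_p + recs_n), layer=2)
        assert np.allclose(maps["positive"], maps["negative"])

    def test_unlabeled_data_error(self, fitted):
        d = Dataset([SequenceRecord("x", "ACGTACGTAC")])
        with pytest.raises(ValueError, match="lack labels"):
            export_feature_maps(fitted, d, layer=1)
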