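import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungcad import mlcnn, phantoms, preprocess


@pytest.fixture(scope="module")
def tiny_image_model():
    cfg = mlcnn.CnnConfig(n_conv_layers=1, filters_per_layer=(2,), seed=3)
    return mlcnn.build_model(cfg, (8, 8), sensor_dim=2)


class TestSplitDataset:
    def test_eighty_twenty(self):
        labels = ["benign"] * 5 + ["malignant"] * 5
        split = mlcnn.split_dataset(labels, seed=0)
        assert len(split.train_indices) == 8
        assert len(split.test_indices) == 2

    def test_stratified_counts(self):
        labels = ["benign"] * 50 + ["malignant"] * 50
        split = mlcnn.split_dataset(labels, seed=1)
        labels = np.asarray(labels)
        train = labels[split.train_indices]
        test = labels[split.test_indices]
        assert (train == "benign").sum() == (train == "malignant").sum() == 40
        assert (test == "benign").sum() == (test == "malignant").sum() == 10

    def test_deterministic_and_disjoint(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 50))
            labels = rng.choice(["a", "b"], size=n)
            if min((labels == "a").sum(), (labels == "b").sum()) < 2:
                continue
            s1 = mlcnn.split_dataset(labels, seed=trial)
            s2 = mlcnn.split_dataset(labels, seed=trial)
            assert np.array_equal(s1.train_indices, s2.train_indices)
            both = np.concatenate([s1.train_indices, s1.test_indices])
            assert len(set(both)) == n
            assert len(s1.train_indices) == round(0.8 * n)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            mlcnn.split_dataset(["a"] * 9 + ["b"], seed=0)


class TestModelBasics:
    @given(st.integers(0, 2**31 - 1))
    def test_softmax_output_is_distribution(self, seed):
        rng = np.random.default_rng(seed)
        cfg = mlcnn.CnnConfig(n_conv_layers=1, filters_per_layer=(2,),
                              seed=int(seed % 1000))
        m = mlcnn.build_model(cfg, (4, 4))
        p = m.predict_proba(rng.normal(size=(4, 4)))
        assert p.shape == (2,)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_seeded_initialization_identical(self):
        cfg = mlcnn.CnnConfig(seed=11)
        a = mlcnn.build_model(cfg, (16, 16))
        b = mlcnn.build_model(cfg, (16, 16))
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_pooling_below_one_pixel_rejected(self):
        cfg = mlcnn.CnnConfig(n_conv_layers=3)
        with pytest.raises(ValueError):
            mlcnn.build_model(cfg, (4, 4))

    def test_gradients_match_finite_differences(self, tiny_image_model, rng):
        m = tiny_image_model
        x = rng.normal(size=(8, 8))
        sv = rng.normal(size=2)
        _, gW, gb = m.loss_and_grads(x, 1, sv)
        h = 1e-5
        for li in range(len(m.weights)):
            W = m.weights[li]
            for _ in range(4):
                idx = tuple(int(rng.integers(0, s)) for s in W.shape)
                orig = W[idx]
                W[idx] = orig + h
                lp, _, _ = m.loss_and_grads(x, 1, sv)
                W[idx] = orig - h
                lm, _, _ = m.loss_and_grads(x, 1, sv)
                W[idx] = orig
                num = (lp - lm) / (2 * h)
                assert abs(num - gW[li][idx]) <= 1e-4 * max(
                    1e-6, abs(num) + abs(gW[li][idx]))


@pytest.fixture(scope="module")
def separable():
    samples = phantoms.separable_dataset(60, image_size=32, seed=5)
    X = [preprocess.zscore_normalize(s.image) for s in samples]
    y, _ = mlcnn.encode_labels([s.label for s in samples])
    return samples, X, y


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, separable):
        _, X, y = separable
        cfg = mlcnn.CnnConfig(epochs=3, seed=0)
        m1 = mlcnn.train_model(mlcnn.build_model(cfg, (32, 32)), X, y)
        m2 = mlcnn.train_model(mlcnn.build_model(cfg, (32, 32)), X, y)
        assert m1.loss_history == m2.loss_history
        assert len(m1.loss_history) == 3
        assert m1.loss_history[-1] < m1.loss_history[0]

    def test_sensor_only_learning_beats_majority(self):
        # linearly separable tabular data: accuracy gain >= 30 points
        samples = phantoms.make_dataset(80, 0.5, image_size=32,
                                        noise_sigma=0.0, seed=9)
        X = [np.asarray(s.sensor.values) for s in samples]
        y, _ = mlcnn.encode_labels([s.label for s in samples])
        wins = 0
        for seed in range(5):
            split = mlcnn.split_dataset([s.label for s in samples], seed=seed)
            cfg = mlcnn.CnnConfig(epochs=5, seed=seed, learning_rate=5e-3)
            m = mlcnn.build_model(cfg, (5,))
            tr = split.train_indices
            mlcnn.train_model(m, [X[i] for i in tr], y[tr])
            acc = np.mean([np.argmax(m.predict_proba(X[i])) == y[i]
                           for i in split.test_indices])
            wins += acc >= 0.5 + 0.30
        assert wins >= 4

    def test_nan_loss_raises(self):
        cfg = mlcnn.CnnConfig(n_conv_layers=1, filters_per_layer=(2,),
                              epochs=1, seed=0)
        m = mlcnn.build_model(cfg, (4, 4))
        with pytest.raises(FloatingPointError):
            mlcnn.train_model(m, [np.full((4, 4), np.nan)], [0])


class TestPredict:
    def test_uniform_distribution_abstains(self, tiny_image_model):
        # untrained model forced to uniform output: entropy 1 bit > 0.5
        m = tiny_image_model
        saved = m.weights[-1].copy(), m.biases[-1].copy()
        m.weights[-1][:] = 0.0
        m.biases[-1][:] = 0.0
        try:
            p = mlcnn.predict(m, np.zeros((8, 8)), sensor=np.zeros(2),
                              entropy_threshold_bits=0.5)
            assert p.abstained
            assert np.allclose(p.probs, 0.5)
        finally:
            m.weights[-1][:], m.biases[-1][:] = saved

    def test_confident_prediction_never_abstains(self, tiny_image_model):
        m = tiny_image_model
        saved = m.biases[-1].copy()
        m.biases[-1][:] = [50.0, -50.0]
        try:
            p = mlcnn.predict(m, np.zeros((8, 8)), sensor=np.zeros(2),
                              entropy_threshold_bits=0.5)
            assert not p.abstained
            assert p.label_index == 0
        finally:
            m.biases[-1][:] = saved


class TestClassProbabilityComponents:
    def test_counting(self):
        assert mlcnn.class_probability_components(["A", "A", "B", "B"]) == \
            {"A": 0.5, "B": 0.5}
        assert mlcnn.class_probability_components(["A", "A", "A", "B"]) == \
            {"A": 0.75, "B": 0.25}
        assert mlcnn.class_probability_components(["A"]) == {"A": 1.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mlcnn.class_probability_components([])


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, tiny_image_model, rng):
        path = str(tmp_path / "model.npz")
        tiny_image_model.save(path)
        loaded = mlcnn.MLCNN.load(path)
        x = rng.normal(size=(8, 8))
        sv = rng.normal(size=2)
        assert np.allclose(tiny_image_model.predict_proba(x, sv),
                           loaded.predict_proba(x, sv))
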