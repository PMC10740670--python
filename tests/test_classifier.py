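import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _regimes import separable_segments as _separable_segments

from swimclass.classifier import (SegmentImageClassifier, TrainConfig, build_model,
                                  extract_embeddings, focal_loss, predict, train)
from swimclass.render import RenderConfig
from swimclass.trajectory import ValidationError
from swimclass.workflow import segment_dataset


class TestFocalLoss:
    def test_perfect_prediction_zero_loss(self):
        for gamma in (0.0, 1.0, 2.0, 5.0):
            assert focal_loss([0.0, 1.0], 1, gamma) == 0.0

    def test_gamma_zero_is_cross_entropy(self):
        assert focal_loss([0.5, 0.5], 0, gamma=0.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_printed_value_gamma2(self):
        # (1-0.9)^2 * (-ln 0.9) = 1.0536e-3
        assert focal_loss([0.1, 0.9], 1, gamma=2.0) == pytest.approx(1.0536e-3, rel=1e-4)

    def test_batch_mean_matches_cross_entropy_at_gamma0(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(5), size=200)
        t = rng.integers(0, 5, size=200)
        fl = focal_loss(p, t, gamma=0.0)
        ce = -np.log(np.clip(p[np.arange(200), t], 1e-7, 1.0)).mean()
        assert fl == pytest.approx(ce, abs=1e-9)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValidationError):
            focal_loss([0.5, 0.5], 0, gamma=-0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.98), st.floats(0.0, 5.0))
    def test_strictly_decreasing_in_pt(self, pt, gamma):
        lo = focal_loss([1 - pt, pt], 1, gamma)
        hi = focal_loss([1 - pt - 0.01, pt + 0.01], 1, gamma)
        assert hi < lo

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.05, 0.95), st.floats(0.0, 4.0))
    def test_non_increasing_in_gamma(self, pt, gamma):
        assert focal_loss([1 - pt, pt], 1, gamma + 0.5) <= focal_loss([1 - pt, pt], 1, gamma)


class TestBuildModel:
    def test_output_width_matches_classes(self):
        model = build_model(9, TrainConfig(seed=0))
        rng = np.random.default_rng(0)
        x = rng.integers(0, 255, size=(2, 64, 64, 3), dtype=np.uint8)
        model.classes_ = np.arange(9)
        proba = model.predict_proba(x)
        assert proba.shape == (2, 9)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(np.isfinite(proba))

    def test_same_seed_identical_init(self):
        a = build_model(4, TrainConfig(seed=7))
        b = build_model(4, TrainConfig(seed=7))
        for pa, pb in zip(a.net_.all_params(), b.net_.all_params()):
            assert np.array_equal(pa.value, pb.value)

    def test_resnet_backbone_forward_finite(self):
        model = build_model(3, TrainConfig(backbone="resnet_small", seed=0))
        x = np.random.default_rng(1).integers(0, 255, (2, 64, 64, 3), dtype=np.uint8)
        model.classes_ = np.arange(3)
        assert np.all(np.isfinite(model.predict_proba(x)))

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValidationError):
            build_model(1, TrainConfig(seed=0))


class TestTraining:
    def test_separable_regimes_reach_perfect_holdout(self):
        segs = _separable_segments()
        images, labels, *_ = segment_dataset(segs, RenderConfig(image_size=64))
        model = SegmentImageClassifier(epochs=5, batch_size=8, seed=0)
        model.fit(images[::2], labels[::2])
        assert np.mean(model.predict(images[1::2]) == labels[1::2]) == 1.0
        assert model.loss_history_[-1] < model.loss_history_[0]
        assert len(model.loss_history_) == 5

    def test_zero_epochs_leaves_model_unchanged(self, blob_images):
        images, labels = blob_images()
        model = build_model(2, TrainConfig(seed=1))
        before = [p.value.copy() for p in model.net_.all_params()]
        model, history = train(model, images, labels, TrainConfig(epochs=0, seed=1))
        assert history == []
        for p, b in zip(model.net_.all_params(), before):
            assert np.array_equal(p.value, b)

    def test_single_class_rejected(self, blob_images):
        images, labels = blob_images()
        model = SegmentImageClassifier(epochs=1, seed=0)
        with pytest.raises(ValidationError):
            model.fit(images[:30], labels[:30])

    def test_training_deterministic(self, blob_images):
        images, labels = blob_images(n_per_class=12)
        runs = []
        for _ in range(2):
            m = SegmentImageClassifier(epochs=2, batch_size=8, seed=5)
            m.fit(images, labels)
            runs.append(m.predict_proba(images))
        assert np.array_equal(runs[0], runs[1])

    def test_focal_beats_cross_entropy_on_minority_recall(self, blob_images):
        # 10:1 imbalance; minority-class recall averaged over 3 seeds
        recalls = {"focal": [], "cross_entropy": []}
        for seed in range(3):
            images, labels = blob_images(n_per_class=55, seed=seed)
            maj = images[:55], labels[:55]
            mino = images[55:], labels[55:]
            x = np.concatenate([maj[0], mino[0][:5], mino[0][35:]])
            y = np.concatenate([maj[1], mino[1][:5], mino[1][35:]])
            train_x, train_y = x[:60], y[:60]  # 55 majority + 5 minority
            test_x, test_y = mino[0][35:], mino[1][35:]
            for loss in recalls:
                m = SegmentImageClassifier(epochs=6, batch_size=8, seed=seed,
                                           loss=loss)
                m.fit(train_x, train_y)
                recalls[loss].append(np.mean(m.predict(test_x) == test_y))
        assert np.mean(recalls["focal"]) >= np.mean(recalls["cross_entropy"])


class TestPredict:
    def test_untrained_model_is_chance_level(self):
        rng = np.random.default_rng(2)
        model = build_model(4, TrainConfig(seed=3))
        model.classes_ = np.arange(4)
        x = rng.integers(0, 255, size=(200, 32, 32, 3), dtype=np.uint8)
        y = np.tile(np.arange(4), 50)
        acc = np.mean(model.predict(x) == y)
        assert abs(acc - 0.25) < 0.1  # ~3 sigma of Binomial(200, 1/4)

    def test_records_probabilities_normalized(self, blob_images):
        images, labels = blob_images(n_per_class=10)
        model = SegmentImageClassifier(epochs=1, batch_size=8, seed=0)
        model.fit(images, labels)
        records = predict(model, images, true_labels=labels)
        assert len(records) == len(images)
        for r in records:
            assert r.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert r.predicted_label == model.classes_[r.probabilities.argmax()]

    def test_duplicated_image_identical_records(self, blob_images):
        images, labels = blob_images(n_per_class=10)
        model = SegmentImageClassifier(epochs=1, batch_size=8, seed=0)
        model.fit(images, labels)
        dup = np.stack([images[0], images[0]])
        records = predict(model, dup)
        assert np.array_equal(records[0].probabilities, records[1].probabilities)
        assert records[0].predicted_label == records[1].predicted_label

    def test_size_mismatch_rejected(self, blob_images):
        images, labels = blob_images(n_per_class=10)
        model = SegmentImageClassifier(epochs=1, batch_size=8, seed=0)
        model.fit(images, labels)
        with pytest.raises(ValidationError):
            model.predict(np.zeros((1, 64, 64, 3), dtype=np.uint8))


class TestEmbeddings:
    def test_identical_images_identical_rows(self, blob_images):
        images, labels = blob_images(n_per_class=10)
        model = SegmentImageClassifier(epochs=1, batch_size=8, seed=0)
        model.fit(images, labels)
        emb = extract_embeddings(model, np.stack([images[0], images[0], images[3]]))
        assert emb.rows.shape == (3, model.embedding_dim_)
        assert np.array_equal(emb.rows[0], emb.rows[1])

    def test_trained_embeddings_linearly_separable(self):
        from sklearn.linear_model import Perceptron

        segs = _separable_segments(seed=8)
        images, labels, *_ = segment_dataset(segs, RenderConfig(image_size=64))
        model = SegmentImageClassifier(epochs=5, batch_size=8, seed=0)
        model.fit(images, labels)
        emb = model.transform(images)
        y = np.array([l.name for l in labels])
        clf = Perceptron(max_iter=200, random_state=0).fit(emb, y)
        assert clf.score(emb, y) == 1.0
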