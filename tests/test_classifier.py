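"""Pose classifier: dataset trimming, splitting, SCG training, streaming
classification and confusion matrices."""

import numpy as np
import pytest

from myograsp import (
    ClassifierError,
    ClassifierModel,
    Dataset,
    EnvelopeStream,
    PoseClass,
    SplitSpec,
    classify_stream,
    confusion,
    extract_dataset,
    split_train_test,
    train_mlp_scg,
)
from myograsp.classifier import _sigmoid, _softmax


def _envelope(labels, fs=2000.0, n_ch=3, seed=0):
    rng = np.random.default_rng(seed)
    return EnvelopeStream(
        values=np.abs(rng.normal(size=(len(labels), n_ch))),
        sampling_rate=fs,
        labels=np.asarray(labels, dtype=np.int8),
        channel_names=tuple(f"ch{i}" for i in range(n_ch)),
    )


class TestExtractDataset:
    def test_ten_second_block_trim_two_keeps_middle(self):
        env = _envelope(np.full(20000, int(PoseClass.TVG)))
        ds = extract_dataset(env, trim=2.0)
        assert len(ds) == 12000
        assert np.array_equal(ds.provenance, np.arange(4000, 16000))

    def test_zero_trim_keeps_everything(self):
        labels = np.concatenate([np.full(500, int(PoseClass.E)),
                                 np.full(500, int(PoseClass.R))])
        env = _envelope(labels, fs=500.0)
        ds = extract_dataset(env, trim=0.0)
        assert len(ds) == 1000
        assert np.array_equal(ds.targets, labels)

    def test_block_shorter_than_twice_trim_rejected(self):
        env = _envelope(np.full(6000, int(PoseClass.LP)))   # 3 s at 2 kHz
        with pytest.raises(ClassifierError):
            extract_dataset(env, trim=2.0)

    def test_rest_blocks_trimmed_symmetrically(self):
        labels = np.concatenate([np.full(20000, int(PoseClass.EG)),
                                 np.full(20000, int(PoseClass.R))])
        env = _envelope(labels)
        ds = extract_dataset(env, trim=2.0)
        assert (ds.targets == int(PoseClass.R)).sum() == 12000
        assert (ds.targets == int(PoseClass.EG)).sum() == 12000


class TestSplit:
    def test_seventy_thirty_on_ten_samples(self):
        ds = Dataset(np.arange(30, dtype=float).reshape(10, 3),
                     np.zeros(10, dtype=np.int8))
        tr, te = split_train_test(ds, SplitSpec(seed=1))
        assert len(tr) == 7 and len(te) == 3
        merged = sorted(np.concatenate([tr.provenance, te.provenance]).tolist())
        assert merged == list(range(10))        # disjoint union, exhaustively

    def test_same_seed_same_split(self):
        ds = Dataset(np.random.default_rng(0).normal(size=(50, 3)),
                     np.zeros(50, dtype=np.int8))
        a = split_train_test(ds, SplitSpec(seed=9))
        b = split_train_test(ds, SplitSpec(seed=9))
        assert np.array_equal(a[0].provenance, b[0].provenance)

    def test_half_split_of_two(self):
        ds = Dataset(np.zeros((2, 3)), np.array([0, 1], dtype=np.int8))
        tr, te = split_train_test(ds, SplitSpec(train_fraction=0.5, seed=0))
        assert len(tr) == 1 and len(te) == 1


class TestScgTraining:
    def _gaussian_blobs(self, centers, n=120, scale=0.05, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([c + scale * rng.normal(size=(n, 3)) for c in centers])
        y = np.repeat(np.arange(len(centers)), n).astype(np.int8)
        perm = rng.permutation(len(y))
        return Dataset(X[perm], y[perm])

    def test_separated_classes_learned_perfectly(self):
        centers = [np.array([0.1, 0.1, 0.1]), np.array([0.8, 0.2, 0.6])]
        train = self._gaussian_blobs(centers, seed=1)
        test = self._gaussian_blobs(centers, seed=2)
        model = train_mlp_scg(train, hidden_units=5, seed=3)
        assert np.mean(model.predict(test.features) == test.targets) == 1.0
        # linear-threshold oracle on the dominant axis agrees
        thresh = 0.45
        oracle = (test.features[:, 0] > thresh).astype(np.int8)
        assert np.array_equal(model.predict(test.features), oracle)

    def test_uninformative_features_yield_prior_softmax(self):
        # constant inputs: cross-entropy optimum is the class prior,
        # so every prediction is the majority class
        X = np.full((300, 3), 0.5)
        y = np.array([0] * 180 + [4] * 90 + [2] * 30, dtype=np.int8)
        model = train_mlp_scg(Dataset(X, y), hidden_units=4, seed=0,
                              max_iterations=300)
        probs = model.predict_proba(X[:1])
        assert probs[0, 0] == pytest.approx(0.6, abs=0.05)
        assert probs[0, 4] == pytest.approx(0.3, abs=0.05)
        assert np.all(model.predict(X) == 0)

    def test_softmax_rows_sum_to_one(self):
        train = self._gaussian_blobs([np.zeros(3), np.ones(3) * 0.5])
        model = train_mlp_scg(train, hidden_units=6, seed=5)
        probs = model.predict_proba(np.random.default_rng(0).normal(size=(40, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_accepted_losses_never_increase(self):
        train = self._gaussian_blobs([np.zeros(3), np.ones(3) * 0.4,
                                      np.array([0.8, 0.0, 0.4])])
        model = train_mlp_scg(train, hidden_units=8, seed=2)
        losses = model.training_log["loss_trajectory"]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_terminates_by_gradient_or_iteration_budget(self):
        train = self._gaussian_blobs([np.zeros(3), np.ones(3) * 0.5])
        model = train_mlp_scg(train, hidden_units=4, seed=7, max_iterations=50)
        log = model.training_log
        assert log["iterations"] <= 50
        assert log["final_gradient_norm"] < 1e-6 or log["iterations"] == 50

    def test_deterministic_given_seed(self):
        train = self._gaussian_blobs([np.zeros(3), np.ones(3) * 0.5])
        m1 = train_mlp_scg(train, seed=11, max_iterations=40)
        m2 = train_mlp_scg(train, seed=11, max_iterations=40)
        assert np.array_equal(m1.hidden_weights, m2.hidden_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError):
            train_mlp_scg(Dataset(np.zeros((10, 3)), np.zeros(10, dtype=np.int8)))

    def test_agrees_with_sklearn_reference_on_separable_data(self):
        sklearn = pytest.importorskip("sklearn.neural_network")
        centers = [np.array([0.05, 0.05, 0.05]), np.array([0.6, 0.1, 0.3]),
                   np.array([0.1, 0.7, 0.1])]
        train = self._gaussian_blobs(centers, seed=4)
        test = self._gaussian_blobs(centers, seed=5)
        ours = train_mlp_scg(train, hidden_units=8, seed=6)
        ref = sklearn.MLPClassifier(hidden_layer_sizes=(8,), solver="lbfgs",
                                    activation="logistic", max_iter=500,
                                    random_state=0)
        ref.fit(train.features, train.targets)
        acc_ours = np.mean(ours.predict(test.features) == test.targets)
        acc_ref = ref.score(test.features, test.targets)
        assert acc_ours >= 0.99 and acc_ref >= 0.99


class TestClassifyStream:
    def _uniform_model(self):
        return ClassifierModel(
            hidden_weights=np.zeros((3, 4)), hidden_bias=np.zeros(4),
            output_weights=np.zeros((4, 5)), output_bias=np.zeros(5))

    def test_probability_tie_resolves_to_relaxation(self):
        model = self._uniform_model()
        env = EnvelopeStream(values=np.ones((3, 3)), sampling_rate=100.0)
        probs, labels = classify_stream(model, env)
        assert np.allclose(probs, 0.2)
        assert np.all(labels == int(PoseClass.R))

    def test_single_sample_equals_batch_entry(self):
        rng = np.random.default_rng(8)
        model = ClassifierModel(
            hidden_weights=rng.normal(size=(3, 6)), hidden_bias=rng.normal(size=6),
            output_weights=rng.normal(size=(6, 5)), output_bias=rng.normal(size=5))
        X = rng.uniform(size=(20, 3))
        batch = model.predict_proba(X)
        single = model.predict_proba(X[7:8])
        assert np.allclose(batch[7], single[0])

    def test_matches_independent_forward_pass(self):
        rng = np.random.default_rng(9)
        model = ClassifierModel(
            hidden_weights=rng.normal(size=(3, 5)), hidden_bias=rng.normal(size=5),
            output_weights=rng.normal(size=(5, 5)), output_bias=rng.normal(size=5))
        env = EnvelopeStream(values=rng.uniform(size=(100, 3)),
                             sampling_rate=100.0)
        _probs, labels = classify_stream(model, env)
        # brute-force per-sample re-implementation of the forward equations
        for t in range(100):
            h = 1.0 / (1.0 + np.exp(-(env.values[t] @ model.hidden_weights
                                      + model.hidden_bias)))
            z = h @ model.output_weights + model.output_bias
            assert labels[t] == int(np.argmax(np.exp(z) / np.exp(z).sum()))

    def test_dimension_mismatch_rejected(self):
        model = self._uniform_model()
        env = EnvelopeStream(values=np.ones((3, 4)), sampling_rate=100.0)
        with pytest.raises(ClassifierError):
            classify_stream(model, env)

    def test_model_json_roundtrip(self):
        rng = np.random.default_rng(10)
        model = ClassifierModel(
            hidden_weights=rng.normal(size=(3, 4)), hidden_bias=rng.normal(size=4),
            output_weights=rng.normal(size=(4, 5)), output_bias=rng.normal(size=5),
            training_log={"iterations": 3, "seed": 1})
        back = ClassifierModel.from_json(model.to_json())
        assert np.array_equal(back.hidden_weights, model.hidden_weights)
        assert np.array_equal(back.output_bias, model.output_bias)
        assert back.training_log["iterations"] == 3


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 0, 1], dtype=np.int8)
        cm = confusion(y, y)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.overall_accuracy == 100.0

    def test_always_relaxation_on_balanced_truth(self):
        truth = np.repeat(np.arange(5), 20).astype(np.int8)
        pred = np.zeros_like(truth)
        cm = confusion(pred, truth)
        assert cm.overall_accuracy == pytest.approx(20.0)

    def test_hand_built_tally(self):
        truth = np.array([0, 0, 1, 1, 4, 4], dtype=np.int8)
        pred = np.array([0, 1, 1, 1, 4, 0], dtype=np.int8)
        cm = confusion(pred, truth)
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1
        assert cm.counts[1, 1] == 2
        assert cm.counts[4, 4] == 1 and cm.counts[4, 0] == 1
        assert cm.total == 6
        assert cm.overall_accuracy == pytest.approx(100 * 4 / 6)
        assert cm.per_class_accuracy[1] == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClassifierError):
            confusion(np.zeros(3, dtype=np.int8), np.zeros(4, dtype=np.int8))
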