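import itertools

import numpy as np
import pytest

import emgseq as E


def _sequence_table(n_per_class=50, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls in E.TASKS:
        for _ in range(n_per_class):
            rows.append(rng.integers(0, 7, size=12))
            labels.append(cls)
    return E.FeatureTable(ids=[f"r{i}" for i in range(len(rows))],
                          labels=labels, X=np.asarray(rows), kind="sequence12")


def _blob_table(n_per_class=30, seed=0, spread=0.05):
    """Four well-separated Gaussian blobs (linearly separable)."""
    rng = np.random.default_rng(seed)
    centers = np.eye(4)
    rows, labels = [], []
    for k, cls in enumerate(E.TASKS):
        rows.append(centers[k] + spread * rng.standard_normal((n_per_class, 4)))
        labels.extend([cls] * n_per_class)
    X = np.abs(np.vstack(rows))
    return E.FeatureTable(ids=[f"b{i}" for i in range(len(labels))],
                          labels=labels, X=X, kind="ets")


class TestSplit:
    def test_eighty_twenty_per_task(self):
        table = _sequence_table()
        train, test = E.split_dataset(table, E.SplitSpec(seed=3))
        for cls in E.TASKS:
            assert sum(1 for l in train.labels if l == cls) == 40
            assert sum(1 for l in test.labels if l == cls) == 10

    def test_split_is_a_partition_and_deterministic(self):
        table = _sequence_table()
        tr1, te1 = E.split_dataset(table, E.SplitSpec(seed=3))
        tr2, te2 = E.split_dataset(table, E.SplitSpec(seed=3))
        assert tr1.ids == tr2.ids and te1.ids == te2.ids
        assert set(tr1.ids) | set(te1.ids) == set(table.ids)
        assert not set(tr1.ids) & set(te1.ids)
        tr3, _ = E.split_dataset(table, E.SplitSpec(seed=4))
        assert tr3.ids != tr1.ids

    def test_tiny_class_rejected(self):
        table = E.FeatureTable(ids=["a", "b", "c"], labels=["Tip", "Tip", "Point"],
                               X=np.zeros((3, 12)), kind="sequence12")
        with pytest.raises(ValueError, match="fewer than 2"):
            E.split_dataset(table)


class TestInteractionExpansion:
    def test_twelve_features_expand_to_seventy_eight(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 12)
        out = E.expand_interactions(x)
        assert out.shape == (78,)
        # independent enumeration oracle
        expected = list(x) + [x[i] * x[j]
                              for i, j in itertools.combinations(range(12), 2)]
        assert out == pytest.approx(np.asarray(expected))

    def test_pair_and_zero_cases(self):
        assert E.expand_interactions(np.array([2.0, 3.0])) == pytest.approx(
            [2.0, 3.0, 6.0])
        assert not E.expand_interactions(np.zeros(5)).any()

    def test_only_degree_two_supported(self):
        with pytest.raises(NotImplementedError):
            E.expand_interactions(np.zeros(3), degree=3)


class TestTraining:
    @pytest.mark.parametrize("kind,hp", [
        ("nlr", {}), ("svm", {}), ("lda", {}),
        ("ann", {"hidden_layers": 1, "max_iter": 500}),
    ])
    def test_separable_blobs_are_perfectly_classified(self, kind, hp):
        table = _blob_table()
        train, test = E.split_dataset(table, E.SplitSpec(seed=0))
        model = E.train(train, E.ModelSpec(kind, hp, seed=0))
        pred = model.predict(test.X)
        assert (pred == np.asarray(test.labels)).mean() == 1.0

    def test_lda_uses_one_vs_all_binary_discriminants(self):
        table = _blob_table()
        model = E.train(table, E.ModelSpec("lda"))
        ovr = model.estimator.named_steps["ovr_lda"]
        assert len(ovr.estimators_) == 4

    def test_training_is_deterministic(self):
        table = _blob_table()
        train, test = E.split_dataset(table)
        for kind in ("nlr", "svm", "lda"):
            a = E.train(train, E.ModelSpec(kind, seed=5)).predict(test.X)
            b = E.train(train, E.ModelSpec(kind, seed=5)).predict(test.X)
            assert np.array_equal(a, b)

    def test_harness_accepts_all_feature_kinds(self, fitted):
        seq_table = fitted.train_table
        for kind, table in [
            ("sequence12", seq_table),
            ("ets", E.FeatureTable(seq_table.ids, seq_table.labels,
                                   np.abs(seq_table.X) + 0.0, "ets")),
            ("ess", E.FeatureTable(seq_table.ids, seq_table.labels,
                                   np.abs(seq_table.X[:, :6]) + 0.0, "ess")),
        ]:
            model = E.train(table, E.ModelSpec("svm", seed=0))
            assert model.feature_kind == kind
            assert set(model.predict(table.X)) <= set(model.classes)

    def test_single_class_rejected(self):
        table = E.FeatureTable(ids=["a", "b"], labels=["Tip", "Tip"],
                               X=np.zeros((2, 12)), kind="sequence12")
        with pytest.raises(ValueError, match="2 classes"):
            E.train(table, E.ModelSpec("nlr"))

    def test_ann_depth_bounds(self):
        table = _blob_table(n_per_class=10)
        with pytest.raises(ValueError, match="1..5"):
            E.train(table, E.ModelSpec("ann", {"hidden_layers": 6}))


def test_shuffled_labels_drop_to_chance(fitted):
    """Label-permutation sanity: held-out accuracy collapses to ~25%."""
    train = fitted.train_table
    test = fitted.test_table
    accs = []
    for s in range(24):
        rng = np.random.default_rng(s)
        shuffled = [train.labels[i] for i in rng.permutation(len(train))]
        table = E.FeatureTable(train.ids, shuffled, train.X, train.kind)
        model = E.train(table, E.ModelSpec("nlr", seed=0))
        pred = model.predict(test.X)
        accs.append(100.0 * (pred == np.asarray(test.labels)).mean())
    assert 15.0 <= float(np.mean(accs)) <= 35.0
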