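"""Fold construction, the training loop contract and the four metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caprilung.evaluation import (
    ConfusionCounts,
    TrainSpec,
    compute_metrics,
    evaluate_model,
    make_folds,
    round_half_up,
    score_from_se_sp,
    train_model,
)
from caprilung.model import reduced_config


class TestMakeFolds:
    def test_balanced_hundred_samples(self):
        labels = np.repeat([0, 1, 2, 3], 25)
        plan = make_folds(labels, k=5, seed=0)
        sizes = [len(t) for t in plan.test_indices]
        assert sizes == [20] * 5

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 83)
        while np.bincount(labels, minlength=4).min() < 5:
            labels = rng.integers(0, 4, 83)
        plan = make_folds(labels, k=5, seed=1)
        all_test = np.concatenate(plan.test_indices)
        assert sorted(all_test) == list(range(83))  # disjoint and covering
        sizes = [len(t) for t in plan.test_indices]
        assert max(sizes) - min(sizes) <= 1

    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1, 2, 3], [40, 25, 20, 15])
        plan = make_folds(labels, k=5, seed=3)
        for test in plan.test_indices:
            counts = np.bincount(labels[list(test)], minlength=4)
            for c in range(4):
                expected = np.sum(labels == c) / 5
                assert abs(counts[c] - expected) <= 1

    def test_groups_never_split(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(np.arange(30), 4)  # 30 recordings x 4 segments
        labels = np.repeat(rng.integers(0, 4, 30), 4)
        while np.bincount(labels[::4], minlength=4).min() < 5:
            labels = np.repeat(rng.integers(0, 4, 30), 4)
        plan = make_folds(labels, k=5, seed=5, group_ids=groups)
        fold_of = {}
        for f, test in enumerate(plan.test_indices):
            for i in test:
                g = groups[i]
                assert fold_of.setdefault(g, f) == f

    def test_same_seed_same_plan(self):
        labels = np.repeat([0, 1, 2, 3], 30)
        a = make_folds(labels, k=5, seed=7)
        b = make_folds(labels, k=5, seed=7)
        assert a.test_indices == b.test_indices

    def test_small_class_rejected(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError):
            make_folds(labels, k=5, seed=0)


class TestMetrics:
    def test_hand_worked_confusion(self):
        """Nl=10 (8 correct), W=5 (4), T=5 (3), Ne=10 (9)."""
        m = np.zeros((4, 4), dtype=int)
        m[0, 0], m[0, 1] = 8, 2
        m[1, 1], m[1, 0] = 4, 1
        m[2, 2], m[2, 3] = 3, 2
        m[3, 3], m[3, 0] = 9, 1
        rep = compute_metrics(ConfusionCounts(m))
        assert rep.accuracy == pytest.approx(80.0)
        assert rep.se == pytest.approx(70.0)
        assert rep.sp == pytest.approx(80.0)
        assert rep.score == pytest.approx(75.0)

    def test_published_score_worked_example(self):
        """Se 86.99 and Sp 89.14 average to a Score of 88.07 at 2 dp."""
        assert round_half_up(score_from_se_sp(86.99, 89.14)) == 88.07

    def test_perfect_predictor(self):
        rep = compute_metrics(ConfusionCounts(np.diag([10, 5, 5, 10])))
        assert (rep.accuracy, rep.se, rep.sp, rep.score) == (100.0, 100.0, 100.0, 100.0)

    def test_count_scaling_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.integers(1, 30, (4, 4))
        a = compute_metrics(ConfusionCounts(m))
        b = compute_metrics(ConfusionCounts(7 * m))
        assert a == b

    def test_score_is_exact_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.integers(1, 50, (4, 4))
            rep = compute_metrics(ConfusionCounts(m))
            assert rep.score == (rep.se + rep.sp) / 2
            assert 0 <= rep.accuracy <= 100

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 40), min_size=16, max_size=16),
        factor=st.integers(1, 9),
    )
    def test_scaling_invariance_property(self, counts, factor):
        m = np.array(counts).reshape(4, 4)
        if m[0].sum() == 0 or m[1].sum() + m[2].sum() == 0:
            return  # undefined Se/Sp; covered by the raising test
        a = compute_metrics(ConfusionCounts(m))
        b = compute_metrics(ConfusionCounts(factor * m))
        assert a == b
        assert 0.0 <= a.accuracy <= 100.0
        assert a.score == (a.se + a.sp) / 2

    def test_undefined_denominators_raise(self):
        m = np.zeros((4, 4), dtype=int)
        m[0, 0] = m[3, 3] = 5
        with pytest.raises(ValueError, match="ensitivity"):
            compute_metrics(ConfusionCounts(m))
        m2 = np.zeros((4, 4), dtype=int)
        m2[1, 1] = m2[2, 2] = 5
        with pytest.raises(ValueError, match="pecificity"):
            compute_metrics(ConfusionCounts(m2))

    def test_from_predictions_row_sums(self):
        y_true = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        y_pred = np.array([0, 1, 1, 1, 2, 0, 3, 3])
        c = ConfusionCounts.from_predictions(y_true, y_pred)
        assert np.array_equal(c.class_totals, [2, 2, 2, 2])
        assert c.matrix.sum() == 8

    def test_constant_predictor_single_column(self):
        y_true = np.array([0, 1, 2, 3, 1])
        c = ConfusionCounts.from_predictions(y_true, np.zeros(5, dtype=int))
        assert c.matrix[:, 1:].sum() == 0
        assert c.matrix[:, 0].sum() == 5


@pytest.fixture(scope="module")
def tiny_config():
    return reduced_config()


class TestTraining:

    def test_zero_epochs_returns_initial_network(self, tiny_config, small_image_batch):
        x, y = small_image_batch
        net, hist = train_model(tiny_config, TrainSpec(epochs=0, seed=0), x, y)
        fresh = train_model(tiny_config, TrainSpec(epochs=0, seed=0), x, y)[0]
        assert np.array_equal(net.predict(x), fresh.predict(x))
        assert hist.train_loss == []

    def test_loss_decreases_over_first_steps(self, tiny_config, small_image_batch):
        x, y = small_image_batch
        _, hist = train_model(
            tiny_config, TrainSpec(lr=1e-4, batch_size=8, epochs=10, seed=0), x, y
        )
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_identical_seeds_identical_traces(self, tiny_config, small_image_batch):
        x, y = small_image_batch
        spec = TrainSpec(lr=1e-3, batch_size=4, epochs=2, seed=5)
        _, h1 = train_model(tiny_config, spec, x, y)
        _, h2 = train_model(tiny_config, spec, x, y)
        assert h1.train_loss == h2.train_loss

    def test_empty_training_set_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            train_model(tiny_config, TrainSpec(), np.zeros((0, 3, 96, 96)), np.zeros(0, int))

    def test_evaluate_empty_set_rejected(self, tiny_config, small_image_batch):
        x, y = small_image_batch
        net, _ = train_model(tiny_config, TrainSpec(epochs=0, seed=0), x, y)
        with pytest.raises(ValueError):
            evaluate_model(net, np.zeros((0, 3, 96, 96)), np.zeros(0, int))
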