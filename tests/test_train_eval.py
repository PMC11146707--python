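"""Metric formulas, early stopping, and the training loop."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, f1_score

from afmsdc.model import build_network
from afmsdc.specs import MSDC_A, network_spec
from afmsdc.train_eval import (
    FOUR_CLASSES,
    ConfusionCounts,
    EarlyStopping,
    MultiClassCounts,
    TrainConfig,
    UndefinedMetricError,
    evaluate,
    f1_scores,
    segments_to_arrays,
    sensitivity_specificity,
    train,
)
from afmsdc.ecgsim import make_dataset


class TestBinaryMetrics:
    @pytest.mark.parametrize(
        "counts,se,sp",
        [
            ((10, 20, 0, 0), 1.0, 1.0),
            ((9, 18, 2, 1), 0.9, 0.9),
            ((0, 5, 0, 5), 0.0, 1.0),
        ],
    )
    def test_hand_computed_values(self, counts, se, sp):
        tp, tn, fp, fn = counts
        got = sensitivity_specificity(ConfusionCounts(tp, tn, fp, fn))
        assert got == (pytest.approx(se), pytest.approx(sp))

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedMetricError, match="[Ss]ensitivity"):
            sensitivity_specificity(ConfusionCounts(0, 5, 5, 0))
        with pytest.raises(UndefinedMetricError, match="[Ss]pecificity"):
            sensitivity_specificity(ConfusionCounts(5, 0, 0, 5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)


class TestF1Scores:
    def test_perfect_classifier(self):
        m = MultiClassCounts(np.diag([5, 5, 5, 5]))
        assert f1_scores(m) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_fixed_matrix(self):
        # Normal row: diag 8, row marginal 10, column marginal 12 -> 16/22
        m = MultiClassCounts(np.array([
            [8, 1, 1, 0],
            [2, 6, 1, 1],
            [1, 0, 7, 0],
            [1, 0, 0, 4],
        ]))
        f1n, f1a, f1o, f1p, f1all = f1_scores(m)
        assert f1n == pytest.approx(16 / 22)
        assert f1a == pytest.approx(12 / 17)
        assert f1o == pytest.approx(14 / 17)
        assert f1p == pytest.approx(8 / 10)
        assert f1all == pytest.approx((f1n + f1a + f1o + f1p) / 4)

    def test_macro_is_exact_mean(self):
        rng = np.random.default_rng(0)
        m = MultiClassCounts(rng.integers(1, 50, size=(4, 4)))
        *per_class, macro = f1_scores(m)
        assert macro == sum(per_class) / 4  # identical float arithmetic

    def test_undefined_class_named_in_error(self):
        m = np.diag([5, 5, 5, 0])
        m[3, :] = 0
        with pytest.raises(UndefinedMetricError, match="noise"):
            f1_scores(MultiClassCounts(m))

    def test_uniform_random_predictions_near_quarter(self):
        rng = np.random.default_rng(42)
        y_true = rng.integers(0, 4, size=10000)
        y_pred = rng.integers(0, 4, size=10000)
        *per_class, macro = f1_scores(MultiClassCounts.from_predictions(y_true, y_pred))
        assert macro == pytest.approx(0.25, abs=0.02)

    def test_matches_sklearn_macro_f1(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 4, size=500)
        y_pred = rng.integers(0, 4, size=500)
        *_, macro = f1_scores(MultiClassCounts.from_predictions(y_true, y_pred))
        assert macro == pytest.approx(f1_score(y_true, y_pred, average="macro"))


class _StubModel:
    """Fixed-prediction model honouring the evaluation interface."""

    def __init__(self, predictions, n_classes):
        self._p = np.asarray(predictions)
        self.spec = network_spec("afmsdc_a", n_blocks=1, n_classes=n_classes,
                                 downsample_schedule=())
        self._ofs = 0

    def predict(self, xb):
        out = self._p[self._ofs : self._ofs + len(xb)]
        self._ofs += len(xb)
        return out


def _segments(labels):
    from afmsdc.ecgsim import EcgSegment

    return [
        EcgSegment(samples=np.zeros(250), fs=250.0, label=lab, duration=1.0)
        for lab in labels
    ]


class TestEvaluate:
    def test_oracle_stub_scores_perfectly(self):
        labels = ["af"] * 6 + ["normal"] * 6
        model = _StubModel([1] * 6 + [0] * 6, n_classes=2)
        report = evaluate(model, _segments(labels), task="binary")
        assert report["metrics"]["sensitivity"] == 1.0
        assert report["metrics"]["specificity"] == 1.0

    def test_constant_stub_hits_degenerate_values(self):
        labels = ["af"] * 5 + ["normal"] * 5
        model = _StubModel([1] * 10, n_classes=2)
        report = evaluate(model, _segments(labels), task="binary")
        assert report["metrics"]["sensitivity"] == 1.0
        assert report["metrics"]["specificity"] == 0.0

    def test_metric_path_equals_double_entry_tally(self):
        """evaluate() agrees with sklearn's independently tallied confusion
        matrix plus the direct formulas, over 100 random cases."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(8, 40))
            y_true = rng.integers(0, 4, size=n)
            y_pred = rng.integers(0, 4, size=n)
            labels = [FOUR_CLASSES[i] for i in y_true]
            cm = confusion_matrix(y_true, y_pred, labels=range(4))
            diag = cm.diagonal()
            denom = cm.sum(axis=0) + cm.sum(axis=1)
            if (denom == 0).any():
                continue
            report = evaluate(_StubModel(y_pred, 4), _segments(labels),
                              task="four_class")
            np.testing.assert_array_equal(report["counts"], cm)
            want = 2 * diag / denom
            got = [report["metrics"][f"f1_{c}"]
                   for c in ("normal", "af", "other", "noise")]
            np.testing.assert_allclose(got, want, atol=1e-12)
            assert report["metrics"]["f1_macro"] == pytest.approx(want.mean())

    def test_task_arity_mismatch_rejected(self):
        model = _StubModel([0], n_classes=2)
        with pytest.raises(ValueError, match="task"):
            evaluate(model, _segments(["af"]), task="four_class")

    def test_report_carries_architecture_summary(self):
        model = _StubModel([1, 0], n_classes=2)
        report = evaluate(model, _segments(["af", "normal"]), task="binary")
        assert report["architecture"]["block"] == "msdc_a"
        assert report["architecture"]["params_published"] == 224


class TestEarlyStopping:
    def test_constant_loss_from_epoch_three_stops_at_thirteen(self):
        """Best at epoch 3; ten flat epochs later training stops at epoch 13."""
        stopper = EarlyStopping(patience=10)
        losses = [1.0, 0.8, 0.5] + [0.5] * 20
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 13
        assert stopper.best_epoch == 3

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopping(patience=10)
        assert not any(
            stopper.update(e, 1.0 / e) for e in range(1, 101)
        )

    def test_patience_counts_strict_improvement_only(self):
        stopper = EarlyStopping(patience=2)
        assert not stopper.update(1, 1.0)
        assert not stopper.update(2, 1.0)   # equal is not an improvement
        assert stopper.update(3, 1.0)


class TestTrainConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=5, early_stop_patience=10)

    def test_config_hash_stable(self):
        assert TrainConfig().config_hash() == TrainConfig().config_hash()
        assert TrainConfig(seed=1).config_hash() != TrainConfig(seed=2).config_hash()


@pytest.fixture(scope="module")
def tiny_sets():
    segs = make_dataset(14, ("af", "normal"), 250.0, 4.0, seed=55)
    return segs[:20], segs[20:28]


class TestTrainLoop:

    def _net(self, seed=0):
        return build_network(
            network_spec("afmsdc_c", n_blocks=1, n_classes=2,
                         downsample_schedule=(0,), input_length="variable"),
            seed=seed,
        )

    def test_empty_sets_rejected_before_training(self, tiny_sets):
        with pytest.raises(ValueError, match="non-empty"):
            train(self._net(), [], tiny_sets[1], TrainConfig(max_epochs=2,
                                                             early_stop_patience=1))

    def test_label_class_mismatch_rejected(self, tiny_sets):
        from afmsdc.ecgsim import EcgSegment

        bad = [EcgSegment(np.zeros(250), 250.0, "weird", 1.0)]
        net = build_network(network_spec("afmsdc_c", n_blocks=1, n_classes=4,
                                         downsample_schedule=()), seed=0)
        with pytest.raises(ValueError, match="weird"):
            train(net, bad, bad, TrainConfig(max_epochs=2, early_stop_patience=1))

    def test_history_and_determinism(self, tiny_sets):
        tr, va = tiny_sets
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=3,
                          early_stop_patience=2, batch_size=8, seed=21)
        _, h1 = train(self._net(seed=2), tr, va, cfg)
        _, h2 = train(self._net(seed=2), tr, va, cfg)
        assert [r["epoch"] for r in h1] == [1, 2, 3]
        assert h1 == h2  # bit-identical seeded training

    def test_early_stop_restores_best_weights(self, tiny_sets):
        """With a zero-progress learning rate the val loss never improves after
        epoch 1, so training stops after 1 + patience epochs."""
        tr, va = tiny_sets
        cfg = TrainConfig(learning_rate=1e-20, max_epochs=20,
                          early_stop_patience=3, batch_size=8, seed=0)
        model, history = train(self._net(seed=4), tr, va, cfg)
        assert len(history) == 4  # epoch 1 best, then 3 stale epochs
        losses = [r["val_loss"] for r in history]
        assert min(losses) == losses[0]


def test_segments_to_arrays_normalizes_per_segment(small_binary_dataset):
    X, y = segments_to_arrays(small_binary_dataset[:4], ("non_af", "af"))
    assert X.shape == (4, 1, 2500)
    np.testing.assert_allclose(X.mean(axis=2), 0.0, atol=1e-5)
    np.testing.assert_allclose(X.std(axis=2), 1.0, atol=1e-4)
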