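"""Optimizer, schedule, metrics and evaluation reports against independent oracles."""

from types import SimpleNamespace

import numpy as np
import pytest

from conftest import tiny_model_config
from gavit import build_model
from gavit._tensor import Tensor
from gavit.train_eval import (Adam, EvalCounts, ReduceLROnPlateau, TrainConfig,
                              accuracy, confusion_matrix, counts_from_confusion,
                              cross_entropy, evaluate, one_hot,
                              precision_recall_f1, save_history, save_report,
                              stratified_split, train)


class TestSchedule:
    def _sched(self, lr=1e-5, patience=5):
        opt = Adam({"w": Tensor(np.zeros(1), requires_grad=True)}, lr)
        return opt, ReduceLROnPlateau(opt, 0.1, patience, 1e-8)

    def test_six_flat_epochs_drop_lr_once(self):
        opt, sched = self._sched()
        for _ in range(6):
            sched.step(1.0)
        assert np.isclose(opt.lr, 1e-6)

    def test_improvement_resets_patience(self):
        opt, sched = self._sched()
        for loss in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4):
            sched.step(loss)
        assert opt.lr == 1e-5

    def test_lr_never_below_floor(self):
        opt, sched = self._sched(lr=1e-7, patience=1)
        for _ in range(20):
            sched.step(1.0)
        assert opt.lr == 1e-8


class TestAdam:
    def test_first_step_matches_hand_derived_update(self):
        w = Tensor(np.array([2.0]), requires_grad=True)
        opt = Adam({"w": w}, lr=0.1)
        g = np.array([3.0])
        w.grad = g.copy()
        opt.step()
        # bias-corrected first step: m_hat=g, v_hat=g^2
        expected = 2.0 - 0.1 * g / (np.abs(g) + 1e-8)
        assert np.allclose(w.data, expected)

    def test_second_step_matches_recurrence(self):
        w = Tensor(np.array([1.0]), requires_grad=True)
        opt = Adam({"w": w}, lr=0.01)
        m = v = 0.0
        x = 1.0
        for t, g in enumerate([2.0, -1.0], start=1):
            w.grad = np.array([g])
            opt.step()
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            x -= 0.01 * (m / (1 - 0.9 ** t)) / (np.sqrt(v / (1 - 0.999 ** t))
                                                + 1e-8)
        assert np.allclose(w.data, [x])


class TestMetrics:
    def test_accuracy_and_f1_arithmetic(self):
        assert accuracy(EvalCounts(tp=99, tn=299, fp=1, fn=1)) == 0.995
        assert precision_recall_f1(EvalCounts(tp=0, tn=5, fp=0, fn=0)) == (0, 0, 0)
        p, r, f1 = precision_recall_f1(EvalCounts(tp=1, tn=0, fp=0, fn=1))
        assert (p, r) == (1.0, 0.5) and np.isclose(f1, 2.0 / 3.0)
        with pytest.raises(ZeroDivisionError):
            accuracy(EvalCounts(0, 0, 0, 0))

    def test_counts_consistent_with_confusion_matrix(self, rng):
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        m = confusion_matrix(y_true, y_pred, 4)
        for k, c in enumerate(counts_from_confusion(m)):
            assert c.tp == m[k, k]
            assert c.fp == m[:, k].sum() - m[k, k]
            assert c.fn == m[k, :].sum() - m[k, k]
            assert c.total == 200

    def test_matches_sklearn_oracle(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y_true = rng.integers(0, 4, size=300)
        y_pred = rng.integers(0, 4, size=300)
        m = confusion_matrix(y_true, y_pred, 4)
        assert np.array_equal(m, sk.confusion_matrix(y_true, y_pred,
                                                     labels=range(4)))
        p_sk, r_sk, f_sk, _ = sk.precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0)
        for k, c in enumerate(counts_from_confusion(m)):
            p, r, f1 = precision_recall_f1(c)
            assert np.allclose((p, r, f1), (p_sk[k], r_sk[k], f_sk[k]))


class TestSplit:
    def test_stratified_fractions_and_disjointness(self, rng):
        labels = np.repeat(np.arange(4), 100)
        tr, va, te = stratified_split(labels, (0.6, 0.2, 0.2), rng)
        assert len(tr) == 240 and len(va) == 80 and len(te) == 80
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
        for split in (tr, va, te):
            counts = np.bincount(labels[split], minlength=4)
            assert len(set(counts)) == 1  # perfectly balanced per class


class _FixedPredictor:
    """Evaluation stub emitting predetermined class probabilities."""

    def __init__(self, preds, k=4):
        self.cfg = SimpleNamespace(num_classes=k)
        self._preds = np.asarray(preds)
        self._cursor = 0

    def forward(self, images, training=False):
        n = images.shape[0]
        out = one_hot(self._preds[self._cursor:self._cursor + n],
                      self.cfg.num_classes)
        self._cursor += n
        return Tensor(out * 0.94 + 0.015)


class TestEvaluate:
    def test_perfect_predictor_identity_confusion(self):
        labels = np.repeat(np.arange(4), 10)
        rep = evaluate(_FixedPredictor(labels), np.zeros((40, 2, 2, 3)), labels)
        assert np.array_equal(rep["confusion_matrix"], np.diag([10] * 4))
        assert rep["overall_accuracy"] == 1.0
        for stats in rep["per_class"].values():
            assert stats["precision"] == stats["recall"] == stats["f1"] == 1.0

    def test_constant_predictor_on_balanced_data(self):
        labels = np.repeat(np.arange(4), 10)
        rep = evaluate(_FixedPredictor(np.zeros(40, dtype=int)),
                       np.zeros((40, 2, 2, 3)), labels)
        assert rep["overall_accuracy"] == 0.25
        assert rep["degenerate_classes"] == [f"class_{i}" for i in (1, 2, 3)]

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_FixedPredictor([]), np.zeros((0, 2, 2, 3)), np.zeros(0))

    def test_report_files_written(self, tmp_path):
        labels = np.repeat(np.arange(4), 5)
        rep = evaluate(_FixedPredictor(labels), np.zeros((20, 2, 2, 3)), labels)
        save_report(rep, tmp_path / "report.json", tmp_path / "confusion.csv")
        import json
        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["overall_accuracy"] == 1.0
        assert (tmp_path / "confusion.csv").read_text().count("\n") == 5


class TestTrainLoop:
    def _data(self, rng, n=24, side=32):
        x = rng.random((n, side, side, 3))
        y = np.tile(np.arange(4), n // 4)
        return x, y

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        model = build_model(tiny_model_config())
        before = {k: t.data.copy() for k, t in model.parameters().items()}
        cfg = TrainConfig(learning_rate=1e-3, epochs=0, batch_size=8,
                          splits=(0.5, 0.25, 0.25))
        train(model, self._data(rng), self._data(rng, n=8), cfg)
        for k, t in model.parameters().items():
            assert np.array_equal(t.data, before[k]), k

    @pytest.mark.parametrize("augment", ["none", "cutmix", "randaugment"])
    def test_two_epochs_record_history_and_stay_finite(self, rng, augment):
        model = build_model(tiny_model_config())
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=8,
                          splits=(0.5, 0.25, 0.25), augment=augment, seed=1)
        _, history = train(model, self._data(rng), self._data(rng, n=8), cfg)
        assert len(history) == 2
        for row in history:
            assert np.isfinite(row["loss"]) and np.isfinite(row["val_loss"])
            assert row["lr"] == 1e-3

    def test_learning_rate_non_increasing_over_training(self, rng):
        model = build_model(tiny_model_config())
        cfg = TrainConfig(learning_rate=1e-3, epochs=8, batch_size=8,
                          splits=(0.5, 0.25, 0.25), plateau_patience=1, seed=0)
        _, history = train(model, self._data(rng, n=8),
                           self._data(rng, n=8), cfg)
        lrs = [row["lr"] for row in history]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert all(lr >= cfg.lr_floor for lr in lrs)

    def test_history_csv_roundtrip(self, tmp_path):
        history = [{"epoch": 0, "loss": 1.0, "val_loss": 1.1,
                    "val_accuracy": 0.5, "lr": 1e-3}]
        save_history(history, tmp_path / "history.csv")
        text = (tmp_path / "history.csv").read_text()
        assert text.splitlines()[0] == "epoch,loss,val_loss,val_accuracy,lr"

    def test_cross_entropy_matches_manual_log_loss(self, rng):
        logits = rng.normal(size=(5, 4))
        y = one_hot(rng.integers(0, 4, size=5), 4)
        got = cross_entropy(Tensor(logits), y).data
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        manual = -np.log(probs[y.astype(bool)]).mean()
        assert np.allclose(got, manual)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(plateau_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(splits=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            TrainConfig(augment="mixup")
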