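"""Metrics, t-test and ablation harness against hand-coded oracles."""

import numpy as np
import pandas as pd
import pytest

from parnet.io_skeleton import WindowSet
from parnet.models import ModelConfig, build_model
from parnet.esn import ReservoirConfig
from parnet.train_eval import (AblationTable, History, TrainConfig,
                               evaluate_model, export_history,
                               metrics_from_predictions, paired_t_test,
                               run_ablation, shuffle_window_frames,
                               significance_vs_reference, train_model)


def macro_metrics_oracle(y_true, y_pred, n_classes):
    """Independent per-class enumeration of macro precision/recall/F1."""
    cm = np.zeros((n_classes, n_classes), int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    precs, recs, f1s = [], [], []
    for c in range(n_classes):
        tp = cm[c, c]
        prec = tp / cm[:, c].sum() if cm[:, c].sum() else 0.0
        rec = tp / cm[c, :].sum() if cm[c, :].sum() else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return (cm, np.trace(cm) / cm.sum(), np.mean(precs), np.mean(recs),
            np.mean(f1s))


class TestMetrics:
    def test_worked_confusion_example(self):
        """Six predictions with two errors: hand-enumerated macro metrics."""
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 1, 1, 1, 2, 0])
        rep = metrics_from_predictions(y_true, y_pred, 3)
        assert rep.accuracy == 66.67
        assert rep.precision == 72.22
        assert rep.recall == 66.67

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = metrics_from_predictions(y, y, 3)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (
            100.0, 100.0, 100.0, 100.0)
        np.testing.assert_array_equal(rep.confusion, 2 * np.eye(3, dtype=int))

    def test_constant_predictor_on_balanced_classes(self):
        y_true = np.repeat(np.arange(5), 10)
        rep = metrics_from_predictions(y_true, np.zeros(50, int), 5)
        assert rep.accuracy == 20.0

    def test_matches_enumeration_oracle_on_random_draws(self, rng):
        for _ in range(50):
            n_classes = int(rng.integers(2, 6))
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, n_classes, n)
            y_pred = rng.integers(0, n_classes, n)
            rep = metrics_from_predictions(y_true, y_pred, n_classes)
            cm, acc, prec, rec, f1 = macro_metrics_oracle(y_true, y_pred,
                                                          n_classes)
            np.testing.assert_array_equal(rep.confusion, cm)
            for got, want in ((rep.accuracy, acc), (rep.precision, prec),
                              (rep.recall, rec), (rep.f1, f1)):
                assert abs(got - 100 * want) <= 0.005 + 1e-9  # 2-dec rounding

    def test_confusion_conservation(self, rng):
        for _ in range(100):
            n_classes = int(rng.integers(2, 5))
            n = int(rng.integers(5, 40))
            y_true = rng.integers(0, n_classes, n)
            y_pred = rng.integers(0, n_classes, n)
            cm = metrics_from_predictions(y_true, y_pred, n_classes).confusion
            np.testing.assert_array_equal(
                cm.sum(axis=1), np.bincount(y_true, minlength=n_classes))
            np.testing.assert_array_equal(
                cm.sum(axis=0), np.bincount(y_pred, minlength=n_classes))
            assert cm.sum() == n


class TestPairedT:
    def test_identical_scores_accept_null(self):
        res = paired_t_test([90, 91, 92], [90, 91, 92])
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        assert not res.reject_null

    def test_worked_example(self):
        """d = (5,4,8,7): t = 6*2/sd(10/3) ~= 6.57 with 3 df."""
        res = paired_t_test([90, 92, 94, 91], [85, 88, 86, 84])
        assert res.df == 3
        assert abs(res.t_statistic - 6.573) < 0.01
        assert res.reject_null

    def test_rejection_rule_follows_alpha(self):
        res = paired_t_test([90, 92, 94, 91], [85, 88, 86, 84], alpha=0.05)
        assert res.reject_null == (res.p_value < 0.05)

    def test_constant_nonzero_difference_is_degenerate(self):
        res = paired_t_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert res.degenerate and res.reject_null and res.p_value == 0.0

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = paired_t_test(a, b)
            d = a - b
            t = d.mean() * np.sqrt(n) / d.std(ddof=1)
            assert abs(res.t_statistic - t) < 1e-9

    def test_needs_at_least_two_pairs(self):
        with pytest.raises(ValueError, match="two"):
            paired_t_test([1.0], [2.0])


def tiny_windowset(n_per_class=20, n_classes=2, L=8, F=4, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)
    data = rng.normal(size=(n, L, F)) + labels[:, None, None] * 2.0
    return WindowSet(data, labels, n_classes, L)


def tiny_model(L=8, F=4, n_classes=2, seed=0):
    return build_model("MLP", ModelConfig(
        L, F, n_classes, reservoir=ReservoirConfig(n_units=4),
        mlp_units=(8,), head_units=4, recurrent_units=4, seed=seed))


class TestTraining:
    def test_zero_epochs_returns_model_unchanged(self):
        ws = tiny_windowset()
        m = tiny_model()
        before = [p.value.copy() for p in m.net.params()]
        m2, hist = train_model(m, ws, None, TrainConfig(epochs=0))
        assert len(hist) == 0
        for p, b in zip(m2.net.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_history_has_one_entry_per_epoch(self):
        ws = tiny_windowset()
        _, hist = train_model(tiny_model(), ws, ws, TrainConfig(epochs=5))
        assert len(hist) == 5
        assert np.all(np.isfinite(hist.train_loss))
        assert np.all(np.isfinite(hist.val_acc))

    def test_training_reduces_loss_on_separable_data(self):
        ws = tiny_windowset()
        _, hist = train_model(tiny_model(), ws, None,
                              TrainConfig(epochs=20, learning_rate=1e-3))
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_same_seed_is_bit_deterministic(self):
        ws = tiny_windowset()
        _, h1 = train_model(tiny_model(seed=3), ws, ws,
                            TrainConfig(epochs=4, seed=9))
        _, h2 = train_model(tiny_model(seed=3), ws, ws,
                            TrainConfig(epochs=4, seed=9))
        assert h1.train_loss == h2.train_loss
        assert h1.val_acc == h2.val_acc

    def test_non_adam_optimizer_is_rejected(self):
        with pytest.raises(ValueError, match="adam"):
            TrainConfig(optimizer="sgd")

    def test_evaluate_on_separable_data(self):
        ws = tiny_windowset()
        m, _ = train_model(tiny_model(), ws, None,
                           TrainConfig(epochs=30, learning_rate=1e-3))
        rep = evaluate_model(m, ws)
        assert rep.accuracy >= 95.0
        assert rep.n_test == ws.n_windows


class TestShuffleFrames:
    def test_preserves_frame_multiset_per_window(self, rng):
        ws = tiny_windowset()
        shuf = shuffle_window_frames(ws, seed=4)
        for i in range(ws.n_windows):
            a = np.sort(ws.data[i], axis=0)
            b = np.sort(shuf.data[i], axis=0)
            np.testing.assert_array_equal(a, b)
        assert any((ws.data[i] != shuf.data[i]).any()
                   for i in range(ws.n_windows))


class TestAblation:
    @staticmethod
    def frame_table(n_per_class=12, T=20, n_classes=2, seed=0):
        from parnet.io_skeleton import FrameTable, SchemaSpec

        rng = np.random.default_rng(seed)
        schema = SchemaSpec(2, 2)
        rows, labels, groups = [], [], []
        g = 0
        for c in range(n_classes):
            for _ in range(n_per_class):
                rows.append(rng.normal(size=(T, 4)) + 2.0 * c)
                labels.extend([c] * T)
                groups.extend([g] * T)
                g += 1
        return FrameTable(np.vstack(rows), np.array(labels), schema,
                          groups=np.array(groups))

    def test_grid_is_complete_and_cached(self, tmp_path):
        data = self.frame_table()
        cfg = TrainConfig(epochs=2, seed=1)
        models, lengths = ["MLP", "ESN"], [10, 20]
        mc = ModelConfig(10, 4, 2, reservoir=ReservoirConfig(n_units=4),
                         mlp_units=(8,), head_units=4, recurrent_units=4)
        t1 = run_ablation(models, lengths, data, cfg, cache_dir=tmp_path,
                          model_config=mc)
        assert t1.is_complete(models, lengths)
        assert not t1.failures
        files = sorted(tmp_path.glob("*.json"))
        assert len(files) == 4
        stamps = {f: f.read_bytes() for f in files}
        t2 = run_ablation(models, lengths, data, cfg, cache_dir=tmp_path,
                          model_config=mc)
        assert {f: f.read_bytes() for f in files} == stamps  # pure cache hit
        for key in t1.results:
            assert t1.results[key].accuracy == t2.results[key].accuracy

    def test_empty_model_list_is_an_empty_table(self):
        t = run_ablation([], [10], self.frame_table(), TrainConfig(epochs=1))
        assert t.results == {} and t.failures == {}

    def test_infeasible_length_is_recorded_not_raised(self):
        data = self.frame_table(T=20)
        t = run_ablation(["MLP"], [500], data, TrainConfig(epochs=1))
        assert ("MLP", 500) in t.failures

    def test_metric_frame_layout(self):
        t = AblationTable()
        t.results[("A", 30)] = metrics_from_predictions(
            np.array([0, 1]), np.array([0, 1]), 2)
        t.results[("A", 60)] = metrics_from_predictions(
            np.array([0, 1]), np.array([0, 0]), 2)
        df = t.metric_frame("accuracy")
        assert list(df.columns) == [30, 60]
        assert df.loc["A", 30] == 100.0 and df.loc["A", 60] == 50.0

    def test_significance_vs_reference_layout(self):
        t = AblationTable()
        for L, (a, b) in zip((30, 60, 90, 120), ((1, 0), (1, 0), (1, 1), (1, 0))):
            y = np.array([0, 1, 0, 1])
            t.results[("PAR-Net", L)] = metrics_from_predictions(
                y, y if a else 1 - y, 2)
            t.results[("MLP", L)] = metrics_from_predictions(
                y, y if b else np.array([0, 0, 1, 1]), 2)
        df = significance_vs_reference(t)
        assert list(df["comparison"]) == ["PAR-Net vs. MLP"]
        assert {"t_statistic", "p_value", "reject_null"} <= set(df.columns)


class TestExportHistory:
    @staticmethod
    def fake_history(n=100):
        h = History()
        for e in range(n):
            h.train_loss.append(1.0 / (e + 1))
            h.train_acc.append(1.0 - 1.0 / (e + 2))
            h.val_loss.append(1.2 / (e + 1))
            h.val_acc.append(1.0 - 1.5 / (e + 2))
        return h

    def test_csv_round_trips_with_plots(self, tmp_path):
        files = export_history(self.fake_history(), tmp_path)
        df = pd.read_csv(tmp_path / "history.csv")
        assert len(df) == 100
        assert set(df.columns) == {"epoch", "train_loss", "train_acc",
                                   "val_loss", "val_acc"}
        # monotone synthetic history: extrema sit at the ends
        assert df["train_loss"].idxmin() == 99 and df["train_loss"].idxmax() == 0
        assert (tmp_path / "history_acc.png").exists()
        assert (tmp_path / "history_loss.png").exists()
        assert len(files) == 3

    def test_empty_history_errors_without_partial_files(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            export_history(History(), tmp_path / "sub")
        assert not (tmp_path / "sub").exists() or \
            not any((tmp_path / "sub").iterdir())
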