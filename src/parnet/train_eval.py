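"""Training recipe, evaluation metrics, ablation grid and significance test.

The training recipe is fixed across all architectures so that the ablation
grid compares feature extractors, not tuning: Adam with learning rate 1e-4,
categorical cross-entropy, batch size 32, 100 epochs, seeded shuffling.
Metrics are the four standard classification scores (accuracy and macro
precision/recall/F1, reported as percentages) derived from the confusion
matrix; model comparisons use a paired two-sided t-test at alpha = 0.05 with
the runs paired by shared window lengths and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .io_skeleton import FrameTable, WindowSet, make_windows, normalize_windows, \
    split_dataset
from .models import ModelConfig, ModelHandle, build_model
from .nn import Adam, softmax_cross_entropy

__all__ = [
    "TrainConfig", "History", "MetricsReport", "SignificanceResult",
    "AblationTable", "train_model", "evaluate_model", "paired_t_test",
    "run_ablation", "significance_vs_reference", "export_history",
    "shuffle_window_frames",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """The shared optimisation recipe (all fields overridable)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment (adam) optimizer is supported")
        if self.loss != "categorical_crossentropy":
            raise ValueError("only categorical cross-entropy is supported")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class History:
    """Per-epoch training curves."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss, "train_acc": self.train_acc,
            "val_loss": self.val_loss, "val_acc": self.val_acc,
        })


@dataclass
class MetricsReport:
    """Confusion matrix plus the four headline percentages (2 decimals)."""

    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    n_test: int

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "n_test": self.n_test}


@dataclass
class SignificanceResult:
    """Paired t-test outcome; ``reject_null`` iff p < alpha."""

    t_statistic: float
    p_value: float
    alpha: float
    reject_null: bool
    df: int
    degenerate: bool = False


def _batch_loss_acc(model: ModelHandle, ws: WindowSet, batch_size: int = 256
                    ) -> tuple[float, float]:
    probs = model.forward(ws.data, batch_size=batch_size)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(ws.n_windows), ws.labels] + eps)))
    acc = float(np.mean(np.argmax(probs, axis=1) == ws.labels))
    return loss, acc


def train_model(model: ModelHandle, train: WindowSet,
                val: WindowSet | None = None,
                cfg: TrainConfig = TrainConfig()
                ) -> tuple[ModelHandle, History]:
    """Fit ``model`` in place with the shared recipe; returns it with the
    per-epoch history.  ``epochs == 0`` returns the model unchanged."""
    if train.n_windows == 0:
        raise ValueError("training set is empty")
    hist = History()
    if cfg.epochs == 0:
        return model, hist
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.net.params(), lr=cfg.learning_rate)
    onehot = train.onehot
    n = train.n_windows
    last_finite = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = train.data[idx], onehot[idx]
            logits = model.net.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}; last finite loss "
                    f"was {last_finite}")
            last_finite = loss
            model.net.backward(dlogits)
            opt.step()  # consumes and clears the gradients
            ep_loss += loss * len(idx)
            ep_correct += int(np.sum(np.argmax(logits, axis=1)
                                     == train.labels[idx]))
        hist.train_loss.append(ep_loss / n)
        hist.train_acc.append(ep_correct / n)
        if val is not None and val.n_windows:
            vl, va = _batch_loss_acc(model, val)
            hist.val_loss.append(vl)
            hist.val_acc.append(va)
        else:
            hist.val_loss.append(float("nan"))
            hist.val_acc.append(float("nan"))
    return model, hist


def evaluate_model(model: ModelHandle, test: WindowSet) -> MetricsReport:
    """Confusion matrix and accuracy / macro precision / recall / F1 (%).

    Predictions are the argmax of the forward probabilities.  A class that is
    never predicted gets precision 0 for the macro average (logged).
    """
    if test.n_windows == 0:
        raise ValueError("test set is empty")
    preds = model.predict(test.data)
    return metrics_from_predictions(test.labels, preds, test.n_classes)


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             n_classes: int) -> MetricsReport:
    labels = np.arange(n_classes)
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    missing = set(labels) - set(np.unique(y_pred))
    if missing & set(np.unique(y_true)):
        log.warning("classes %s never predicted: their precision counts as 0 "
                    "in the macro average", sorted(missing))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="macro", zero_division=0)
    acc = np.trace(cm) / cm.sum()
    return MetricsReport(
        confusion=cm,
        accuracy=round(100.0 * float(acc), 2),
        precision=round(100.0 * float(prec), 2),
        recall=round(100.0 * float(rec), 2),
        f1=round(100.0 * float(f1), 2),
        n_test=int(cm.sum()),
    )


def paired_t_test(scores_a, scores_b, alpha: float = 0.05
                  ) -> SignificanceResult:
    """Two-sided paired t-test on per-run metric vectors (paired by run).

    Zero-variance differences are handled explicitly: all-equal scores give
    t = 0, p = 1; a constant non-zero difference is flagged degenerate.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired runs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return SignificanceResult(0.0, 1.0, alpha, False, n - 1)
        return SignificanceResult(float(np.sign(d.mean()) * np.inf), 0.0,
                                  alpha, True, n - 1, degenerate=True)
    t, p = scipy.stats.ttest_rel(a, b)
    return SignificanceResult(float(t), float(p), alpha, bool(p < alpha), n - 1)


@dataclass
class AblationTable:
    """(model x window length) grid of metric reports plus histories."""

    results: dict = field(default_factory=dict)   # (model, L) -> MetricsReport
    histories: dict = field(default_factory=dict)  # (model, L) -> History
    failures: dict = field(default_factory=dict)   # (model, L) -> str

    def metric_frame(self, metric: str = "accuracy") -> pd.DataFrame:
        """Wide table: rows = models, columns = window lengths."""
        rows = {}
        for (m, L), rep in self.results.items():
            rows.setdefault(m, {})[L] = getattr(rep, metric)
        df = pd.DataFrame(rows).T
        return df[sorted(df.columns)] if len(df.columns) else df

    def long_frame(self) -> pd.DataFrame:
        recs = []
        for (m, L), rep in self.results.items():
            recs.append({"model": m, "window_length": L, **rep.as_dict()})
        return pd.DataFrame(recs)

    def is_complete(self, models, lengths) -> bool:
        return all((m, L) in self.results for m in models for L in lengths)


def _cache_key(model_name: str, length: int, cfg: TrainConfig,
               data_digest: str, model_seed: int) -> str:
    payload = json.dumps({"model": model_name, "length": length,
                          "cfg": asdict(cfg), "data": data_digest,
                          "model_seed": model_seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def prepare_windows(data: FrameTable, length: int, seed: int,
                    fractions=(0.8, 0.1, 0.1), normalization: str = "zscore",
                    stride: int | None = None
                    ) -> tuple[WindowSet, WindowSet, WindowSet]:
    """window -> stratified split -> normalise (train statistics only)."""
    ws = make_windows(data, length, stride)
    tr, va, te = split_dataset(ws, fractions, seed=seed)
    tr, stats = normalize_windows(tr, normalization)
    va, _ = normalize_windows(va, normalization, stats=stats)
    te, _ = normalize_windows(te, normalization, stats=stats)
    return tr, va, te


def run_ablation(models, lengths, data: FrameTable,
                 cfg: TrainConfig = TrainConfig(),
                 fractions=(0.8, 0.1, 0.1), normalization: str = "zscore",
                 cache_dir=None, model_config: ModelConfig | None = None
                 ) -> AblationTable:
    """Train and evaluate every (model, window length) cell with shared seeds.

    Within the grid every model sees the same windows, the same split and the
    same seed ladder, so cross-model comparisons are paired.  With
    ``cache_dir`` set, completed cells are written as JSON and skipped on
    re-run.  An infeasible cell (e.g. a window shorter than a receptive
    field) is recorded as failed and the grid continues.
    """
    from pathlib import Path

    table = AblationTable()
    F = data.schema.n_features
    n_classes = data.n_classes
    data_digest = _digest(data.features)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    for L in lengths:
        try:
            tr, va, te = prepare_windows(data, L, cfg.seed, fractions,
                                         normalization)
        except Exception as exc:  # infeasible length for the data
            for m in models:
                table.failures[(m, L)] = str(exc)
            continue
        for m in models:
            key = _cache_key(m, L, cfg, data_digest, cfg.seed)
            if cache is not None:
                f = cache / f"{key}.json"
                if f.exists():
                    payload = json.loads(f.read_text())
                    table.results[(m, L)] = MetricsReport(
                        confusion=np.array(payload["confusion"]),
                        **payload["metrics"])
                    log.info("cache hit for (%s, %d)", m, L)
                    continue
            try:
                mc = model_config or ModelConfig(L, F, n_classes, seed=cfg.seed)
                mc = replace(mc, window_length=L, feature_dim=F,
                             n_classes=n_classes, seed=cfg.seed)
                model = build_model(m, mc)
                model, hist = train_model(model, tr, va, cfg)
                rep = evaluate_model(model, te)
            except Exception as exc:
                log.warning("cell (%s, %d) failed: %s", m, L, exc)
                table.failures[(m, L)] = str(exc)
                continue
            table.results[(m, L)] = rep
            table.histories[(m, L)] = hist
            if cache is not None:
                payload = {"confusion": rep.confusion.tolist(),
                           "metrics": {k: v for k, v in rep.as_dict().items()}}
                (cache / f"{key}.json").write_text(json.dumps(payload))
    return table


def significance_vs_reference(table: AblationTable, reference: str = "PAR-Net",
                              metric: str = "accuracy", alpha: float = 0.05
                              ) -> pd.DataFrame:
    """Paired t-test of every other model against the reference across the
    window lengths of the grid (the paired-run unit)."""
    df = table.metric_frame(metric)
    if reference not in df.index:
        raise ValueError(f"reference model {reference!r} not in the grid")
    ref = df.loc[reference].to_numpy()
    rows = []
    for m in df.index:
        if m == reference:
            continue
        res = paired_t_test(ref, df.loc[m].to_numpy(), alpha=alpha)
        rows.append({"comparison": f"{reference} vs. {m}",
                     "t_statistic": res.t_statistic, "p_value": res.p_value,
                     "reject_null": res.reject_null})
    return pd.DataFrame(rows)


def export_history(hist: History, out_dir, stem: str = "history",
                   plot: bool = True) -> list:
    """Write the per-epoch curves as CSV (and accuracy/loss plots).

    Returns the list of files written; an empty history is an error and
    writes nothing."""
    from pathlib import Path

    if len(hist) == 0:
        raise ValueError("empty history: nothing to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    csv_path = out / f"{stem}.csv"
    hist.to_frame().to_csv(csv_path, index=False)
    files.append(csv_path)
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = hist.to_frame()
        for kind in ("acc", "loss"):
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(df["epoch"], df[f"train_{kind}"], label=f"train {kind}")
            if np.isfinite(df[f"val_{kind}"]).any():
                ax.plot(df["epoch"], df[f"val_{kind}"], label=f"val {kind}")
            ax.set_xlabel("epoch")
            ax.set_ylabel("accuracy" if kind == "acc" else "loss")
            ax.legend()
            fig.tight_layout()
            p = out / f"{stem}_{kind}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            files.append(p)
    return files


def shuffle_window_frames(ws: WindowSet, seed: int = 0) -> WindowSet:
    """Destroy frame order inside each window (a temporal-information probe)."""
    rng = np.random.default_rng(seed)
    data = ws.data.copy()
    for i in range(ws.n_windows):
        data[i] = data[i][rng.permutation(ws.window_length)]
    return WindowSet(data, ws.labels, ws.n_classes, ws.window_length)
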