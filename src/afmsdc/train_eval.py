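"""Training protocol and evaluation metrics for the detection networks.

Training follows the standard protocol for this family of models: Adam at
an initial learning rate of 1e-4 for up to 100 epochs, with early stopping
when the validation loss has not improved for 10 consecutive epochs; the
weights of the best-validation-loss epoch are restored.  Loss is softmax
cross-entropy.  Every segment is normalized to zero mean / unit variance
before entering the network.

Metrics: sensitivity TP/(TP+FN) and specificity TN/(TN+FP) for the binary
AF / non-AF task; per-class F1 = 2*diag / (row marginal + column marginal)
and their unweighted macro mean (F1all) for the four-class task
(Normal / AF / Other / Noise).  Zero denominators raise an explicit
undefined-metric error rather than silently returning 0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .ecgsim import EcgSegment
from .model import Network
from .nn import Adam, softmax_cross_entropy
from .specs import analyze_block

BINARY_CLASSES = ("non_af", "af")          # positive class "af" is index 1
FOUR_CLASSES = ("normal", "af", "other", "noise")


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given counts."""


# ---------------------------------------------------------------------------
# counts and metric formulas

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary tallies with AF as the positive class."""

    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    def __post_init__(self):
        if min(self.n_tp, self.n_tn, self.n_fp, self.n_fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n_tp + self.n_tn + self.n_fp + self.n_fn == 0:
            raise ValueError("confusion counts are all zero")


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(Se, Sp) = (TP/(TP+FN), TN/(TN+FP))."""
    if c.n_tp + c.n_fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive-class samples")
    if c.n_tn + c.n_fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative-class samples")
    return c.n_tp / (c.n_tp + c.n_fn), c.n_tn / (c.n_tn + c.n_fp)


class MultiClassCounts:
    """4x4 confusion tallies over (true, predicted) in Normal/AF/Other/Noise."""

    def __init__(self, matrix: np.ndarray, classes: tuple[str, ...] = FOUR_CLASSES):
        m = np.asarray(matrix)
        if m.shape != (len(classes), len(classes)):
            raise ValueError(f"expected a {len(classes)}x{len(classes)} matrix")
        if (m < 0).any():
            raise ValueError("counts must be non-negative")
        self.matrix = m.astype(np.int64)
        self.classes = classes

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         classes: tuple[str, ...] = FOUR_CLASSES) -> "MultiClassCounts":
        k = len(classes)
        m = np.zeros((k, k), dtype=np.int64)
        np.add.at(m, (np.asarray(y_true), np.asarray(y_pred)), 1)
        return cls(m, classes)

    def row_marginal(self, i: int) -> int:
        return int(self.matrix[i].sum())

    def col_marginal(self, i: int) -> int:
        return int(self.matrix[:, i].sum())


def f1_scores(m: MultiClassCounts) -> tuple[float, float, float, float, float]:
    """(F1n, F1a, F1o, F1p, F1all): per-class F1 and the unweighted macro mean.

    F1 for class X is ``2 * diag_X / (row marginal + column marginal)``.
    """
    per_class = []
    for i, name in enumerate(m.classes):
        denom = m.row_marginal(i) + m.col_marginal(i)
        if denom == 0:
            raise UndefinedMetricError(
                f"F1 undefined for class {name!r}: no true or predicted samples"
            )
        per_class.append(2.0 * m.matrix[i, i] / denom)
    macro = sum(per_class) / len(per_class)
    return (*per_class, macro)


# ---------------------------------------------------------------------------
# data preparation

def segments_to_arrays(
    segments: list[EcgSegment], classes: tuple[str, ...]
) -> tuple[np.ndarray | list[np.ndarray], np.ndarray]:
    """Per-segment z-normalized inputs and integer labels.

    Returns a dense (n, 1, L) array when all segments share one length,
    otherwise a list of (1, L_i) arrays for zero-padded batching.
    """
    if classes == BINARY_CLASSES:
        # binary AF / non-AF task: every non-AF rhythm label counts as non_af
        y = np.array([1 if s.label == "af" else 0 for s in segments], dtype=np.int64)
    else:
        idx = {c: i for i, c in enumerate(classes)}
        unknown = sorted({s.label for s in segments} - set(classes))
        if unknown:
            raise ValueError(f"segment labels {unknown} not in class set {classes}")
        y = np.array([idx[s.label] for s in segments], dtype=np.int64)
    xs = []
    for s in segments:
        x = np.asarray(s.samples, dtype=np.float32)
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 1e-8 else 1.0)
        xs.append(x[None, :])
    lengths = {x.shape[1] for x in xs}
    if len(lengths) == 1:
        return np.stack(xs), y
    return xs, y


def _batches(X, y, batch_size: int, rng: np.random.Generator | None):
    n = len(y)
    order = rng.permutation(n) if rng is not None else np.arange(n)
    for s in range(0, n, batch_size):
        sel = order[s : s + batch_size]
        if isinstance(X, np.ndarray):
            yield X[sel], y[sel]
        else:
            chunk = [X[i] for i in sel]
            L = max(c.shape[1] for c in chunk)
            xb = np.zeros((len(chunk), 1, L), dtype=np.float32)
            for j, c in enumerate(chunk):
                xb[j, :, : c.shape[1]] = c
            yield xb, y[sel]


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    """Optimization protocol: Adam, early stopping on validation loss."""

    learning_rate: float = 1e-4
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 64
    seed: int = 0
    loss: str = "cross_entropy"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.early_stop_patience < self.max_epochs):
            raise ValueError("early_stop_patience must lie in (0, max_epochs)")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


class EarlyStopping:
    """Stop after ``patience`` epochs without strict improvement of the best loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record this epoch's validation loss; True means stop now."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def train(
    model: Network,
    train_set: list[EcgSegment],
    val_set: list[EcgSegment],
    cfg: TrainConfig,
) -> tuple[Network, list[dict]]:
    """Fit under the standard protocol; returns (model at best epoch, history).

    History rows are ``{"epoch", "train_loss", "val_loss"}`` (1-based
    epochs).  Fully deterministic given ``cfg.seed`` and the model's own
    initialization seed.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    classes = BINARY_CLASSES if model.spec.n_classes == 2 else FOUR_CLASSES
    Xtr, ytr = segments_to_arrays(train_set, classes)
    Xva, yva = segments_to_arrays(val_set, classes)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    stopper = EarlyStopping(cfg.early_stop_patience)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_state = model.state_copy()
    for epoch in range(1, cfg.max_epochs + 1):
        losses = []
        for xb, yb in _batches(Xtr, ytr, cfg.batch_size, rng):
            logits = model.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(yb))
        train_loss = float(np.sum(losses) / len(ytr))
        val_losses = []
        for xb, yb in _batches(Xva, yva, cfg.batch_size, None):
            logits = model.forward(xb, training=False)
            loss, _ = softmax_cross_entropy(logits, yb)
            val_losses.append(loss * len(yb))
        val_loss = float(np.sum(val_losses) / len(yva))
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.state_copy()
        if stop:
            break
    model.load_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# evaluation

def accuracy(model: Network, segments: list[EcgSegment],
             batch_size: int = 64) -> float:
    classes = BINARY_CLASSES if model.spec.n_classes == 2 else FOUR_CLASSES
    X, y = segments_to_arrays(segments, classes)
    correct = 0
    for xb, yb in _batches(X, y, batch_size, None):
        correct += int((model.predict(xb) == yb).sum())
    return correct / len(y)


def evaluate(model: Network, test_set: list[EcgSegment], task: str = "binary",
             batch_size: int = 64) -> dict:
    """Score a trained model: argmax predictions -> counts -> metric report.

    The report carries the raw counts, the metrics for the task, and the
    static architecture summary of the model's block.
    """
    if task not in ("binary", "four_class"):
        raise ValueError(f"task must be 'binary' or 'four_class', got {task!r}")
    n_classes = 2 if task == "binary" else 4
    if model.spec.n_classes != n_classes:
        raise ValueError(
            f"model has {model.spec.n_classes} output classes but task {task!r} "
            f"needs {n_classes}"
        )
    classes = BINARY_CLASSES if task == "binary" else FOUR_CLASSES
    X, y = segments_to_arrays(test_set, classes)
    preds = []
    trues = []
    for xb, yb in _batches(X, y, batch_size, None):
        preds.append(model.predict(xb))
        trues.append(yb)
    y_pred = np.concatenate(preds)
    y_true = np.concatenate(trues)
    report: dict = {"task": task, "n_test": int(len(y_true))}
    if task == "binary":
        c = ConfusionCounts(
            n_tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            n_tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            n_fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            n_fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )
        se, sp = sensitivity_specificity(c)
        report["counts"] = asdict(c)
        report["metrics"] = {
            "sensitivity": se,
            "specificity": sp,
            "accuracy": float((y_true == y_pred).mean()),
        }
    else:
        m = MultiClassCounts.from_predictions(y_true, y_pred)
        f1n, f1a, f1o, f1p, f1all = f1_scores(m)
        report["counts"] = m.matrix.tolist()
        report["metrics"] = {
            "f1_normal": f1n, "f1_af": f1a, "f1_other": f1o,
            "f1_noise": f1p, "f1_macro": f1all,
            "accuracy": float((y_true == y_pred).mean()),
        }
    report["architecture"] = analyze_block(model.spec.block)
    return report
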