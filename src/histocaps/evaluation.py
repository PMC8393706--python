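"""Evaluation metrics, data splitting, k-fold harness and the training loop.

Per-class metrics follow the one-vs-rest convention: each class in turn is
the positive class, every other class negative, giving per-class TP/FP/TN/FN
from which sensitivity, specificity, precision, recall, accuracy and F1 are
computed.  ROC-AUC is likewise one-vs-rest, with the class-capsule norm as
the score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .losses import ThreefoldLossConfig, threefold_loss_and_grad
from .network import Adam, CapsNet

__all__ = [
    "ConfusionCounts",
    "TrainConfig",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "roc_auc_one_vs_rest",
    "split_dataset",
    "SPLIT_PROPORTIONS",
    "kfold_run",
    "train",
    "evaluate_model",
    "build_report",
    "write_report_csv",
    "write_report_json",
]

#: train/validation/test shares (18320 : 4580 : 2100 out of 25000)
SPLIT_PROPORTIONS = (18320 / 25000, 4580 / 25000, 2100 / 25000)

#: column names of the tabular per-class report
REPORT_COLUMNS = [
    "Class", "Accuracy", "Precision", "Recall", "f1-Score",
    "Sensitivity", "Specificity", "AUC", "#Test Images",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the published setup)."""

    learning_rate: float = 0.0001
    epochs: int = 50
    batch_size: int = 32
    optimizer: str = "adam"
    kfold: int = 5
    seed: int = 1485

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training hyperparameters")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class MetricsReport:
    class_names: list[str]
    per_class: list[dict]          # one dict per class with metric values
    overall_accuracy: float
    macro_f1: float


# ---------------------------------------------------------------------------
# confusion matrix and derived metrics
# ---------------------------------------------------------------------------

def confusion_matrix(
    predictions, labels, n_classes: int
) -> tuple[np.ndarray, list[ConfusionCounts]]:
    """Row = true class, column = predicted class, plus per-class one-vs-rest
    counts."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if np.any(labels < 0) or np.any(labels >= n_classes) or np.any(
        predictions < 0
    ) or np.any(predictions >= n_classes):
        raise ValueError(f"labels/predictions must lie in [0, {n_classes})")
    matrix = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(matrix, (labels, predictions), 1)
    total = matrix.sum()
    counts = []
    for c in range(n_classes):
        tp = int(matrix[c, c])
        fn = int(matrix[c].sum() - tp)
        fp = int(matrix[:, c].sum() - tp)
        tn = int(total - tp - fn - fp)
        counts.append(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    return matrix, counts


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def per_class_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision, recall, accuracy and F1 from
    one-vs-rest counts.  Recall is identically sensitivity."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    metrics = {
        "sensitivity": sensitivity,
        "specificity": _ratio(tn, tn + fp, "specificity"),
        "precision": _ratio(tp, tp + fp, "precision"),
        "recall": sensitivity,
        "accuracy": (tp + tn) / counts.total,
        "f1": _ratio(tp, tp + 0.5 * (fp + fn), "f1"),
    }
    return metrics


def roc_auc_one_vs_rest(scores: np.ndarray, labels) -> np.ndarray:
    """Per-class trapezoidal AUC with tie averaging.

    ``scores`` is (n_samples, n_classes) — e.g. class-capsule norms; class c's
    AUC uses column c as the score for the binary task "class c vs rest".
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_classes = scores.shape[1]
    aucs = np.empty(n_classes)
    for c in range(n_classes):
        positives = labels == c
        if positives.all() or not positives.any():
            raise ValueError(
                f"AUC undefined for class {c}: needs both positives and negatives"
            )
        aucs[c] = roc_auc_score(positives, scores[:, c])
    return aucs


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(labels, seed: int, stratify: bool = True):
    """Partition indices into train/val/test with shares 18320:4580:2100.

    ``labels`` is the per-item class label array (its length defines the
    dataset size).  The train share is rounded to the nearest integer, the
    validation share likewise, and the test set takes the remainder, so the
    three parts are disjoint and exhaustive.  The same index partition is
    meant to be applied to the original and pre-processed image sets.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items to split")
    n_train = int(np.floor(SPLIT_PROPORTIONS[0] * n + 0.5))
    n_val = int(np.floor(SPLIT_PROPORTIONS[1] * n + 0.5))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    idx = np.arange(n)

    def _strat(lab):
        # sklearn needs >= 2 members per class to stratify a split
        if not stratify:
            return None
        _, counts = np.unique(lab, return_counts=True)
        return lab if counts.min() >= 2 else None

    train_idx, rest = train_test_split(
        idx, train_size=n_train, random_state=seed, stratify=_strat(labels)
    )
    val_idx, test_idx = train_test_split(
        rest, train_size=n_val, random_state=seed + 1, stratify=_strat(labels[rest])
    )
    return np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)


def kfold_run(labels, k: int, evaluate_fold, seed: int = 1485) -> dict:
    """Stratified k-fold harness.

    ``evaluate_fold(train_idx, test_idx) -> accuracy`` trains a fresh model
    on k-1 folds and scores the held-out fold.  Returns the per-fold
    accuracies and their mean.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, class_counts = np.unique(labels, return_counts=True)
    if k > class_counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({class_counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        accuracies.append(float(evaluate_fold(train_idx, test_idx)))
    return {
        "fold_accuracies": accuracies,
        "mean_accuracy": float(np.mean(accuracies)),
        "k": k,
    }


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes)
    return eye[np.asarray(labels, dtype=int)]


def _prf_macro(predictions, labels, n_classes) -> tuple[float, float, float]:
    _, counts = confusion_matrix(predictions, labels, n_classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per = [per_class_metrics(c) for c in counts]
    p = float(np.mean([m["precision"] for m in per]))
    r = float(np.mean([m["recall"] for m in per]))
    f = float(np.mean([m["f1"] for m in per]))
    return p, r, f


def train(
    model: CapsNet,
    datasets: dict,
    config: TrainConfig,
    loss_config: ThreefoldLossConfig | None = None,
    freeze_weights: bool = False,
    verbose: bool = False,
) -> dict:
    """Mini-batch Adam training of the capsule model under the threefold loss.

    ``datasets`` holds arrays ``x_orig``, ``x_prep``, ``y`` for training and
    optionally ``val_x_orig``, ``val_x_prep``, ``val_y``.  Training metrics
    are accumulated from the batches as they are seen (running training
    accuracy); validation metrics come from a full pass after each epoch.
    Returns a history dict of per-epoch lists; deterministic for a fixed
    config seed.  Raises ``RuntimeError`` on a non-finite loss.
    """
    loss_config = loss_config or ThreefoldLossConfig()
    x_orig = np.asarray(datasets["x_orig"])
    x_prep = np.asarray(datasets["x_prep"])
    y = np.asarray(datasets["y"], dtype=int)
    n = len(y)
    n_classes = model.spec.class_capsules
    targets = _one_hot(y, n_classes)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model, lr=config.learning_rate)
    history: dict[str, list] = {
        k: []
        for k in (
            "loss", "accuracy", "precision", "recall", "f1",
            "val_loss", "val_accuracy", "val_precision", "val_recall", "val_f1",
        )
    }
    has_val = "val_y" in datasets and datasets["val_y"] is not None

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        preds = np.empty(n, dtype=int)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            v = model.forward(x_orig[sel], x_prep[sel])
            norms = np.linalg.norm(v, axis=-1)
            preds[sel] = np.argmax(norms, axis=-1)
            loss, dv = threefold_loss_and_grad(v, targets[sel], loss_config)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}"
                )
            epoch_loss += loss * len(sel)
            if not freeze_weights:
                model.backward(dv)
                optimizer.step()
        p, r, f = _prf_macro(preds, y, n_classes)
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(float(np.mean(preds == y)))
        history["precision"].append(p)
        history["recall"].append(r)
        history["f1"].append(f)
        if has_val:
            vl, va, vp, vr, vf = _eval_pass(
                model, datasets["val_x_orig"], datasets["val_x_prep"],
                np.asarray(datasets["val_y"], dtype=int), config.batch_size,
                loss_config,
            )
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
            history["val_precision"].append(vp)
            history["val_recall"].append(vr)
            history["val_f1"].append(vf)
        if verbose:
            msg = (
                f"epoch {epoch + 1}/{config.epochs} "
                f"loss={history['loss'][-1]:.4f} acc={history['accuracy'][-1]:.3f}"
            )
            if has_val:
                msg += f" val_acc={history['val_accuracy'][-1]:.3f}"
            print(msg)
    return history


def _eval_pass(model, x_orig, x_prep, y, batch_size, loss_config):
    n = len(y)
    n_classes = model.spec.class_capsules
    targets = _one_hot(y, n_classes)
    total_loss = 0.0
    preds = np.empty(n, dtype=int)
    for start in range(0, n, batch_size):
        sel = slice(start, start + batch_size)
        v = model.forward(np.asarray(x_orig)[sel], np.asarray(x_prep)[sel])
        preds[sel] = np.argmax(np.linalg.norm(v, axis=-1), axis=-1)
        loss, _ = threefold_loss_and_grad(v, targets[sel], loss_config)
        total_loss += loss * (preds[sel].shape[0])
    p, r, f = _prf_macro(preds, y, n_classes)
    return total_loss / n, float(np.mean(preds == y)), p, r, f


def evaluate_model(
    model: CapsNet, x_orig, x_prep, y, class_names=None, batch_size: int = 32
) -> MetricsReport:
    """Full per-class report (confusion counts, Eqs-style metrics, AUC)."""
    y = np.asarray(y, dtype=int)
    n_classes = model.spec.class_capsules
    scores = []
    for start in range(0, len(y), batch_size):
        sel = slice(start, start + batch_size)
        v = model.forward(np.asarray(x_orig)[sel], np.asarray(x_prep)[sel])
        scores.append(np.linalg.norm(v, axis=-1))
    scores = np.concatenate(scores, axis=0)
    preds = np.argmax(scores, axis=-1)
    return build_report(preds, scores, y, n_classes, class_names)


def build_report(predictions, scores, labels, n_classes, class_names=None) -> MetricsReport:
    """Assemble a MetricsReport from predictions and per-class scores."""
    labels = np.asarray(labels, dtype=int)
    if class_names is None:
        class_names = [f"class{c}" for c in range(n_classes)]
    matrix, counts = confusion_matrix(predictions, labels, n_classes)
    try:
        aucs = roc_auc_one_vs_rest(scores, labels)
    except ValueError:
        aucs = np.full(n_classes, np.nan)
    per_class = []
    for c, cc in enumerate(counts):
        m = per_class_metrics(cc)
        m["auc"] = float(aucs[c])
        m["n_test"] = int(np.sum(labels == c))
        m["class"] = class_names[c]
        per_class.append(m)
    overall = float(np.trace(matrix) / matrix.sum())
    macro_f1 = float(np.mean([m["f1"] for m in per_class]))
    return MetricsReport(
        class_names=list(class_names),
        per_class=per_class,
        overall_accuracy=overall,
        macro_f1=macro_f1,
    )


def _report_rows(report: MetricsReport) -> list[dict]:
    rows = []
    for m in report.per_class:
        rows.append(
            {
                "Class": m["class"],
                "Accuracy": m["accuracy"],
                "Precision": m["precision"],
                "Recall": m["recall"],
                "f1-Score": m["f1"],
                "Sensitivity": m["sensitivity"],
                "Specificity": m["specificity"],
                "AUC": m["auc"],
                "#Test Images": m["n_test"],
            }
        )
    return rows


def write_report_csv(path, report: MetricsReport) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
        writer.writeheader()
        writer.writerows(_report_rows(report))


def write_report_json(path, report: MetricsReport) -> None:
    payload = {
        "per_class": _report_rows(report),
        "overall_accuracy": report.overall_accuracy,
        "macro_f1": report.macro_f1,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
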