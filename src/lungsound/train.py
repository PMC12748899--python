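"""Training loop, subject-wise cross-validation, and evaluation metrics.

Cross-validation is stratified at subject granularity: all recordings of
one subject land in a single fold, so no identity leaks between the
train/validation/test roles of any fold.  Training uses Adam on shuffled
mini-batches of 32 with cross-entropy + L2 loss and early stopping on
validation loss.  Metrics are one-vs-rest per class (sensitivity,
specificity, precision, recall, F1, accuracy, AUC) with unweighted macro
averages; overall accuracy is trace/total of the confusion matrix.
Undefined ratios (0/0) are reported as NaN, never coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model.network import (AdamOptimizer, ModelConfig, clip_gradients,
                            clone_params, fusion_backward, fusion_forward,
                            init_parameters, loss_cross_entropy_l2)

__all__ = ["TrainConfig", "FoldSplit", "MetricsReport", "kfold_split",
           "train_model", "grid_search_lr", "confusion_matrix",
           "metrics_from_confusion", "roc_curve_auc", "evaluate_model"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    lr_grid: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)
    batch_size: int = 32
    epochs: int = 50
    lam: float = 0.0001
    patience: int = 5
    clip_norm: float = 5.0   # global gradient-norm clip; 0 disables
    class_weights: tuple[float, ...] | None = None  # per-class loss weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class FoldSplit:
    fold_of_row: np.ndarray   # fold index per manifest row
    k: int

    def roles(self, fold: int):
        """(train_idx, val_idx, test_idx) for one fold; validation is the
        next fold in cyclic order and is used for early stopping."""
        if not 0 <= fold < self.k:
            raise ValueError("fold out of range")
        test = np.flatnonzero(self.fold_of_row == fold)
        val = np.flatnonzero(self.fold_of_row == (fold + 1) % self.k)
        train = np.flatnonzero(
            (self.fold_of_row != fold) & (self.fold_of_row != (fold + 1) % self.k))
        return train, val, test


def kfold_split(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldSplit:
    """Class-stratified subject-wise k-fold assignment."""
    subjects = manifest.groupby("subject_id")["label"].first()
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    fold_of_subject: dict[str, int] = {}
    offset = 0
    for label in sorted(subjects.unique()):
        ids = sorted(subjects.index[subjects == label])
        rng.shuffle(ids)
        for j, sid in enumerate(ids):
            fold_of_subject[sid] = (j + offset) % k
        offset += len(ids)  # stagger classes so fold sizes stay balanced
    fold_of_row = manifest["subject_id"].map(fold_of_subject).to_numpy()
    return FoldSplit(fold_of_row=fold_of_row, k=k)


def _forward_batches(params, config, X, batch=64):
    out = []
    for s in range(0, len(X), batch):
        out.append(fusion_forward(X[s: s + batch], config, params))
    return np.concatenate(out, axis=0)


def _eval_loss_acc(params, config, X, y, lam):
    probs = _forward_batches(params, config, X)
    onehot = np.eye(config.n_classes)[y]
    loss = loss_cross_entropy_l2(probs, onehot, params, lam)
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc, probs


def train_model(X_train, y_train, X_val, y_val,
                config: TrainConfig = TrainConfig(),
                model_config: ModelConfig | None = None,
                verbose: bool = False):
    """Train the fusion model; returns (best parameters, history)."""
    X_train = np.asarray(X_train, dtype=np.float32)
    y_train = np.asarray(y_train)
    if len(X_train) == 0:
        raise ValueError("empty training set")
    if model_config is None:
        model_config = ModelConfig(n_classes=int(y_train.max()) + 1)
    params = init_parameters(model_config, seed=config.seed)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    if config.epochs == 0:
        return params, history

    opt = AdamOptimizer(params, lr=config.learning_rate, lam=config.lam)
    rng = np.random.default_rng(config.seed)
    eye = np.eye(model_config.n_classes, dtype=np.float32)
    cw = None
    if config.class_weights is not None:
        cw = np.asarray(config.class_weights, dtype=np.float32)
        if cw.size != model_config.n_classes:
            raise ValueError("class_weights length must equal n_classes")
    best_val = np.inf
    best_params = clone_params(params)
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_train))
        losses, correct = [], 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s: s + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            probs, cache = fusion_forward(xb, model_config, params,
                                          return_cache=True)
            onehot = eye[yb]
            losses.append(loss_cross_entropy_l2(probs, onehot, params, config.lam))
            correct += int((probs.argmax(axis=1) == yb).sum())
            if cw is None:
                dlogits = ((probs - onehot) / len(idx)).astype(np.float32)
            else:
                w = cw[yb]
                dlogits = ((probs - onehot) * w[:, None] / w.sum()).astype(
                    np.float32)
            grads = fusion_backward(cache, dlogits, model_config, params)
            clip_gradients(grads, config.clip_norm)
            opt.step(params, grads)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / len(order))
        val_loss, val_acc, _ = _eval_loss_acc(params, model_config, X_val, y_val,
                                              config.lam)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if verbose:
            print(f"epoch {epoch + 1}: train_loss={history['train_loss'][-1]:.4f} "
                  f"train_acc={history['train_acc'][-1]:.3f} "
                  f"val_loss={val_loss:.4f} val_acc={val_acc:.3f}")
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = clone_params(params)
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return best_params, history


def grid_search_lr(X_train, y_train, X_val, y_val,
                   grid=(0.1, 0.01, 0.001, 0.0001),
                   config: TrainConfig = TrainConfig(),
                   model_config: ModelConfig | None = None,
                   epochs: int | None = None):
    """Select the learning rate with the lowest final validation loss
    (ties go to the smaller rate).  Returns (alpha, {alpha: val_loss})."""
    if not grid:
        raise ValueError("empty learning-rate grid")
    results = {}
    for lr in grid:
        cfg = TrainConfig(learning_rate=lr, lr_grid=tuple(grid),
                          batch_size=config.batch_size,
                          epochs=config.epochs if epochs is None else epochs,
                          lam=config.lam, patience=config.patience,
                          clip_norm=config.clip_norm, seed=config.seed)
        _, history = train_model(X_train, y_train, X_val, y_val, cfg, model_config)
        results[lr] = history["val_loss"][-1] if history["val_loss"] else np.inf
    best = min(sorted(results, key=lambda a: a), key=lambda a: (results[a], a))
    return best, results


# ------------------------------------------------------------- metrics ----

@dataclass
class MetricsReport:
    labels: list[str]
    per_class: dict            # label -> {sensitivity, specificity, ...}
    macro: dict                # unweighted averages over defined classes
    overall_accuracy: float
    confusion: np.ndarray      # rows actual, columns predicted

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class).T


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (0/0); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_confusion(cm: np.ndarray, labels: list[str],
                           aucs: dict | None = None) -> MetricsReport:
    """One-vs-rest metrics per class plus unweighted macro averages."""
    cm = np.asarray(cm)
    total = cm.sum()
    per_class = {}
    for i, label in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if cm[i].sum() == 0:
            warnings.warn(f"class {label!r} absent from the test set; "
                          "excluded from macro averages", stacklevel=2)
        sens = _safe_div(tp, tp + fn, f"{label} sensitivity")
        prec = _safe_div(tp, tp + fp, f"{label} precision")
        f1 = (2 * prec * sens / (prec + sens)
              if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
              else float("nan"))
        per_class[label] = {
            "sensitivity": sens,
            "specificity": _safe_div(tn, tn + fp, f"{label} specificity"),
            "precision": prec,
            "recall": sens,
            "f1": f1,
            "accuracy": _safe_div(tp + tn, total, f"{label} accuracy"),
        }
        if aucs is not None:
            per_class[label]["auc"] = aucs.get(label, float("nan"))
    keys = next(iter(per_class.values())).keys() if per_class else []
    macro = {}
    for key in keys:
        vals = [per_class[c][key] for c in labels
                if np.isfinite(per_class[c][key])]
        macro[key] = float(np.mean(vals)) if vals else float("nan")
    overall = _safe_div(np.trace(cm), total, "overall accuracy")
    return MetricsReport(labels=list(labels), per_class=per_class, macro=macro,
                         overall_accuracy=overall, confusion=cm)


def roc_curve_auc(scores, labels):
    """Binary ROC by threshold sweep over unique scores.

    Tied scores step simultaneously, making the trapezoidal AUC equal to
    the pairwise concordance P(s+ > s-) + 0.5 P(s+ = s-).
    Returns (fpr, tpr, thresholds, auc).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # group ties: advance TP and FP together across equal scores
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)) , sorted_scores.size - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = distinct + 1 - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def evaluate_model(params, model_config: ModelConfig,
                   X_frames, frame_recording, y_recording,
                   class_labels: list[str], batch: int = 64):
    """Segment probabilities aggregated to recordings by mean, then argmax.

    ``frame_recording`` maps each frame row to its recording index;
    ``y_recording`` holds one integer label per recording.
    Returns (MetricsReport, recording probability matrix, predictions).
    """
    X_frames = np.asarray(X_frames, dtype=np.float32)
    y_recording = np.asarray(y_recording)
    if len(y_recording) == 0:
        raise ValueError("empty test set")
    frame_probs = _forward_batches(params, model_config, X_frames, batch)
    n_rec = len(y_recording)
    probs = np.zeros((n_rec, model_config.n_classes))
    counts = np.zeros(n_rec)
    np.add.at(probs, frame_recording, frame_probs)
    np.add.at(counts, frame_recording, 1)
    probs /= counts[:, None]
    preds = probs.argmax(axis=1)
    cm = confusion_matrix(y_recording, preds, model_config.n_classes)
    aucs = {}
    for i, label in enumerate(class_labels):
        binary = (y_recording == i).astype(int)
        if 0 < binary.sum() < binary.size:
            aucs[label] = roc_curve_auc(probs[:, i], binary)[3]
        else:
            aucs[label] = float("nan")
    report = metrics_from_confusion(cm, class_labels, aucs=aucs)
    return report, probs, preds
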