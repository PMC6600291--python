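"""Evaluation protocol: 80/20 split, accuracy, confusion matrix, ROC/AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .io_formats import DatasetManifest


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_dataset(
    manifest: DatasetManifest, spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive, seeded train/test id partition.

    With ``stratified`` each class keeps the train fraction within one
    sample; a class with fewer than 2 samples is rejected.
    """
    ids = manifest.ids
    labels = manifest.labels
    if spec.stratified:
        _, counts = np.unique(labels, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("stratified split needs >= 2 samples per class")
    train_ids, test_ids = train_test_split(
        ids,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        shuffle=True,
        stratify=labels if spec.stratified else None,
    )
    return list(train_ids), list(test_ids)


def overall_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(y_true == y_pred))


def confusion_matrix_percent(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 6
) -> np.ndarray:
    """Row-normalized percentage confusion matrix (row = true class 1..l).

    Each row with at least one sample sums to 100; the diagonal holds the
    per-class accuracies.  Rows for classes absent from ``y_true`` are zero.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes))
    for t, p in zip(y_true, y_pred):
        counts[t - 1, p - 1] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return pct


def roc_auc_per_class(
    scores: np.ndarray, y_true: np.ndarray, n_classes: int = 6
) -> dict[int, dict[str, object]]:
    """One-vs-rest ROC curve and trapezoidal AUC per class.

    ``scores`` is (n, n_classes) of decision scores; classes labelled
    1..n_classes.  A class absent from ``y_true`` gets ``auc=None`` (flagged,
    never reported as 0).  Thresholds sweep the unique scores; ties move
    (FPR, TPR) simultaneously, as in the standard ROC construction.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, int)
    if scores.ndim != 2 or scores.shape[1] != n_classes:
        raise ValueError(f"scores must be n x {n_classes}")
    if scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores/labels length mismatch")
    out: dict[int, dict[str, object]] = {}
    for c in range(1, n_classes + 1):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[c] = {"fpr": None, "tpr": None, "auc": None}
            continue
        s = scores[:, c - 1]
        order = np.argsort(-s, kind="stable")
        s_sorted, pos_sorted = s[order], pos[order]
        # group ties: step once per distinct threshold
        distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
        tp = np.cumsum(pos_sorted)[distinct]
        fp = np.cumsum(~pos_sorted)[distinct]
        tpr = np.r_[0.0, tp / n_pos]
        fpr = np.r_[0.0, fp / n_neg]
        auc = float(np.trapezoid(tpr, fpr))
        out[c] = {"fpr": fpr, "tpr": tpr, "auc": auc}
    return out


def evaluation_report(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None,
    n_classes: int = 6,
) -> dict:
    """Bundle accuracy, per-class accuracy, confusion matrix and AUCs."""
    cm = confusion_matrix_percent(y_true, y_pred, n_classes)
    report = {
        "overall_accuracy": overall_accuracy(y_true, y_pred),
        "per_class_accuracy": {c: float(cm[c - 1, c - 1]) for c in range(1, n_classes + 1)},
        "confusion_matrix_percent": cm.tolist(),
    }
    if scores is not None:
        rocs = roc_auc_per_class(scores, y_true, n_classes)
        report["auc"] = {c: rocs[c]["auc"] for c in rocs}
    return report
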