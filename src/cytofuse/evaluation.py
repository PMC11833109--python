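"""Stratified cross-validated evaluation of the CAE classifiers.

Performance is summarized per fold by the confusion matrix, balanced
accuracy (mean of per-class recalls — robust to the class imbalance a
top-10% gate produces) and macro-averaged F1 ("balanced F1"), then
aggregated across folds as mean +/- SD.  Fold splitting and the metric
arithmetic are delegated to scikit-learn; this module owns the
orchestration (fresh model per fold, strict train/test separation,
latent export).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import balanced_accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

from . import cae_models
from .config import TrainingConfig
from .errors import InputError


@dataclass
class FoldMetrics:
    fold_index: int
    confusion: np.ndarray            # rows = true class, cols = predicted
    balanced_accuracy: float
    f1_per_class: np.ndarray
    balanced_f1: float               # macro-averaged F1


@dataclass
class CVResult:
    folds: list[FoldMetrics]
    mean_balanced_accuracy: float
    sd_balanced_accuracy: float
    mean_balanced_f1: float
    sd_balanced_f1: float
    latents: list[np.ndarray] = field(default_factory=list)
    latent_labels: list[np.ndarray] = field(default_factory=list)
    histories: list[list[dict]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "sd_balanced_accuracy": self.sd_balanced_accuracy,
            "mean_balanced_f1": self.mean_balanced_f1,
            "sd_balanced_f1": self.sd_balanced_f1,
            "folds": [
                {
                    "fold_index": f.fold_index,
                    "confusion": f.confusion.tolist(),
                    "balanced_accuracy": f.balanced_accuracy,
                    "f1_per_class": f.f1_per_class.tolist(),
                    "balanced_f1": f.balanced_f1,
                }
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            n_cls = len(self.folds[0].f1_per_class) if self.folds else 0
            writer.writerow(["fold", "balanced_accuracy", "balanced_f1"]
                            + [f"f1_class_{c}" for c in range(n_cls)])
            for f in self.folds:
                writer.writerow([f.fold_index, f.balanced_accuracy,
                                 f.balanced_f1] + list(f.f1_per_class))


def stratified_kfold(labels: np.ndarray, k: int = 5,
                     seed: int = 0) -> list[np.ndarray]:
    """Disjoint test-index sets of a stratified k-fold split.

    The folds partition all indices; per-class counts across folds
    differ by at most one.  Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise InputError(
            f"class {small} has {counts.min()} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)),
                                                  labels)]


def compute_metrics(true: np.ndarray, pred: np.ndarray,
                    fold_index: int = 0,
                    labels: list[int] | None = None) -> FoldMetrics:
    """Confusion matrix, balanced accuracy and macro F1 for one fold."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise InputError("true and pred must have equal length")
    if labels is None:
        labels = sorted(set(true.tolist()) | set(pred.tolist()))
    conf = confusion_matrix(true, pred, labels=labels)
    bal_acc = balanced_accuracy_score(true, pred)
    f1 = f1_score(true, pred, labels=labels, average=None, zero_division=0)
    return FoldMetrics(
        fold_index=fold_index,
        confusion=conf,
        balanced_accuracy=float(bal_acc),
        f1_per_class=np.asarray(f1, dtype=float),
        balanced_f1=float(np.mean(f1)),
    )


def run_cv_experiment(dataset: cae_models.CellImageDataset,
                      model_builder, config: TrainingConfig,
                      k: int = 5, seed: int = 0) -> CVResult:
    """Train a fresh model per fold and evaluate on the held-out fold.

    ``model_builder(config)`` must return an untrained classifier whose
    ``train``/``predict`` operate on ``dataset``'s modalities.  Test
    indices are never part of that fold's training split (asserted).
    Per-fold latent matrices of the test cells are collected for
    visualization.
    """
    if dataset.labels is None:
        raise InputError("run_cv_experiment requires a labeled dataset")
    n = len(dataset)
    folds = stratified_kfold(dataset.labels, k=k, seed=seed)
    result_folds: list[FoldMetrics] = []
    latents: list[np.ndarray] = []
    latent_labels: list[np.ndarray] = []
    histories: list[list[dict]] = []
    classes = sorted(np.unique(dataset.labels).tolist())
    for fold_index, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        assert not set(train_idx) & set(test_idx), "train/test leak"

        model = model_builder(config)
        model, history = cae_models.train(model, dataset.subset(train_idx),
                                          config)
        test = dataset.subset(test_idx)
        probs = cae_models.predict(model, test.x_3d, test.x_2d)
        pred = probs.argmax(axis=1)
        result_folds.append(compute_metrics(test.labels, pred,
                                            fold_index, labels=classes))
        latents.append(cae_models.encode_latent(model, test.x_3d, test.x_2d))
        latent_labels.append(test.labels.copy())
        histories.append(history)

    bals = np.array([f.balanced_accuracy for f in result_folds])
    f1s = np.array([f.balanced_f1 for f in result_folds])
    return CVResult(
        folds=result_folds,
        mean_balanced_accuracy=float(bals.mean()),
        sd_balanced_accuracy=float(bals.std(ddof=1)) if k > 1 else 0.0,
        mean_balanced_f1=float(f1s.mean()),
        sd_balanced_f1=float(f1s.std(ddof=1)) if k > 1 else 0.0,
        latents=latents,
        latent_labels=latent_labels,
        histories=histories,
    )
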