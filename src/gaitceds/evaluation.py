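"""Held-out evaluation metrics and penultimate-feature extraction.

Four summary metrics: accuracy, macro-averaged recall, macro-averaged
F1, and macro one-vs-rest AUC computed from the softmax score matrix.
Classes absent from the test set are excluded from the macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    precision_recall_fscore_support,
    roc_auc_score,
)

from . import nn


@dataclass
class ClassRow:
    label: int
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    f1: float
    auc: float
    per_class: list[ClassRow]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "per_class": [vars(r) for r in self.per_class],
        }


def metrics_from_scores(scores: np.ndarray, y_true: np.ndarray) -> MetricsReport:
    """Compute the report from a softmax score matrix and true labels."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty test set")
    y_pred = scores.argmax(axis=1)
    present = np.unique(y_true)
    accuracy = float((y_pred == y_true).mean())
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=present, zero_division=0
    )
    per_class = [
        ClassRow(int(c), float(p), float(r), float(f), int(s))
        for c, p, r, f, s in zip(present, prec, rec, f1, support)
    ]
    aucs = []
    for c in present:
        pos = y_true == c
        if pos.all():
            continue  # one-class test set: AUC undefined for this label
        aucs.append(roc_auc_score(pos, scores[:, c]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    return MetricsReport(
        accuracy=accuracy,
        recall=float(rec.mean()),
        f1=float(f1.mean()),
        auc=auc,
        per_class=per_class,
    )


def evaluate(net: nn.Network, x: np.ndarray, y: np.ndarray) -> MetricsReport:
    """Evaluate a trained network on held-out samples."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    head_width = net.children[-1].p["b"].shape[0]
    y = np.asarray(y)
    if y.min() < 0 or y.max() >= head_width:
        raise ValueError(
            f"labels span [{y.min()}, {y.max()}] but the head has {head_width} outputs"
        )
    return metrics_from_scores(net.predict_proba(x), y)


def extract_features(net: nn.Network, x: np.ndarray) -> np.ndarray:
    """Flattened penultimate activations, one row per sample.

    Width 2048 for the plain or squeeze-excitation models, 1792 when the
    context-encoding attention's valid-padding depthwise stage narrows
    the map.  Suitable input for external embedding tools (e.g. t-SNE).
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    return net.features(x)


def intra_inter_distances(features: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mean intra-class and inter-class pairwise Euclidean distances.

    A discriminative embedding has intra < inter; this is the assertable
    form of a class-separation scatter plot.
    """
    y = np.asarray(y)
    d2 = ((features[:, None, :] - features[None, :, :]) ** 2).sum(-1) ** 0.5
    same = y[:, None] == y[None, :]
    iu = np.triu_indices(len(y), k=1)
    same_u = same[iu]
    return float(d2[iu][same_u].mean()), float(d2[iu][~same_u].mean())
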