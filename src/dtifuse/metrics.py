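"""Ranking and classification metrics for interaction prediction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


class MetricError(ValueError):
    """Metric undefined for the given labels (e.g. a single class)."""


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise MetricError("both classes must be present to compute a ranking metric")
    return labels


def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUROC; ties contribute 1/2."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision)."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores)))


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of correct hard calls at the threshold."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    return float(((scores >= threshold).astype(int) == labels).mean())


@dataclass
class MetricReport:
    auroc: float
    aupr: float
    acc: float
    threshold: float = 0.5

    def __post_init__(self):
        for name in ("auroc", "aupr", "acc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MetricError(f"{name} = {v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {"auroc": self.auroc, "aupr": self.aupr, "acc": self.acc,
                "threshold": self.threshold}


def evaluate_scores(scores, labels, threshold: float = 0.5) -> MetricReport:
    return MetricReport(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        acc=accuracy(scores, labels, threshold),
        threshold=threshold,
    )
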