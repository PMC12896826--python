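"""Evaluation metrics: confusion matrices, per-class sensitivity/precision,
Cohen's kappa, and multi-run aggregation.

Accuracy is the multiclass trace/total form; sensitivity and precision are
per-class one-vs-rest TP/(TP+FN) and TP/(TP+FP).  A per-class one-vs-rest
accuracy (TP+TN over all frames) is also reported because per-behavior
"accuracy" in collar-behavior studies usually means exactly that; it is
named ``ovr_accuracy`` to keep it distinct from the overall accuracy.
Undefined ratios (zero denominators) are reported as None, never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true labels, columns predicted labels."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def confusion(model, X, y, class_names: Sequence[str] | None = None) -> ConfusionMatrix:
    """Confusion matrix of ``model.predict`` on (X, y).

    Prediction ties are broken toward the lowest class index (argmax
    semantics), keeping runs bitwise reproducible.
    """
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    pred = model.predict(np.asarray(X, dtype=float))
    labels = getattr(model, "classes_", np.unique(y))
    names = list(class_names) if class_names is not None else [str(c) for c in labels]
    counts = _sk_confusion(y, pred, labels=labels)
    return ConfusionMatrix(counts, names)


@dataclass
class MetricsReport:
    """Single-run metrics derived from one confusion matrix."""

    accuracy: float
    per_class: dict[str, dict]
    n: int

    def to_json(self) -> str:
        return json.dumps(
            {"accuracy": self.accuracy, "per_class": self.per_class, "n": self.n},
            indent=2,
        )


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class sensitivity/precision and one-vs-rest accuracy."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(counts)) / total
    per_class = {}
    for i, name in enumerate(cm.class_names):
        tp = int(counts[i, i])
        fn = int(counts[i].sum() - tp)
        fp = int(counts[:, i].sum() - tp)
        tn = total - tp - fn - fp
        per_class[name] = {
            "sensitivity": tp / (tp + fn) if tp + fn > 0 else None,
            "precision": tp / (tp + fp) if tp + fp > 0 else None,
            "ovr_accuracy": (tp + tn) / total,
            "support": tp + fn,
        }
    return MetricsReport(accuracy=accuracy, per_class=per_class, n=total)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    When both raters are constant and identical (p_e = 1) the agreement is
    perfect by construction and kappa is defined as 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1-D and equal length")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    cats, ai = np.unique(np.concatenate([a, b]), return_inverse=True)
    ai, bi = ai[: len(a)], ai[len(a):]
    n = len(a)
    po = float(np.mean(ai == bi))
    pa = np.bincount(ai, minlength=len(cats)) / n
    pb = np.bincount(bi, minlength=len(cats)) / n
    pe = float(pa @ pb)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


@dataclass
class AggregateReport:
    """Mean +/- std over repeated randomized runs."""

    runs: list[MetricsReport]
    seeds: list[int]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.runs])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=0))

    def summary(self) -> str:
        return f"{100 * self.mean_accuracy:.2f}% (±{100 * self.std_accuracy:.2f}%)"

    def to_json(self) -> str:
        return json.dumps(
            {
                "seeds": list(self.seeds),
                "runs": [json.loads(r.to_json()) for r in self.runs],
                "mean_accuracy": self.mean_accuracy,
                "std_accuracy": self.std_accuracy,
                "summary": self.summary(),
            },
            indent=2,
        )


def repeat_experiment(
    run: Callable[[int], MetricsReport], seeds: Sequence[int]
) -> AggregateReport:
    """Re-run a seeded experiment once per seed and aggregate.

    ``run`` must perform the full randomized pipeline (re-split, re-train,
    evaluate) for a given seed and return a MetricsReport.
    """
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    return AggregateReport(runs=[run(int(s)) for s in seeds],
                           seeds=[int(s) for s in seeds])
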