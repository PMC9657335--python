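"""Confusion-matrix metrics, k-fold cross-validation and comparison reports.

Five metrics, all reported in percent: accuracy, sensitivity (recall of
the positive class), specificity, precision, and F-measure (harmonic mean
of precision and sensitivity).  The positive class is post-lesion
(class 1): detecting the lesion effect is the clinical question.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .preprocessing import SegmentDataset

__all__ = [
    "METRIC_NAMES",
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "metrics",
    "stratified_folds",
    "kfold_cv",
    "compare_report",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f_measure")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = post-lesion = 1."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions, truth) -> ConfusionMatrix:
    """Count tp/fp/tn/fn with class 1 positive."""
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    for arr, name in ((predictions, "predictions"), (truth, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((predictions == 1) & (truth == 1))),
        fp=int(np.sum((predictions == 1) & (truth == 0))),
        tn=int(np.sum((predictions == 0) & (truth == 0))),
        fn=int(np.sum((predictions == 0) & (truth == 1))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator): reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The five metrics of a confusion matrix, in percent."""
    accuracy = _ratio(cm.tp + cm.tn, cm.n, "accuracy")
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    f_measure = _ratio(2 * precision * sensitivity, precision + sensitivity, "f_measure")
    return {
        "accuracy": 100.0 * accuracy,
        "sensitivity": 100.0 * sensitivity,
        "specificity": 100.0 * specificity,
        "precision": 100.0 * precision,
        "f_measure": 100.0 * f_measure,
    }


@dataclass
class EvaluationReport:
    """Per-fold metrics plus their mean and standard deviation."""

    classifier: str
    per_fold: list = field(default_factory=list)  # list of metric dicts
    side: str = "all"

    @property
    def mean(self) -> dict[str, float]:
        return {
            name: float(np.mean([f[name] for f in self.per_fold]))
            for name in METRIC_NAMES
        }

    @property
    def std(self) -> dict[str, float]:
        return {
            name: float(np.std([f[name] for f in self.per_fold]))
            for name in METRIC_NAMES
        }

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, fold in enumerate(self.per_fold):
            rows.append({"classifier": self.classifier, "side": self.side,
                         "fold": i, **fold})
        rows.append({"classifier": self.classifier, "side": self.side,
                     "fold": "mean", **self.mean})
        return pd.DataFrame(rows)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint, exhaustive, label-stratified fold index arrays."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        if len(rows) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
        perm = rng.permutation(rows)
        for i, chunk in enumerate(np.array_split(perm, k)):
            folds[i].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def kfold_cv(
    fit_predict: Callable[[SegmentDataset, SegmentDataset], np.ndarray],
    dataset: SegmentDataset,
    k: int = 5,
    seed: int = 0,
    classifier_name: str = "classifier",
    side: str = "all",
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a classifier recipe.

    ``fit_predict(train, test)`` must return hard 0/1 predictions for the
    test rows.  Each fold serves once as the test set; metrics are computed
    per fold and summarized as mean +/- std.
    """
    folds = stratified_folds(dataset.labels, k, seed)
    all_idx = np.arange(len(dataset))
    report = EvaluationReport(classifier=classifier_name, side=side)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        preds = fit_predict(dataset.subset(train_idx), dataset.subset(test_idx))
        cm = confusion(preds, dataset.labels[test_idx])
        report.per_fold.append(metrics(cm))
    return report


def compare_report(
    reports: Sequence[EvaluationReport], out_dir, plot: bool = True
) -> dict[str, Path]:
    """Write a side-by-side metric table (CSV) and a grouped bar plot."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = [r for r in reports if r is not None]
    outputs: dict[str, Path] = {}

    if len(reports) == 1:
        note = f"single classifier report: {reports[0].classifier}"
    else:
        note = ""
    table = pd.concat([r.to_dataframe() for r in reports], ignore_index=True)
    csv_path = out_dir / "comparison.csv"
    table.to_csv(csv_path, index=False)
    outputs["table"] = csv_path
    if note:
        (out_dir / "comparison_note.txt").write_text(note + "\n")

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        width = 0.8 / max(len(reports), 1)
        xs = np.arange(len(METRIC_NAMES))
        for j, rep in enumerate(reports):
            vals = [rep.mean[name] for name in METRIC_NAMES]
            ax.bar(xs + j * width, vals, width, label=rep.classifier)
        ax.set_xticks(xs + width * (len(reports) - 1) / 2)
        ax.set_xticklabels([n.replace("_", "-") for n in METRIC_NAMES])
        ax.set_ylabel("percent")
        ax.set_ylim(0, 105)
        ax.legend()
        ax.set_title("Classifier evaluation metrics")
        fig.tight_layout()
        png_path = out_dir / "comparison.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        outputs["plot"] = png_path
    return outputs
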