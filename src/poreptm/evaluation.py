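"""Evaluation protocols: confusion matrices, accuracy-versus-selection curves,
mixture assignment and the chronological train/validation split.

Confusion matrices follow the convention of the reference experiments: columns
are the actual peptides of the test set, rows the peptides the model assigned
them to, normalized per actual class so every column sums to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "SelectionCurve",
    "MixtureResult",
    "confusion_matrix",
    "accuracy_vs_selection",
    "mean_selection_curve",
    "assign_mixture",
    "chronological_split",
    "match_events_to_truth",
]


def _labels_of(predictions):
    """Accept a Predictions object or a plain sequence of label strings."""
    if hasattr(predictions, "predicted_label"):
        return np.asarray(predictions.predicted_label)
    return np.asarray(list(predictions))


@dataclass
class ConfusionMatrix:
    """Row = assigned class, column = actual class; percentages per column."""

    class_labels: tuple[str, ...]
    counts: np.ndarray  # (K, K) ints, rows assigned / columns actual
    percent: np.ndarray  # column-normalized to 100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.percent,
            index=pd.Index(self.class_labels, name="assigned"),
            columns=pd.Index(self.class_labels, name="actual"),
        )


def confusion_matrix(predictions, true_labels, class_labels=None) -> ConfusionMatrix:
    """Tally counts then normalize per actual class (columns sum to 100%)."""
    pred = _labels_of(predictions)
    true = np.asarray(list(true_labels))
    if pred.shape[0] != true.shape[0]:
        raise ValueError("predictions and true labels must align")
    if class_labels is None:
        if hasattr(predictions, "class_labels"):
            class_labels = tuple(predictions.class_labels)
        else:
            class_labels = tuple(sorted(set(true) | set(pred)))
    idx = {name: k for k, name in enumerate(class_labels)}
    for lab in np.concatenate([pred, true]):
        if lab not in idx:
            raise ValueError(f"label {lab!r} outside the model classes {class_labels}")
    K = len(class_labels)
    counts = np.zeros((K, K), dtype=int)
    for p, t in zip(pred, true):
        counts[idx[p], idx[t]] += 1
    col_sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(col_sums > 0, 100.0 * counts / col_sums, 0.0)
    return ConfusionMatrix(tuple(class_labels), counts, percent)


@dataclass
class SelectionCurve:
    """Averaged accuracy at each selection percentage (descending grid)."""

    selection_pct: np.ndarray
    accuracy: np.ndarray
    n_repeats: int = 1

    def __post_init__(self):
        self.selection_pct = np.asarray(self.selection_pct, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any((self.selection_pct <= 0) | (self.selection_pct > 100)):
            raise ValueError("selection percentages must lie in (0, 100]")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"selection_pct": self.selection_pct, "accuracy": self.accuracy}
        )


def accuracy_vs_selection(
    predictions, true_labels, grid=(100.0, 75.0, 50.0, 25.0)
) -> SelectionCurve:
    """Accuracy on the confidence-selected subset for each grid percentage."""
    from .classifier import select_by_confidence

    true = np.asarray(list(true_labels))
    grid = sorted((float(g) for g in grid), reverse=True)
    accs = []
    for pct in grid:
        subset, _ = select_by_confidence(predictions, pct)
        correct = subset.predicted_label == true[subset.indices]
        accs.append(float(np.mean(correct)))
    return SelectionCurve(np.array(grid), np.array(accs), n_repeats=1)


def mean_selection_curve(runs, grid=(100.0, 75.0, 50.0, 25.0)) -> SelectionCurve:
    """Average the curve over independent (predictions, true_labels) repeats."""
    curves = [accuracy_vs_selection(p, t, grid) for p, t in runs]
    acc = np.mean([c.accuracy for c in curves], axis=0)
    return SelectionCurve(curves[0].selection_pct, acc, n_repeats=len(curves))


@dataclass
class MixtureResult:
    """Per-class assignment percentages of a mixture run, with SE over repeats.

    Percentages are relative to all events; events removed by the selection
    threshold appear in ``unassigned_pct`` so that the total is always 100.
    """

    class_labels: tuple[str, ...]
    assignment_pct: dict
    assignment_se: dict
    unassigned_pct: float
    unassigned_se: float
    n_repeats: int

    def __post_init__(self):
        total = sum(self.assignment_pct.values()) + self.unassigned_pct
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"assignment percentages sum to {total}, expected 100")


def assign_mixture(prediction_runs, selection_pct: float = 100.0) -> MixtureResult:
    """Assignment percentages of selected events, averaged over repeats.

    ``prediction_runs`` is one Predictions object or a list of them (one per
    independent repeat); the model must have been trained on pure-class data
    only (holdout protocol — the mixture never appears in training).
    """
    from .classifier import select_by_confidence

    if not isinstance(prediction_runs, (list, tuple)):
        prediction_runs = [prediction_runs]
    class_labels = tuple(prediction_runs[0].class_labels)
    per_run = {name: [] for name in class_labels}
    unassigned = []
    for pred in prediction_runs:
        n = len(pred)
        subset, _ = select_by_confidence(pred, selection_pct)
        labels = subset.predicted_label
        for name in class_labels:
            per_run[name].append(100.0 * np.sum(labels == name) / n)
        unassigned.append(100.0 * (n - len(subset)) / n)

    def se(xs):
        xs = np.asarray(xs, dtype=float)
        return float(xs.std(ddof=1) / np.sqrt(len(xs))) if len(xs) > 1 else 0.0

    return MixtureResult(
        class_labels=class_labels,
        assignment_pct={k: float(np.mean(v)) for k, v in per_run.items()},
        assignment_se={k: se(v) for k, v in per_run.items()},
        unassigned_pct=float(np.mean(unassigned)),
        unassigned_se=se(unassigned),
        n_repeats=len(prediction_runs),
    )


def chronological_split(items, frac: float = 0.75):
    """Split by acquisition order (never randomly): first ``frac`` trains.

    Sizes are floor(frac*N) and the remainder.  Fewer than 4 items cannot be
    split meaningfully.
    """
    n = len(items)
    if n < 4:
        raise ValueError(f"need at least 4 events to split, got {n}")
    n_train = int(np.floor(frac * n))
    return items[:n_train], items[n_train:]


def match_events_to_truth(events, truth):
    """Match detected events to annotated ones by sample-interval overlap.

    Returns (pairs, recall, precision) where ``pairs`` maps detected-event
    index -> truth index of the annotation with maximal overlap.  Each truth
    event is matched at most once (greedy, in time order).
    """
    pairs: dict[int, int] = {}
    used: set[int] = set()
    truth_list = list(truth)
    cursor = 0
    for d_idx, ev in enumerate(events):
        while cursor < len(truth_list) and truth_list[cursor].end_index <= ev.start_index:
            cursor += 1
        best, best_ov = None, 0
        j = cursor
        while j < len(truth_list) and truth_list[j].start_index < ev.end_index:
            tr = truth_list[j]
            ov = min(ev.end_index, tr.end_index) - max(ev.start_index, tr.start_index)
            if ov > best_ov and j not in used:
                best, best_ov = j, ov
            j += 1
        if best is not None:
            pairs[d_idx] = best
            used.add(best)
    recall = len(pairs) / len(truth_list) if truth_list else 1.0
    precision = len(pairs) / len(events) if events else 1.0
    return pairs, recall, precision
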