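"""Event classification with a rejection option.

Two sequence networks read the (time, relative current) local-extrema sequence
of each blockade event:

* the **classifier** — an LSTM with state size 128 and no activation function
  on the state readout, followed by 6 fully connected hidden layers of size
  256 with ReLU and a softmax output over the peptide classes;
* the **assessor** — a scaled-down reader (LSTM state 32, 3 hidden layers of
  size 64 with tanh, sigmoid output of size 1) that predicts whether the
  classifier's prediction is correct.

Both are trained together on a 3-part loss: the classification cross-entropy,
the binary cross-entropy between the assessment score and the actual
prediction validity, and a reinforcement term — the classification
cross-entropy scaled per event by the assessment score.  At evaluation time a
threshold on the assessment score is translated into a selection percentage,
trading coverage for accuracy.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import LSTM, MLP, Adam, global_norm_clip, sigmoid, softmax

__all__ = [
    "ExtremaSequence",
    "ClassifierConfig",
    "LossParts",
    "Predictions",
    "ClassifierBundle",
    "prepare_sequences",
    "three_part_loss",
    "train",
    "predict",
    "select_by_confidence",
]

_EPS = 1e-12


@dataclass
class ExtremaSequence:
    """Rescaled (t, c) extrema pairs for one event; model input."""

    values: np.ndarray  # (T, 2) float32, already rescaled
    truncated: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32).reshape(-1, 2)
        if self.values.shape[0] < 1:
            raise ValueError("sequence must contain at least one (t, c) pair")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rescaled features must be finite")
        t = self.values[:, 0]
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("extrema times must be strictly increasing")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class ClassifierConfig:
    """Architecture and training hyper-parameters.

    The network widths/depths are the reference architecture and should not
    normally be changed; the training hyper-parameters (optimizer Adam,
    lr 1e-3, batch 256, up to 50 epochs with early stopping) are package
    defaults.  ``rescale`` holds the fixed (f_t, f_c) feature factors: times
    in seconds are scaled to a millisecond-like range and percentages to unit
    scale, which shortens training.
    """

    n_classes: int = 8
    lstm_size: int = 128
    mlp_width: int = 256
    mlp_depth: int = 6
    assessor_lstm_size: int = 32
    assessor_width: int = 64
    assessor_depth: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 50
    patience: int = 10
    max_len: int = 64
    rescale: tuple[float, float] = (1e3, 1e-2)
    seed: int = 0
    grad_clip: float = 5.0
    reinforce_through_assessor: bool = False
    class_weighting: bool = False
    min_events_per_class: int = 100

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass(frozen=True)
class LossParts:
    """The three loss components and their sum."""

    cls: float
    assess: float
    reinforce: float
    total: float = field(init=False)

    def __post_init__(self):
        if min(self.cls, self.assess, self.reinforce) < 0:
            raise ValueError("loss parts must be non-negative")
        object.__setattr__(self, "total", self.cls + self.assess + self.reinforce)


def prepare_sequences(
    events,
    rescale: tuple[float, float] = (1e3, 1e-2),
    max_len: int = 64,
) -> list[ExtremaSequence]:
    """Turn feature-populated events into rescaled model input sequences.

    Each extremum (t, c) becomes (t*f_t, c*f_c).  Sequences longer than
    ``max_len`` keep their first ``max_len`` extrema (tail truncation) and are
    flagged; events without extrema receive the single sentinel pair
    (0, rel_current_pct), rescaled the same way, so that every event still
    carries its amplitude information.
    """
    f_t, f_c = rescale
    out = []
    for ev in events:
        if ev.extrema:
            arr = np.asarray(ev.extrema, dtype=np.float64)
        else:
            arr = np.array([[0.0, ev.rel_current_pct]], dtype=np.float64)
        truncated = arr.shape[0] > max_len
        if truncated:
            arr = arr[:max_len]
        arr = arr * np.array([f_t, f_c])
        out.append(ExtremaSequence(arr.astype(np.float32), truncated=truncated))
    return out


def three_part_loss(probs, assessment_scores, true_labels) -> LossParts:
    """Compute the 3-part loss over a batch.

    * ``cls``: mean classification cross-entropy -log p_true;
    * ``assess``: mean binary cross-entropy between the assessment score and
      the actual prediction validity v (1 if argmax equals the true label);
    * ``reinforce``: mean of assessment_score * (-log p_true).

    Probabilities of the true class at 0 are clamped to 1e-12 with a warning.
    """
    probs = np.asarray(probs, dtype=np.float64)
    a = np.asarray(assessment_scores, dtype=np.float64)
    y = np.asarray(true_labels, dtype=int)
    if probs.ndim != 2 or probs.shape[0] != a.shape[0] or probs.shape[0] != y.shape[0]:
        raise ValueError("batch-aligned inputs required")
    p_true = probs[np.arange(len(y)), y]
    if np.any(p_true <= 0.0):
        warnings.warn("true-class probability of 0 clamped to 1e-12", RuntimeWarning)
    p_true = np.clip(p_true, _EPS, 1.0)
    ce = -np.log(p_true)
    v = (np.argmax(probs, axis=1) == y).astype(np.float64)
    a_c = np.clip(a, _EPS, 1.0 - _EPS)
    bce = -(v * np.log(a_c) + (1.0 - v) * np.log(1.0 - a_c))
    return LossParts(
        cls=float(ce.mean()),
        assess=float(bce.mean()),
        reinforce=float((a * ce).mean()),
    )


@dataclass
class Predictions:
    """Per-event class probabilities, argmax predictions and assessment scores."""

    probs: np.ndarray  # (N, K)
    assessment: np.ndarray  # (N,)
    class_labels: tuple[str, ...]
    indices: np.ndarray | None = None  # positions in the originating event list

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.assessment = np.asarray(self.assessment, dtype=np.float64)
        if self.indices is None:
            self.indices = np.arange(self.probs.shape[0])

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def predicted_index(self) -> np.ndarray:
        return np.argmax(self.probs, axis=1)

    @property
    def predicted_label(self) -> np.ndarray:
        return np.asarray(self.class_labels)[self.predicted_index]

    def take(self, idx) -> "Predictions":
        idx = np.asarray(idx, dtype=int)
        return Predictions(
            self.probs[idx], self.assessment[idx], self.class_labels, self.indices[idx]
        )


@dataclass
class ClassifierBundle:
    """Trained classifier + assessor with their preprocessing constants."""

    config: ClassifierConfig
    class_labels: tuple[str, ...]
    clf_lstm: LSTM
    clf_mlp: MLP
    ass_lstm: LSTM
    ass_mlp: MLP

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for prefix, mod in self._modules().items():
            for key, value in mod.params.items():
                arrays[f"{prefix}.{key}"] = value
        np.savez(directory / "weights.npz", **arrays)
        cfg = asdict(self.config)
        cfg["class_labels"] = list(self.class_labels)
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, directory) -> "ClassifierBundle":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        class_labels = tuple(cfg.pop("class_labels"))
        cfg["rescale"] = tuple(cfg["rescale"])
        config = ClassifierConfig(**cfg)
        bundle = _build_bundle(config, class_labels)
        with np.load(directory / "weights.npz") as data:
            for prefix, mod in bundle._modules().items():
                for key in mod.params:
                    mod.params[key][...] = data[f"{prefix}.{key}"]
        return bundle

    def _modules(self) -> dict:
        return {
            "clf_lstm": self.clf_lstm,
            "clf_mlp": self.clf_mlp,
            "ass_lstm": self.ass_lstm,
            "ass_mlp": self.ass_mlp,
        }


def _build_bundle(config: ClassifierConfig, class_labels: tuple[str, ...]) -> ClassifierBundle:
    rng = np.random.default_rng(config.seed)
    c = config
    clf_lstm = LSTM(2, c.lstm_size, rng)
    clf_mlp = MLP(
        [c.lstm_size] + [c.mlp_width] * c.mlp_depth + [c.n_classes], "relu", rng
    )
    ass_lstm = LSTM(2, c.assessor_lstm_size, rng)
    ass_mlp = MLP(
        [c.assessor_lstm_size] + [c.assessor_width] * c.assessor_depth + [1], "tanh", rng
    )
    return ClassifierBundle(c, class_labels, clf_lstm, clf_mlp, ass_lstm, ass_mlp)


def _pad_batch(seqs: list[ExtremaSequence], pad_to: int | None = None):
    lengths = [len(s) for s in seqs]
    T = pad_to or max(lengths)
    X = np.zeros((len(seqs), T, 2), dtype=np.float32)
    mask = np.zeros((len(seqs), T), dtype=np.float32)
    for row, s in enumerate(seqs):
        X[row, : len(s)] = s.values
        mask[row, : len(s)] = 1.0
    return X, mask


def _forward(bundle: ClassifierBundle, X, mask, cache=False):
    h_c = bundle.clf_lstm.forward(X, mask, cache=cache)
    logits = bundle.clf_mlp.forward(h_c, cache=cache)
    probs = softmax(logits.astype(np.float64))
    h_a = bundle.ass_lstm.forward(X, mask, cache=cache)
    a_logit = bundle.ass_mlp.forward(h_a, cache=cache)[:, 0]
    a = sigmoid(a_logit.astype(np.float64))
    return probs, a


def train(
    sequences: list[ExtremaSequence],
    labels,
    config: ClassifierConfig,
    class_labels: tuple[str, ...] | None = None,
    split: float = 0.75,
) -> tuple[ClassifierBundle, list[dict]]:
    """Jointly train the classifier and assessor on the 3-part loss.

    Events are split chronologically — the first (in time) ``split`` fraction
    trains, the remainder validates.  The validity label that supervises the
    assessor is recomputed each step from the classifier's current argmax.
    Training stops early when the validation total loss has not improved for
    ``config.patience`` epochs; the best-validation weights are returned.
    The returned log holds one dict per epoch with all loss parts and the
    validation accuracy.  A fixed seed makes the run reproducible.
    """
    labels = list(labels)
    if len(labels) != len(sequences):
        raise ValueError("labels and sequences must align")
    if class_labels is None:
        class_labels = tuple(sorted(set(labels)))
    if len(class_labels) != config.n_classes:
        raise ValueError(
            f"config.n_classes = {config.n_classes} but {len(class_labels)} classes present"
        )
    label_to_idx = {name: k for k, name in enumerate(class_labels)}
    y = np.array([label_to_idx[l] for l in labels], dtype=int)

    n = len(sequences)
    n_train = int(np.floor(split * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"cannot split {n} events into train/validation")
    train_seqs, val_seqs = sequences[:n_train], sequences[n_train:]
    y_train, y_val = y[:n_train], y[n_train:]
    counts = np.bincount(y_train, minlength=config.n_classes)
    if counts.min() < config.min_events_per_class:
        raise ValueError(
            f"class {class_labels[int(np.argmin(counts))]!r} has only {counts.min()} "
            f"training events (< {config.min_events_per_class})"
        )
    class_w = None
    if config.class_weighting:
        class_w = counts.sum() / (len(counts) * np.maximum(counts, 1))

    bundle = _build_bundle(config, tuple(class_labels))
    rng = np.random.default_rng(config.seed + 1)
    modules = list(bundle._modules().values())
    optimizer = Adam(modules, lr=config.learning_rate)
    X_val, mask_val = _pad_batch(val_seqs)

    log: list[dict] = []
    best = {"val_total": np.inf, "epoch": -1, "params": None}
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for lo in range(0, n_train, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            X, mask = _pad_batch([train_seqs[i] for i in idx])
            yb = y_train[idx]
            B = len(idx)
            probs, a = _forward(bundle, X, mask, cache=True)
            parts = three_part_loss(probs, a, yb)
            if not np.isfinite(parts.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: cls={parts.cls} "
                    f"assess={parts.assess} reinforce={parts.reinforce}"
                )
            epoch_losses.append(parts)

            onehot = np.zeros_like(probs)
            onehot[np.arange(B), yb] = 1.0
            w = np.ones(B)
            if class_w is not None:
                w = class_w[yb]
            # classification + reinforcement gradient; the reinforcement term
            # scales each event's cross-entropy by its assessment score
            dlogits = (probs - onehot) * (w * (1.0 + a))[:, None] / B
            # assessor gradient from the validity cross-entropy
            v = (np.argmax(probs, axis=1) == yb).astype(np.float64)
            da_logit = (a - v) / B
            if config.reinforce_through_assessor:
                ce = -np.log(np.clip(probs[np.arange(B), yb], _EPS, 1.0))
                da_logit = da_logit + ce * a * (1.0 - a) / B
            dh_c = bundle.clf_mlp.backward(dlogits.astype(np.float32))
            bundle.clf_lstm.backward(dh_c)
            dh_a = bundle.ass_mlp.backward(da_logit.astype(np.float32)[:, None])
            bundle.ass_lstm.backward(dh_a)
            global_norm_clip(modules, config.grad_clip)
            optimizer.step()

        probs_v, a_v = _forward(bundle, X_val, mask_val)
        val_parts = three_part_loss(probs_v, a_v, y_val)
        val_acc = float(np.mean(np.argmax(probs_v, axis=1) == y_val))
        log.append(
            {
                "epoch": epoch,
                "train_cls": float(np.mean([p.cls for p in epoch_losses])),
                "train_assess": float(np.mean([p.assess for p in epoch_losses])),
                "train_reinforce": float(np.mean([p.reinforce for p in epoch_losses])),
                "train_total": float(np.mean([p.total for p in epoch_losses])),
                "val_total": val_parts.total,
                "val_accuracy": val_acc,
            }
        )
        if val_parts.total < best["val_total"]:
            best = {
                "val_total": val_parts.total,
                "epoch": epoch,
                "params": [copy.deepcopy(m.params) for m in modules],
            }
        elif epoch - best["epoch"] >= config.patience:
            break

    if best["params"] is not None:
        for mod, saved in zip(modules, best["params"]):
            for key in mod.params:
                mod.params[key][...] = saved[key]
    return bundle, log


def predict(bundle: ClassifierBundle, sequences: list[ExtremaSequence],
            batch_size: int = 512) -> Predictions:
    """Deterministic forward pass; probabilities are normalized softmax outputs."""
    if sequences and sequences[0].values.shape[1] != 2:
        raise ValueError("sequences must hold (t, c) pairs")
    probs_all, a_all = [], []
    for lo in range(0, len(sequences), batch_size):
        X, mask = _pad_batch(sequences[lo : lo + batch_size])
        probs, a = _forward(bundle, X, mask)
        probs_all.append(probs)
        a_all.append(a)
    if not probs_all:
        return Predictions(
            np.zeros((0, bundle.config.n_classes)), np.zeros(0), bundle.class_labels
        )
    return Predictions(np.vstack(probs_all), np.concatenate(a_all), bundle.class_labels)


def select_by_confidence(predictions: Predictions, selection_pct: float):
    """Keep the highest-assessment fraction of events.

    Returns the ceil(selection_pct/100 * N) events with the highest assessment
    score (stable — ties are broken by event order) together with the score
    threshold actually used, i.e. the selection percentage translated into a
    confidence threshold on the evaluation set itself.
    """
    if not 0 < selection_pct <= 100:
        raise ValueError(f"selection_pct must lie in (0, 100], got {selection_pct}")
    n = len(predictions)
    if n == 0:
        raise ValueError("empty prediction set")
    k = int(np.ceil(selection_pct / 100.0 * n))
    order = np.argsort(-predictions.assessment, kind="stable")
    chosen = np.sort(order[:k])  # preserve event order in the subset
    threshold = float(predictions.assessment[order[k - 1]])
    return predictions.take(chosen), threshold
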