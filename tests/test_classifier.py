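"""Sequence preparation, the 3-part loss, joint training and selection."""

import math

import numpy as np
import pytest

from poreptm import (
    predict,
    prepare_sequences,
    select_by_confidence,
    three_part_loss,
)
from poreptm.classifier import ClassifierBundle, ExtremaSequence, Predictions
from poreptm.event_detection import BlockadeEvent


def _event_with_extrema(extrema, rel=9.0):
    ev = BlockadeEvent(0, 10, np.zeros(10))
    ev.rel_current_pct = rel
    ev.extrema = extrema
    return ev


# --- prepare_sequences -----------------------------------------------------


def test_rescale_arithmetic():
    seqs = prepare_sequences([_event_with_extrema([(0.001, 9.0)])], rescale=(1000, 0.01))
    np.testing.assert_allclose(seqs[0].values, [[1.0, 0.09]])


def test_identity_rescale():
    extrema = [(0.001, 9.0), (0.002, 17.0)]
    seqs = prepare_sequences([_event_with_extrema(extrema)], rescale=(1, 1))
    np.testing.assert_allclose(seqs[0].values, extrema)


def test_inverse_rescale_recovers_originals():
    rng = np.random.default_rng(2)
    events = []
    for _ in range(20):
        times = np.sort(rng.uniform(0, 0.005, rng.integers(1, 10)))
        times += np.arange(len(times)) * 1e-6  # enforce strict increase
        events.append(_event_with_extrema([(t, rng.uniform(5, 35)) for t in times]))
    seqs = prepare_sequences(events, rescale=(1e3, 1e-2))
    for ev, seq in zip(events, seqs):
        decoded = seq.values.astype(np.float64) * np.array([1e-3, 1e2])
        np.testing.assert_allclose(decoded, np.asarray(ev.extrema), rtol=1e-5)


def test_tail_truncation_flagged():
    extrema = [(i * 1e-4, 10.0 + (i % 2)) for i in range(50)]
    seqs = prepare_sequences([_event_with_extrema(extrema)], max_len=8)
    assert len(seqs[0]) == 8
    assert seqs[0].truncated
    # the head of the sequence is kept, the tail dropped
    np.testing.assert_allclose(seqs[0].values[0, 0], 0.0)


def test_empty_extrema_sentinel_carries_amplitude():
    seqs = prepare_sequences([_event_with_extrema([], rel=9.0)], rescale=(1e3, 1e-2))
    np.testing.assert_allclose(seqs[0].values, [[0.0, 0.09]])


# --- three-part loss -------------------------------------------------------


def test_perfect_prediction_zero_loss():
    probs = np.eye(3)[[0, 1, 2]]
    parts = three_part_loss(probs, np.ones(3), [0, 1, 2])
    assert parts.cls == pytest.approx(0.0, abs=1e-9)
    assert parts.assess == pytest.approx(0.0, abs=1e-6)
    assert parts.reinforce == pytest.approx(0.0, abs=1e-9)
    assert parts.total == parts.cls + parts.assess + parts.reinforce


def test_uniform_probabilities_give_ln8():
    probs = np.full((5, 8), 1 / 8)
    parts = three_part_loss(probs, np.full(5, 0.5), np.zeros(5, dtype=int))
    assert parts.cls == pytest.approx(math.log(8), rel=1e-12)


def _loss_oracle(probs, scores, labels):
    """Independent per-sample scalar computation."""
    n, k = len(labels), len(probs[0])
    ce, bce, rein = [], [], []
    for i in range(n):
        p = max(probs[i][labels[i]], 1e-12)
        ce.append(-math.log(p))
        argmax = max(range(k), key=lambda j: probs[i][j])
        v = 1.0 if argmax == labels[i] else 0.0
        a = min(max(scores[i], 1e-12), 1 - 1e-12)
        bce.append(-(v * math.log(a) + (1 - v) * math.log(1 - a)))
        rein.append(scores[i] * ce[i])
    return sum(ce) / n, sum(bce) / n, sum(rein) / n


def test_loss_matches_scalar_oracle():
    rng = np.random.default_rng(9)
    for _ in range(5):
        logits = rng.normal(size=(16, 8))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        scores = rng.uniform(0, 1, 16)
        labels = rng.integers(0, 8, 16)
        parts = three_part_loss(probs, scores, labels)
        o_cls, o_ass, o_rein = _loss_oracle(probs.tolist(), scores.tolist(), labels.tolist())
        assert parts.cls == pytest.approx(o_cls, abs=1e-9)
        assert parts.assess == pytest.approx(o_ass, abs=1e-9)
        assert parts.reinforce == pytest.approx(o_rein, abs=1e-9)


def test_zero_probability_clamped_with_warning():
    probs = np.array([[0.0, 1.0]])
    with pytest.warns(RuntimeWarning, match="clamped"):
        parts = three_part_loss(probs, [0.5], [0])
    assert np.isfinite(parts.total)


# --- training and prediction ----------------------------------------------


def test_training_loss_decreases(two_class_model):
    log = two_class_model["log"]
    assert log[-1]["train_total"] < log[0]["train_total"]


def test_separable_two_class_validation_accuracy(two_class_model):
    """On a threshold-separable task the network reaches the oracle regime."""
    acc = np.mean(
        two_class_model["val_pred"].predicted_label == two_class_model["val_labels"]
    )
    assert acc >= 0.97


def test_prediction_agrees_with_threshold_oracle(two_class_model):
    """A mid-gap relative-current threshold is a perfect rule on this task."""
    events = two_class_model["val_events"]
    oracle = np.where(
        np.array([ev.rel_current_pct for ev in events]) < 18.75, "wt", "pY125"
    )
    agreement = np.mean(two_class_model["val_pred"].predicted_label == oracle)
    assert agreement >= 0.97


def test_predict_deterministic_and_normalized(two_class_model):
    bundle = two_class_model["bundle"]
    seqs = prepare_sequences(two_class_model["val_events"][:64], bundle.config.rescale, 32)
    p1 = predict(bundle, seqs)
    p2 = predict(bundle, seqs)
    np.testing.assert_array_equal(p1.probs, p2.probs)
    np.testing.assert_allclose(p1.probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all((p1.assessment >= 0) & (p1.assessment <= 1))


def test_prediction_invariant_to_padding(two_class_model):
    """Batching (hence padding length) must not change the outputs."""
    bundle = two_class_model["bundle"]
    seqs = prepare_sequences(two_class_model["val_events"][:50], bundle.config.rescale, 32)
    whole = predict(bundle, seqs, batch_size=50)
    chunked = predict(bundle, seqs, batch_size=7)
    np.testing.assert_allclose(whole.probs, chunked.probs, atol=1e-5)
    np.testing.assert_allclose(whole.assessment, chunked.assessment, atol=1e-5)


def test_bundle_save_load_round_trip(tmp_path, two_class_model):
    bundle = two_class_model["bundle"]
    seqs = prepare_sequences(two_class_model["val_events"][:20], bundle.config.rescale, 32)
    bundle.save(tmp_path / "model")
    back = ClassifierBundle.load(tmp_path / "model")
    np.testing.assert_array_equal(
        predict(bundle, seqs).probs, predict(back, seqs).probs
    )
    assert back.class_labels == bundle.class_labels


# --- selection -------------------------------------------------------------


def _toy_predictions(scores):
    n = len(scores)
    probs = np.tile([0.8, 0.2], (n, 1))
    return Predictions(probs, np.asarray(scores, dtype=float), ("a", "b"))


def test_full_selection_is_identity():
    pred = _toy_predictions(np.linspace(0, 1, 10))
    subset, _ = select_by_confidence(pred, 100)
    assert len(subset) == 10
    np.testing.assert_array_equal(subset.indices, np.arange(10))


def test_top_half_selected_by_score():
    scores = [0.1, 0.9, 0.3, 0.8, 0.2, 0.7, 0.4, 0.6, 0.05, 0.5]
    subset, threshold = select_by_confidence(_toy_predictions(scores), 50)
    assert len(subset) == 5
    assert sorted(subset.indices.tolist()) == [1, 3, 5, 7, 9]
    assert threshold == 0.5


def test_selection_size_is_ceiling():
    pred = _toy_predictions(np.linspace(0, 1, 7))
    subset, _ = select_by_confidence(pred, 50)
    assert len(subset) == int(np.ceil(0.5 * 7))


def test_selection_ties_stable():
    subset, _ = select_by_confidence(_toy_predictions([0.5, 0.5, 0.5, 0.5]), 50)
    np.testing.assert_array_equal(subset.indices, [0, 1])


def test_empty_selection_rejected():
    with pytest.raises(ValueError, match="empty"):
        select_by_confidence(_toy_predictions([]), 50)
    with pytest.raises(ValueError, match="selection_pct"):
        select_by_confidence(_toy_predictions([0.5]), 0)


def test_sequence_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        ExtremaSequence(np.array([[0.2, 1.0], [0.1, 2.0]]))
    with pytest.raises(ValueError, match="finite"):
        ExtremaSequence(np.array([[0.0, np.inf]]))
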