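"""Shared fixtures: simulated datasets and trained models.

Training fixtures are session-scoped so the expensive joint-training runs are
shared between the unit tests and the acceptance suite.  Scales (events per
class, epochs) are reduced relative to the experimental datasets but keep the
same protocols; all randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from poreptm import (
    ClassifierConfig,
    default_signatures,
    predict,
    prepare_sequences,
    simulate_labeled_events,
    train,
)
from poreptm.simulator import SimulationConfig

TWO_CLASS_NAMES = ("wt", "pY125")
EIGHT_LEVEL_MEANS = (6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 34.0)


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def two_class_signatures(signatures):
    """Two classes separable by a relative-current threshold (5-10% vs 25-35%)."""
    return {
        "wt": signatures["wt"].with_levels((7.5, 1.0, 1.0)),
        "pY125": signatures["pY125"].with_levels((30.0, 2.0, 1.0)),
    }


@pytest.fixture(scope="session")
def two_class_events(two_class_signatures):
    """2000 labelled events per class from a simulated 1:1 recording."""
    events, opm = simulate_labeled_events(
        two_class_signatures,
        {"wt": 0.5, "pY125": 0.5},
        n_events=4000,
        seed=3,
        config=SimulationConfig(capture_rate_hz=10.0),
        per_class_cap=2000,
    )
    return events


@pytest.fixture(scope="session")
def two_class_model(two_class_events):
    """Classifier + assessor jointly trained on the separable 2-class set."""
    config = ClassifierConfig(n_classes=2, epochs=12, patience=4, max_len=32, seed=7)
    seqs = prepare_sequences(two_class_events, config.rescale, config.max_len)
    labels = [ev.label for ev in two_class_events]
    bundle, log = train(seqs, labels, config)
    n_train = int(np.floor(0.75 * len(seqs)))
    val_events = two_class_events[n_train:]
    val_pred = predict(bundle, seqs[n_train:])
    return {
        "bundle": bundle,
        "log": log,
        "config": config,
        "events": two_class_events,
        "val_events": val_events,
        "val_labels": np.array(labels[n_train:]),
        "val_pred": val_pred,
    }


@pytest.fixture(scope="session")
def eight_class_signatures(signatures):
    """All eight presets with overridden, distinct single levels (sd 2.0%).

    The level grid deliberately keeps neighbouring classes ~2 sd apart so the
    task is learnable but not trivial — the regime where confidence-based
    selection has something to trade.
    """
    out = {}
    for (name, sig), mean in zip(signatures.items(), EIGHT_LEVEL_MEANS):
        out[name] = sig.with_levels((mean, 2.0, 1.0))
    return out


@pytest.fixture(scope="session")
def eight_class_runs(eight_class_signatures):
    """Five independent simulate+train runs of the 8-class protocol."""
    names = list(eight_class_signatures)
    mix = {name: 1.0 / len(names) for name in names}
    runs = []
    for k in range(5):
        events, _ = simulate_labeled_events(
            eight_class_signatures,
            mix,
            n_events=2400,
            seed=100 + k,
            config=SimulationConfig(capture_rate_hz=10.0),
        )
        # small-batch regime: with ~1800 training events the joint system
        # needs many small steps per epoch to co-adapt stably
        config = ClassifierConfig(
            n_classes=8, epochs=30, patience=10, max_len=32, seed=k,
            batch_size=32, learning_rate=3e-4,
        )
        seqs = prepare_sequences(events, config.rescale, config.max_len)
        labels = [ev.label for ev in events]
        bundle, log = train(seqs, labels, config, class_labels=tuple(sorted(names)))
        n_train = int(np.floor(0.75 * len(seqs)))
        runs.append(
            {
                "pred": predict(bundle, seqs[n_train:]),
                "labels": np.array(labels[n_train:]),
                "log": log,
            }
        )
    return runs
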