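"""End-to-end helpers chaining simulation, detection and labelling.

These are the glue used by the CLI, the test suite and the acceptance script:
run the full detection stack on a trace, or produce a labelled event set from
a simulated recording by matching detections back to the ground truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .event_detection import (
    BlockadeEvent,
    OpenPoreModel,
    compute_features,
    extract_events,
    filter_events,
    fit_open_pore,
)
from .evaluation import match_events_to_truth
from .simulator import ClassSignature, SimulationConfig, simulate_trace
from .trace_io import CurrentTrace

__all__ = ["detect", "simulate_labeled_events"]


def detect(
    trace: CurrentTrace,
    k_sigma: float = 3.0,
    dwell_range_ms: tuple[float, float] = (0.2, 100.0),
    rel_current_range_pct: tuple[float, float] = (0.0, 40.0),
    min_prominence_pA: float | None = None,
    opm: OpenPoreModel | None = None,
) -> tuple[OpenPoreModel, list[BlockadeEvent], dict]:
    """Open-pore fit, event extraction, features and standard filters.

    Returns the fitted baseline, the surviving events (features populated) and
    a summary dict (I0, sigma0, counts before/after filtering).
    """
    if opm is None:
        opm = fit_open_pore(trace)
    events = extract_events(trace, opm, k_sigma=k_sigma)
    for ev in events:
        compute_features(ev, opm, trace.sampling_rate, min_prominence_pA)
    kept, counts = filter_events(
        events, dwell_range_ms, rel_current_range_pct, return_counts=True
    )
    summary = {
        "I0_pA": opm.I0,
        "sigma0_pA": opm.sigma0,
        "threshold_pA": opm.threshold(k_sigma),
        "n_extracted": len(events),
        "n_kept": counts["kept"],
        "n_discarded": counts["discarded"],
    }
    return opm, kept, summary


def simulate_labeled_events(
    signatures: dict[str, ClassSignature],
    class_mix: dict[str, float],
    n_events: int,
    seed: int,
    config: SimulationConfig | None = None,
    per_class_cap: int | None = None,
) -> tuple[list[BlockadeEvent], OpenPoreModel]:
    """Simulate a recording and return detected events labelled from the truth.

    The trace duration is chosen with a margin so that at least ``n_events``
    labelled events survive detection and filtering; events are returned in
    acquisition order, truncated to ``n_events`` (and optionally to
    ``per_class_cap`` events per class, preserving order).
    """
    base = config or SimulationConfig()
    rate = base.capture_rate_hz if base.capture_rate_hz > 0 else 10.0
    duration = n_events / rate * 1.35 + 2.0
    cfg = replace(base, capture_rate_hz=rate, duration_s=duration, seed=seed)
    trace, truth = simulate_trace(cfg, signatures, class_mix)
    opm, events, _ = detect(trace)
    pairs, _, _ = match_events_to_truth(events, truth)
    labeled = []
    for d_idx, ev in enumerate(events):
        if d_idx in pairs:
            ev.label = truth[pairs[d_idx]].class_name
            labeled.append(ev)
    if len(labeled) < n_events:
        raise RuntimeError(
            f"simulation produced only {len(labeled)} labelled events, "
            f"needed {n_events}; increase duration margin"
        )
    if per_class_cap is not None:
        counts: dict[str, int] = {}
        capped = []
        for ev in labeled:
            c = counts.get(ev.label, 0)
            if c < per_class_cap:
                capped.append(ev)
                counts[ev.label] = c + 1
        labeled = capped
    return labeled[:n_events], opm
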