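"""Open-pore fitting, event extraction, features, extrema and population fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poreptm import (
    BlockadeEvent,
    CurrentTrace,
    OpenPoreModel,
    compute_features,
    extract_events,
    extract_local_extrema,
    filter_events,
    fit_open_pore,
    fit_population_gaussians,
    simulate_trace,
)
from poreptm.simulator import SimulationConfig


# --- open-pore fitting -----------------------------------------------------


def test_constant_trace_degenerate_fit():
    opm = fit_open_pore(CurrentTrace(np.full(2000, 72.0), 10_000.0))
    assert opm.I0 == 72.0
    assert opm.sigma0 == 0.0


def test_gaussian_baseline_recovered_to_tolerance():
    rng = np.random.default_rng(12)
    trace = CurrentTrace(rng.normal(72.0, 1.5, 100_000), 10_000.0)
    opm = fit_open_pore(trace)
    assert abs(opm.I0 - 72.0) < 0.05
    assert abs(opm.sigma0 - 1.5) < 0.05


def test_bimodal_trace_selects_highest_mean_peak():
    """With 10% of samples in a deep-blockade mode, I0 is the open-pore mode."""
    rng = np.random.default_rng(7)
    samples = np.concatenate(
        [rng.normal(72.0, 1.0, 90_000), rng.normal(10.0, 1.0, 10_000)]
    )
    rng.shuffle(samples)
    opm = fit_open_pore(CurrentTrace(samples, 10_000.0))
    assert abs(opm.I0 - 72.0) < 0.1  # not the 65.8 weighted average
    assert abs(opm.sigma0 - 1.0) < 0.1


def test_too_short_trace_rejected():
    with pytest.raises(ValueError, match="at least"):
        fit_open_pore(CurrentTrace(np.full(10, 72.0), 10_000.0))


# --- event extraction ------------------------------------------------------


def _brute_force_events(samples, thr):
    """Independent sample-by-sample threshold scan (boundary events dropped)."""
    events, start = [], None
    for i, x in enumerate(samples):
        if x < thr and start is None:
            start = i
        elif x >= thr and start is not None:
            events.append((start, i))
            start = None
    if start is not None:
        events.append((start, len(samples)))
    return [(s, e) for s, e in events if s != 0 and e != len(samples)]


def test_no_subthreshold_samples_gives_empty():
    trace = CurrentTrace(np.full(2000, 72.0), 10_000.0)
    opm = OpenPoreModel(72.0, 1.5)
    assert extract_events(trace, opm) == []


def test_square_pulse_event_arithmetic():
    """50 samples at 6.48 pA in a clean 72 pA baseline: dwell 5 ms, I/I0 = 9%."""
    samples = np.full(1000, 72.0)
    samples[400:450] = 6.48
    trace = CurrentTrace(samples, 10_000.0)
    opm = OpenPoreModel(72.0, 0.0)
    events = extract_events(trace, opm)
    assert len(events) == 1
    ev = compute_features(events[0], opm, trace.sampling_rate)
    assert (ev.start_index, ev.end_index) == (400, 450)
    assert ev.dwell_ms == pytest.approx(5.0)
    assert ev.rel_current_pct == pytest.approx(9.0)
    assert ev.rel_sigma is None  # undefined when sigma0 = 0, never infinite


def test_extraction_matches_brute_force_on_simulated_trace(signatures):
    cfg = SimulationConfig(capture_rate_hz=5.0, duration_s=10.0, seed=21)
    trace, _ = simulate_trace(cfg, signatures, {"wt": 0.5, "nY125": 0.5})
    opm = fit_open_pore(trace)
    got = [(ev.start_index, ev.end_index) for ev in extract_events(trace, opm)]
    assert got == _brute_force_events(trace.samples, opm.threshold())


def test_simulator_round_trip_recall_and_dwell(signatures):
    """Detection recovers annotated events (rel current <= 20%, dwell >= 0.5 ms)."""
    from poreptm import match_events_to_truth

    cfg = SimulationConfig(capture_rate_hz=5.0, duration_s=60.0, seed=22)
    trace, truth = simulate_trace(cfg, signatures, {"wt": 1.0})
    opm = fit_open_pore(trace)
    events = extract_events(trace, opm)
    for ev in events:
        compute_features(ev, opm, trace.sampling_rate)
    events = filter_events(events)
    pairs, recall, _ = match_events_to_truth(events, truth)
    eligible = [t for t in truth if t.dwell_ms >= 0.5]
    assert recall >= 0.95 * len(eligible) / len(truth)
    for d_idx, t_idx in pairs.items():
        if truth[t_idx].dwell_ms < 0.5:
            continue
        true_n = truth[t_idx].end_index - truth[t_idx].start_index
        assert abs(events[d_idx].n_samples - true_n) <= 2


# --- features --------------------------------------------------------------


def test_dwell_from_sample_count():
    ev = BlockadeEvent(100, 126, np.full(26, 10.0))
    compute_features(ev, OpenPoreModel(72.0, 1.5), 10_000.0)
    assert ev.dwell_ms == pytest.approx(2.6)


def test_features_equal_direct_recomputation():
    rng = np.random.default_rng(5)
    samples = rng.uniform(5, 20, 40)
    ev = BlockadeEvent(10, 50, samples)
    opm = OpenPoreModel(72.0, 1.5)
    compute_features(ev, opm, 10_000.0)
    assert ev.mean_residual_pA == pytest.approx(samples.mean())
    assert ev.rel_current_pct == pytest.approx(100 * samples.mean() / 72.0)
    assert ev.rel_sigma == pytest.approx(samples.std() / 1.5)


# --- local extrema ---------------------------------------------------------


def _zigzag_oracle(values, delta):
    """Quadratic re-derivation of the committed turning points.

    A turning point is committed once the signal has moved away from the
    running extreme by more than ``delta``; this oracle recomputes each
    committed extremum from full prefix slices instead of the streaming walk.
    """
    vals, idx, i = [], [], 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[i]:
            j += 1
        vals.append(values[i])
        idx.append((i + j) // 2)
        i = j + 1
    n = len(vals)
    out, pos, direction = [], 0, 0
    while pos < n - 1:
        hit = None
        for j in range(pos + 1, n):
            w = vals[pos : j + 1]
            if direction >= 0 and max(w) - vals[j] > delta:
                hit = (pos + w.index(max(w)), -1, j)
                break
            if direction <= 0 and vals[j] - min(w) > delta:
                hit = (pos + w.index(min(w)), +1, j)
                break
        if hit is None:
            break
        k, direction, j = hit
        out.append((k, vals[k]))
        pos = j
    return [(idx[k], v) for k, v in out if 0 < k < n - 1]


def _extrema_of(samples, delta, i0=72.0, fs=10_000.0):
    ev = BlockadeEvent(0, len(samples), np.asarray(samples, dtype=float))
    return extract_local_extrema(ev, OpenPoreModel(i0, 0.0), fs, delta)


def test_monotone_sequence_has_no_extrema():
    assert _extrema_of(np.linspace(50, 10, 20), 0.0) == []


def test_short_events_have_no_extrema():
    assert _extrema_of([10.0], 0.0) == []
    assert _extrema_of([10.0, 20.0], 0.0) == []


def test_hand_enumerated_extrema():
    """[50, 30, 60, 20, 70]: minima at idx 1 and 3, maximum at idx 2."""
    got = _extrema_of([50.0, 30.0, 60.0, 20.0, 70.0], 0.0)
    times = [t for t, _ in got]
    vals = [c for _, c in got]
    assert times == pytest.approx([1e-4, 2e-4, 3e-4])
    assert vals == pytest.approx([100 * 30 / 72, 100 * 60 / 72, 100 * 20 / 72])


def test_extrema_alternate_and_match_oracle_on_noise():
    rng = np.random.default_rng(17)
    for delta in (0.0, 1.0, 3.0):
        samples = rng.normal(10.0, 2.0, 200)
        got = _extrema_of(samples, delta)
        oracle = _zigzag_oracle(list(samples), delta)
        assert [t for t, _ in got] == pytest.approx([i / 10_000.0 for i, _ in oracle])
        assert [c for _, c in got] == pytest.approx([100 * v / 72.0 for _, v in oracle])
        vals = [c for _, c in got]
        signs = np.sign(np.diff(vals))
        assert np.all(signs[1:] == -signs[:-1])  # strict min/max alternation


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=40),
    st.sampled_from([0.0, 1.0, 2.5]),
)
def test_extrema_equal_oracle_property(values, delta):
    samples = np.array(values, dtype=float) + 36.0  # keep currents positive
    got = _extrema_of(samples, delta)
    oracle = _zigzag_oracle(list(samples), delta)
    assert [t for t, _ in got] == pytest.approx([i / 10_000.0 for i, _ in oracle])
    assert [c for _, c in got] == pytest.approx([100 * v / 72.0 for _, v in oracle])


# --- filters ---------------------------------------------------------------


def _toy_event(dwell_ms, rel_pct):
    n = max(1, int(round(dwell_ms * 10)))
    ev = BlockadeEvent(0, n, np.zeros(n))
    ev.dwell_ms = dwell_ms
    ev.rel_current_pct = rel_pct
    return ev


def test_filter_boundaries_inclusive():
    events = [_toy_event(d, 10.0) for d in (0.1, 0.2, 2.58, 100.0, 150.0)]
    kept, counts = filter_events(events, return_counts=True)
    assert [ev.dwell_ms for ev in kept] == [0.2, 2.58, 100.0]
    assert counts == {"kept": 3, "discarded": 2}


def test_filter_rejects_shallow_blockades():
    assert filter_events([_toy_event(1.0, 45.0)]) == []
    assert filter_events([_toy_event(1.0, 40.0)]) != []


def test_filter_idempotent_and_order_preserving():
    rng = np.random.default_rng(3)
    events = [_toy_event(d, c) for d, c in zip(rng.uniform(0.05, 150, 50), rng.uniform(0, 60, 50))]
    once = filter_events(events)
    assert filter_events(once) == once
    kept_ids = [id(ev) for ev in once]
    assert kept_ids == [id(ev) for ev in events if id(ev) in set(kept_ids)]


# --- population Gaussians --------------------------------------------------


def test_two_population_fit_recovers_wt_levels():
    """Draws from 0.5 N(9,2) + 0.5 N(17.1,2): means back within 0.2."""
    rng = np.random.default_rng(31)
    values = np.concatenate([rng.normal(9.0, 2.0, 5000), rng.normal(17.1, 2.0, 5000)])
    fit = fit_population_gaussians(values, K=2, seed=0)
    assert fit.means[0] == pytest.approx(9.0, abs=0.2)
    assert fit.means[1] == pytest.approx(17.1, abs=0.2)
    assert fit.weights[0] == pytest.approx(0.5, abs=0.05)


def test_degenerate_identical_values():
    fit = fit_population_gaussians(np.full(100, 9.0), K=1)
    assert fit.means == (9.0,)
    assert fit.sds == (0.0,)


def test_single_component_moment_recovery():
    rng = np.random.default_rng(8)
    values = rng.normal(9.0, 2.0, 2000)
    fit = fit_population_gaussians(values, K=1, seed=0)
    assert abs(fit.means[0] - 9.0) < 3 * 2.0 / np.sqrt(len(values))


def test_population_fit_preconditions():
    with pytest.raises(ValueError, match="at least 50"):
        fit_population_gaussians(np.ones(10), K=1)
    with pytest.raises(ValueError, match="K must be"):
        fit_population_gaussians(np.random.default_rng(0).normal(9, 2, 100), K=4)
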