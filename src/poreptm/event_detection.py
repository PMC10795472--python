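"""Open-pore fitting, blockade-event extraction, per-event features and
relative-current population fits.

The open-pore distribution (I0, sigma0) is obtained by fitting a Gaussian to
the histogram peak with the highest mean current — the open-pore mode, never a
blockade mode.  Events are maximal runs of samples below I0 - k*sigma0 (k = 3
by default).  Per event we compute the dwell time, the mean residual current I,
the relative current percentage 100*I/I0, the relative noise sigma/sigma0, and
the ordered local-extrema sequence that feeds the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .trace_io import CurrentTrace

__all__ = [
    "OpenPoreModel",
    "BlockadeEvent",
    "PopulationFit",
    "fit_open_pore",
    "extract_events",
    "compute_features",
    "extract_local_extrema",
    "filter_events",
    "fit_population_gaussians",
]


@dataclass(frozen=True)
class OpenPoreModel:
    """Fitted open-pore baseline: mean I0 (pA), SD sigma0 (pA), fit window."""

    I0: float
    sigma0: float
    fit_window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.I0 > 0:
            raise ValueError(f"I0 must be > 0, got {self.I0}")
        if self.sigma0 < 0:
            raise ValueError(f"sigma0 must be >= 0, got {self.sigma0}")

    def threshold(self, k_sigma: float = 3.0) -> float:
        return self.I0 - k_sigma * self.sigma0


@dataclass
class BlockadeEvent:
    """One extracted blockade (half-open, 0-based sample indices).

    Feature fields are ``None`` until :func:`compute_features` populates them.
    ``extrema`` is the ordered list of (time within event in s, relative
    current in percent) turning points.
    """

    start_index: int
    end_index: int
    samples: np.ndarray
    dwell_ms: float | None = None
    mean_residual_pA: float | None = None
    rel_current_pct: float | None = None
    rel_sigma: float | None = None
    extrema: list[tuple[float, float]] = field(default_factory=list)
    label: str | None = None
    prediction: str | None = None
    assessment_score: float | None = None

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_open_pore(trace: CurrentTrace, min_samples: int = 1000) -> OpenPoreModel:
    """Fit the open-pore current distribution of a trace.

    A histogram (Freedman-Diaconis bins) is scanned for local maxima; the peak
    with the highest mean current is taken as the open-pore mode and a Gaussian
    is fitted to the bin counts within +/- 3 sigma of it (sigma first estimated
    from the peak's full width at half maximum).  Blockade modes at lower
    current are thereby excluded from the fit.
    """
    x = trace.samples
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples to fit the open pore, got {x.size}")
    if np.ptp(x) == 0.0:
        return OpenPoreModel(I0=float(x[0]), sigma0=0.0, fit_window=(float(x[0]), float(x[0])))

    counts, edges = np.histogram(x, bins=np.histogram_bin_edges(x, bins="fd"))
    centers = 0.5 * (edges[:-1] + edges[1:])
    cmax = counts.max()
    if cmax == counts.min():
        raise ValueError("no identifiable open-pore peak: histogram is flat")

    # local maxima (plateau tolerant), ignoring near-empty fluctuation bins
    left = np.r_[-1, counts[:-1]]
    right = np.r_[counts[1:], -1]
    is_peak = (counts > left) & (counts >= right) & (counts >= 0.05 * cmax)
    peaks = np.flatnonzero(is_peak)
    if peaks.size == 0:
        raise ValueError("no identifiable open-pore peak: histogram is flat")
    mode = peaks[np.argmax(centers[peaks])]  # peak with the highest mean current

    # FWHM-based scale estimate around the mode
    half = counts[mode] / 2.0
    lo = mode
    while lo > 0 and counts[lo] > half:
        lo -= 1
    hi = mode
    while hi < counts.size - 1 and counts[hi] > half:
        hi += 1
    bin_w = edges[1] - edges[0]
    fwhm = max((hi - lo) * bin_w, bin_w)
    sigma_est = fwhm / 2.355

    w_lo, w_hi = centers[mode] - 3 * sigma_est, centers[mode] + 3 * sigma_est
    sel = (centers >= w_lo) & (centers <= w_hi)
    try:
        popt, _ = curve_fit(
            _gauss,
            centers[sel],
            counts[sel],
            p0=(counts[mode], centers[mode], sigma_est),
            maxfev=10_000,
        )
        i0, sigma0 = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        # moment fallback on the samples inside the window
        window = x[(x >= w_lo) & (x <= w_hi)]
        i0, sigma0 = float(window.mean()), float(window.std())
    return OpenPoreModel(I0=i0, sigma0=sigma0, fit_window=(float(w_lo), float(w_hi)))


def extract_events(
    trace: CurrentTrace,
    opm: OpenPoreModel,
    k_sigma: float = 3.0,
    discard_boundary: bool = True,
) -> list[BlockadeEvent]:
    """Extract blockades as maximal runs of samples below I0 - k_sigma*sigma0.

    Boundaries are the first/last sub-threshold samples (half-open indices);
    events touching the trace boundaries are discarded (their dwell cannot be
    measured).  Returned in time order.
    """
    thr = opm.threshold(k_sigma)
    below = trace.samples < thr
    padded = np.r_[0, below.view(np.int8), 0]
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    events = []
    n = trace.samples.size
    for s, e in zip(starts, ends):
        if discard_boundary and (s == 0 or e == n):
            continue
        events.append(BlockadeEvent(int(s), int(e), trace.samples[s:e].copy()))
    return events


def compute_features(
    event: BlockadeEvent,
    opm: OpenPoreModel,
    sampling_rate: float,
    min_prominence_pA: float | None = None,
) -> BlockadeEvent:
    """Populate dwell/current features and the local-extrema sequence in place.

    ``rel_sigma`` is left ``None`` (undefined) when sigma0 = 0.  The extrema
    prominence threshold defaults to 1*sigma0 to suppress pure-noise turning
    points.
    """
    if event.n_samples < 1:
        raise ValueError("event must contain at least one sample")
    s = event.samples
    event.dwell_ms = event.n_samples / sampling_rate * 1000.0
    event.mean_residual_pA = float(s.mean())
    event.rel_current_pct = 100.0 * event.mean_residual_pA / opm.I0
    event.rel_sigma = float(s.std() / opm.sigma0) if opm.sigma0 > 0 else None
    if min_prominence_pA is None:
        min_prominence_pA = opm.sigma0
    event.extrema = extract_local_extrema(event, opm, sampling_rate, min_prominence_pA)
    return event


def _collapse_plateaus(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal values to single points at the run midpoints."""
    if values.size == 0:
        return values, np.array([], dtype=int)
    change = np.r_[True, np.diff(values) != 0]
    run_starts = np.flatnonzero(change)
    run_ends = np.r_[run_starts[1:], values.size]
    idx = (run_starts + run_ends - 1) // 2
    return values[run_starts], idx


def extract_local_extrema(
    event: BlockadeEvent,
    opm: OpenPoreModel,
    sampling_rate: float,
    min_prominence_pA: float = 0.0,
) -> list[tuple[float, float]]:
    """Ordered alternating local extrema of the event's sample sequence.

    After plateau collapse, turning points are committed by a hysteresis walk:
    an extremum counts only once the signal has reversed away from it by more
    than ``min_prominence_pA`` (any strict reversal when the threshold is 0).
    The first and last samples are never emitted, so 1- and 2-sample events
    yield an empty list.  Each extremum is returned as (time within event in
    seconds, relative current in percent of I0); the sequence strictly
    alternates between minima and maxima.
    """
    vals, idx = _collapse_plateaus(np.asarray(event.samples, dtype=float))
    n = vals.size
    out: list[tuple[int, float]] = []
    if n >= 3:
        delta = float(min_prominence_pA)
        hi_i, hi_v = 0, vals[0]
        lo_i, lo_v = 0, vals[0]
        direction = 0  # 0 unknown, +1 rising (tracking hi), -1 falling (tracking lo)
        for j in range(1, n):
            v = vals[j]
            if direction >= 0 and v > hi_v:
                hi_i, hi_v = j, v
            if direction <= 0 and v < lo_v:
                lo_i, lo_v = j, v
            if direction == 0:
                if v < hi_v - delta:
                    out.append((hi_i, hi_v))
                    direction = -1
                    lo_i, lo_v = j, v
                elif v > lo_v + delta:
                    out.append((lo_i, lo_v))
                    direction = 1
                    hi_i, hi_v = j, v
            elif direction == -1:
                if v > lo_v + delta:
                    out.append((lo_i, lo_v))
                    direction = 1
                    hi_i, hi_v = j, v
            else:
                if v < hi_v - delta:
                    out.append((hi_i, hi_v))
                    direction = -1
                    lo_i, lo_v = j, v
    # drop committed extrema that sit on the (collapsed) event boundaries
    interior = [(i, v) for i, v in out if 0 < i < n - 1]
    return [
        (float(idx[i]) / sampling_rate, 100.0 * v / opm.I0) for i, v in interior
    ]


def filter_events(
    events: list[BlockadeEvent],
    dwell_range_ms: tuple[float, float] = (0.2, 100.0),
    rel_current_range_pct: tuple[float, float] = (0.0, 40.0),
    return_counts: bool = False,
):
    """Keep events with dwell and relative current inside the standard windows.

    Defaults are the selection rules used throughout: dwell time 0.2-100.0 ms
    and average relative current 0-40% (boundaries inclusive), discarding
    events that are too short, too long, or that do not block the current
    sufficiently.  Order-preserving and idempotent.
    """
    d_lo, d_hi = dwell_range_ms
    c_lo, c_hi = rel_current_range_pct
    kept = [
        ev
        for ev in events
        if d_lo <= ev.dwell_ms <= d_hi and c_lo <= ev.rel_current_pct <= c_hi
    ]
    if return_counts:
        return kept, {"kept": len(kept), "discarded": len(events) - len(kept)}
    return kept


@dataclass(frozen=True)
class PopulationFit:
    """K-component Gaussian fit of a relative-current histogram.

    Components are sorted by mean; weights sum to 1.
    """

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("population weights must sum to 1")
        if any(sd < 0 for sd in self.sds):
            raise ValueError("population SDs must be non-negative")

    @property
    def K(self) -> int:
        return len(self.means)


def fit_population_gaussians(values, K: int, seed: int = 0) -> PopulationFit:
    """Maximum-likelihood K-component Gaussian mixture of relative currents.

    EM with k-means initialization, 10 restarts and tolerance 1e-8, seeded for
    reproducibility.  ``K`` must be 1, 2 or 3 and at least 50 values are
    required.  A degenerate all-identical sample is handled exactly for K = 1.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 50:
        raise ValueError(f"need at least 50 values, got {x.shape[0]}")
    if K not in (1, 2, 3):
        raise ValueError(f"K must be 1, 2 or 3, got {K}")
    if np.ptp(x) == 0.0:
        if K == 1:
            return PopulationFit((1.0,), (float(x[0, 0]),), (0.0,))
        raise ValueError(f"all values identical: cannot fit {K} components")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=10,
        tol=1e-8,
        reg_covar=1e-10,
        max_iter=500,
        init_params="k-means++",
        random_state=seed,
    ).fit(x)
    if not gm.converged_:
        raise RuntimeError(
            f"Gaussian mixture EM did not converge (K={K}, n={x.shape[0]}, "
            f"lower bound {gm.lower_bound_:.6g})"
        )
    order = np.argsort(gm.means_.ravel())
    return PopulationFit(
        weights=tuple(float(w) for w in gm.weights_.ravel()[order]),
        means=tuple(float(m) for m in gm.means_.ravel()[order]),
        sds=tuple(float(np.sqrt(c)) for c in gm.covariances_.ravel()[order]),
    )
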