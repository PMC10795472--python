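"""Capture-rate quantification: f_sig = k_on * [analyte]0.

The blockade-event frequency f_sig is proportional to the analyte
concentration; fitting the proportionality constant k_on on a calibration
series lets an observed frequency be inverted into a concentration estimate.
The law has no intercept, so the fit is constrained through the origin; a
free-intercept diagnostic fit is reported alongside but never used for
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CaptureFit", "event_frequency", "fit_capture_rate", "estimate_concentration"]


@dataclass(frozen=True)
class CaptureFit:
    """Through-origin least-squares fit of frequency versus concentration.

    ``k_on`` is in Hz per concentration unit of the calibration points;
    ``k_on_se`` is its standard error from the residuals.  The diagnostic
    free-intercept fit (slope, intercept) is informational only.
    """

    k_on: float
    k_on_se: float
    concentration_range: tuple[float, float]
    n_points: int
    diagnostic_slope: float
    diagnostic_intercept: float

    def __post_init__(self):
        if not self.k_on > 0:
            raise ValueError(f"invalid fit: k_on = {self.k_on} must be > 0")


def event_frequency(events, recording_duration_s: float) -> float:
    """Blockade frequency in Hz: count of (filtered) events over the duration."""
    if not recording_duration_s > 0:
        raise ValueError("recording duration must be > 0")
    n = len(events) if hasattr(events, "__len__") else int(events)
    return n / recording_duration_s


def fit_capture_rate(points) -> CaptureFit:
    """Fit f_sig = k_on * c by least squares through the origin.

    ``points`` is a sequence of (concentration, f_sig) pairs; at least 3
    points with positive concentrations are required.  The slope SE follows
    from the residual variance with n-1 degrees of freedom.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 (concentration, f_sig) points")
    c, f = pts[:, 0], pts[:, 1]
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.all(f == 0):
        raise ValueError("all frequencies are zero: nothing to fit")
    scc = float(np.sum(c * c))
    k_on = float(np.sum(c * f) / scc)
    resid = f - k_on * c
    dof = len(c) - 1
    se = float(np.sqrt(np.sum(resid**2) / dof / scc)) if dof > 0 else 0.0
    slope, intercept = np.polyfit(c, f, 1)
    return CaptureFit(
        k_on=k_on,
        k_on_se=se,
        concentration_range=(float(c.min()), float(c.max())),
        n_points=len(c),
        diagnostic_slope=float(slope),
        diagnostic_intercept=float(intercept),
    )


def estimate_concentration(fit: CaptureFit, f_sig: float) -> tuple[float, float]:
    """Invert the capture-rate law: concentration = f_sig / k_on, with SE.

    First-order error propagation: SE(c) = c * SE(k_on) / k_on.
    """
    if f_sig < 0:
        raise ValueError("f_sig must be >= 0")
    if not fit.k_on > 0:
        raise ValueError("fit has k_on <= 0")
    conc = f_sig / fit.k_on
    return conc, conc * fit.k_on_se / fit.k_on
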