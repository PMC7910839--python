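"""AFM deflection-trace processing: drift correction, smoothing, pooling.

The cantilever deflection reports the normal force between the picked-up
T-cell and the bilayer.  Slow instrumental drift is removed by fitting a
smoothing spline to the pre-contact segment and subtracting it (extended
linearly beyond the fitted segment); display traces are 1-s moving
averages; for population histograms, force samples are pooled into
time windows fixed relative to the calcium half-rise: before
(−50 s ≤ t ≤ −16 s), during (−16 s < t ≤ +16 s) and after
(16 s < t ≤ 50 s) calcium flux.

Sign convention: negative force = cell pulls toward the surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .imaging_io import ForceTraceRaw

__all__ = [
    "ForceTraceProcessed",
    "ForceHistogramSet",
    "DEFAULT_FORCE_WINDOWS",
    "drift_correct",
    "smooth",
    "pool_force_windows",
]

MIN_PRECONTACT_S = 10.0
DEFAULT_SMOOTH_WINDOW_S = 1.0
#: (label, lo, hi, lo_closed, hi_closed) — endpoint conventions as printed.
DEFAULT_FORCE_WINDOWS: tuple[tuple[str, float, float, bool, bool], ...] = (
    ("before", -50.0, -16.0, True, True),
    ("during", -16.0, 16.0, False, True),
    ("after", 16.0, 50.0, False, True),
)
DEFAULT_BIN_EDGES = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.1), 10)


@dataclass
class ForceTraceProcessed:
    """Drift-corrected force trace with a 1-s smoothed companion."""

    time_s: np.ndarray
    force_nN: np.ndarray
    smoothed_force_nN: np.ndarray
    contact_time_s: float

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.force_nN) == len(self.smoothed_force_nN)):
            raise ValueError("processed trace arrays must share one length")


@dataclass
class ForceHistogramSet:
    """Per-window force histograms over shared bin edges."""

    bin_edges_nN: np.ndarray
    counts: dict[str, np.ndarray]
    n_samples: dict[str, int]


def smooth(force: np.ndarray, rate_hz: float, window_s: float = DEFAULT_SMOOTH_WINDOW_S) -> np.ndarray:
    """Centered moving average; edges use truncated windows (same length out)."""
    force = np.asarray(force, dtype=np.float64)
    w = max(1, int(round(window_s * rate_hz)))
    if w <= 1:
        return force.copy()
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(force)])
    n = len(force)
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def drift_correct(
    trace: ForceTraceRaw,
    contact_time_s: float,
    knot_spacing_s: float = 10.0,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> ForceTraceProcessed:
    """Remove offset and slow drift using the pre-contact segment.

    A cubic least-squares spline with roughly one interior knot per
    ``knot_spacing_s`` of pre-contact data is fit to samples with
    t < ``contact_time_s`` and subtracted from the whole trace; beyond the
    fitted segment the spline is continued linearly at its end slope so
    the slow trend is removed from the post-contact part as well.
    Requires at least 10 s of pre-contact data.
    """
    t = trace.time_s
    f = trace.deflection_nN
    pre = t < contact_time_s
    pre_span = t[pre][-1] - t[pre][0] if pre.any() else 0.0
    if pre_span < MIN_PRECONTACT_S:
        raise ValueError(
            f"need >= {MIN_PRECONTACT_S:.0f} s of pre-contact data, got {pre_span:.1f} s"
        )
    t_pre, f_pre = t[pre], f[pre]
    # decimate to ~10 Hz bin means before the spline fit: the fit targets
    # drift on >10 s scales, and this keeps the lsq problem small
    bin_w = max(1, int(round(trace.rate_hz / 10.0)))
    n_bins = len(t_pre) // bin_w
    t_fit = t_pre[: n_bins * bin_w].reshape(n_bins, bin_w).mean(axis=1)
    f_fit = f_pre[: n_bins * bin_w].reshape(n_bins, bin_w).mean(axis=1)
    n_knots = max(0, int(pre_span / knot_spacing_s) - 1)
    interior = np.linspace(t_fit[0], t_fit[-1], n_knots + 2)[1:-1]
    spline = LSQUnivariateSpline(t_fit, f_fit, interior, k=3)

    baseline = np.empty_like(f)
    in_seg = t <= t_fit[-1]
    baseline[in_seg] = spline(t[in_seg])
    # linear continuation beyond the fitted segment
    end_val = float(spline(t_fit[-1]))
    end_slope = float(spline.derivative()(t_fit[-1]))
    baseline[~in_seg] = end_val + end_slope * (t[~in_seg] - t_fit[-1])

    corrected = f - baseline
    smoothed = smooth(corrected, trace.rate_hz, smooth_window_s)
    return ForceTraceProcessed(t.copy(), corrected, smoothed, contact_time_s)


def pool_force_windows(
    trace: ForceTraceProcessed,
    t_zero_s: float,
    windows: tuple[tuple[str, float, float, bool, bool], ...] = DEFAULT_FORCE_WINDOWS,
    bin_edges_nN: np.ndarray = DEFAULT_BIN_EDGES,
    use_smoothed: bool = True,
) -> ForceHistogramSet:
    """Histogram force samples by time window relative to the calcium half-rise.

    Sample times are shifted by ``t_zero_s``; each window keeps its printed
    closed/open endpoint convention, so a sample exactly at t = −16 s falls
    in the "before" window only.  By default the 1-s smoothed force is
    pooled.
    """
    t_shift = trace.time_s - t_zero_s
    values = trace.smoothed_force_nN if use_smoothed else trace.force_nN
    counts: dict[str, np.ndarray] = {}
    n_samples: dict[str, int] = {}
    any_hit = False
    for label, lo, hi, lo_closed, hi_closed in windows:
        sel_lo = t_shift >= lo if lo_closed else t_shift > lo
        sel_hi = t_shift <= hi if hi_closed else t_shift < hi
        sel = sel_lo & sel_hi
        n_samples[label] = int(sel.sum())
        any_hit = any_hit or sel.any()
        counts[label], _ = np.histogram(values[sel], bins=bin_edges_nN)
    if not any_hit:
        raise ValueError("trace is disjoint from every requested window")
    return ForceHistogramSet(np.asarray(bin_edges_nN, dtype=np.float64), counts, n_samples)
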