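"""Half-maximal transition times, trace synchronization, parametric coupling.

Event times across modalities are defined by one statistic: the time at
which a trace crosses the midpoint between its extreme values (the
half-maximal transition time t_median).  For a rising trace the minimum
f(t1) must precede the maximum f(t2); among the crossings of the
half-amplitude level the one closest to t2 is chosen, with linear
interpolation between the bracketing samples.  Cells are synchronized by
shifting every modality's time axis so the calcium t_median sits at
t = 0; cross-modal lags and area-versus-ratio coupling points follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .imaging_io import cycle_frame_times, DEFAULT_CYCLE_PERIOD_S

__all__ = [
    "TransitionDetection",
    "SynchronizedCell",
    "NoTransitionError",
    "detect_transition",
    "synchronize",
    "coupling_points",
]

DEFAULT_COUPLING_WINDOW_S = (-50.0, 100.0)


class NoTransitionError(ValueError):
    """Trace has no detectable transition (flat, or extremes mis-ordered)."""


@dataclass(frozen=True)
class TransitionDetection:
    """Extremes, half-amplitude level and detected transition time."""

    t1_s: float            # time of the first extreme (minimum for a rise)
    t2_s: float            # time of the second extreme (maximum for a rise)
    f_t1: float
    f_t2: float
    t_median_s: float

    @property
    def half_level(self) -> float:
        return 0.5 * (self.f_t1 + self.f_t2)


@dataclass
class SynchronizedCell:
    """One cell's traces on time axes shifted so calcium t_median = 0."""

    calcium_t: np.ndarray
    calcium_values: np.ndarray
    area_t: np.ndarray | None
    area_values: np.ndarray | None
    force_t: np.ndarray | None
    force_values: np.ndarray | None
    calcium_transition: TransitionDetection
    area_transition: TransitionDetection | None
    lag_area_s: float | None
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S


def _extremes(
    t: np.ndarray, values: np.ndarray, direction: str, rank: int = 0
) -> tuple[int, int]:
    """Indices of the first/second extreme; rank > 0 picks the
    (rank+1)-th most extreme sample (used for the stability check)."""
    order_min = np.argsort(values, kind="stable")
    order_max = order_min[::-1]
    if direction == "rise":
        i1 = int(order_min[min(rank, len(values) - 1)])
        i2 = int(order_max[min(rank, len(values) - 1)])
    elif direction == "fall":
        i1 = int(order_max[min(rank, len(values) - 1)])
        i2 = int(order_min[min(rank, len(values) - 1)])
    else:
        raise ValueError("direction must be 'rise' or 'fall'")
    return i1, i2


def detect_transition(
    timestamps_s: np.ndarray,
    values: np.ndarray,
    direction: str = "rise",
    presmooth: bool = True,
    interpolate: bool = True,
    extreme_rank: int = 0,
) -> TransitionDetection:
    """Find the half-maximal transition time of a monotone-trend trace.

    The extremes f(t1) (minimum, for a rise) and f(t2) (maximum) are
    located on a lightly smoothed copy (3-sample median filter) so single
    noisy samples do not define the amplitude; ``presmooth=False`` uses
    raw extremes.  The half-amplitude level is (f(t1)+f(t2))/2, and of all
    level crossings between t1 and t2 the one closest to t2 is returned,
    linearly interpolated between the bracketing samples (or snapped to
    the nearer sample when ``interpolate=False``).

    Raises :class:`NoTransitionError` for flat traces and ValueError when
    the maximum precedes the minimum in rise mode (no rising transition).
    """
    t = np.asarray(timestamps_s, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    if len(v) < 4:
        raise ValueError("need at least 4 finite samples")
    v_s = medfilt(v, kernel_size=3) if presmooth else v

    i1, i2 = _extremes(t, v_s, direction, rank=extreme_rank)
    f1, f2 = float(v_s[i1]), float(v_s[i2])
    if f1 == f2:
        raise NoTransitionError("flat trace: extremes coincide")
    if t[i1] >= t[i2]:
        raise ValueError(
            f"no {direction} transition: second extreme at t={t[i2]:.3g} s "
            f"precedes first extreme at t={t[i1]:.3g} s"
        )
    half = 0.5 * (f1 + f2)

    # crossings of the half level between t1 and t2, evaluated on the
    # smoothed trace; choose the one closest to t2
    seg = slice(i1, i2 + 1)
    ts, vs = t[seg], v_s[seg]
    above = vs >= half if direction == "rise" else vs <= half
    crossing_t = None
    for j in range(len(vs) - 1, 0, -1):
        if above[j] and not above[j - 1]:
            if interpolate and vs[j] != vs[j - 1]:
                frac = (half - vs[j - 1]) / (vs[j] - vs[j - 1])
                crossing_t = float(ts[j - 1] + frac * (ts[j] - ts[j - 1]))
            else:
                crossing_t = float(ts[j] if abs(vs[j] - half) <= abs(vs[j - 1] - half) else ts[j - 1])
            break
    if crossing_t is None:
        # degenerate: the very first sample already sits above the level
        crossing_t = float(ts[np.argmax(above)])
    return TransitionDetection(float(t[i1]), float(t[i2]), f1, f2, crossing_t)


def synchronize(
    calcium_t: np.ndarray,
    calcium_values: np.ndarray,
    area_t: np.ndarray | None = None,
    area_values: np.ndarray | None = None,
    force_t: np.ndarray | None = None,
    force_values: np.ndarray | None = None,
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S,
) -> SynchronizedCell:
    """Shift all modalities so the calcium half-rise sits at t = 0.

    The calcium transition must exist (cells without one are excluded as
    "no calcium flux" upstream).  The area transition is optional: in the
    low-stimulus phenotype no clear area increase occurs, in which case
    the lag is marked missing and the cell retained.
    """
    ca = detect_transition(calcium_t, calcium_values, "rise")
    t0 = ca.t_median_s

    area_det: TransitionDetection | None = None
    lag: float | None = None
    if area_t is not None and area_values is not None:
        try:
            area_det = detect_transition(area_t, area_values, "rise")
            lag = area_det.t_median_s - t0
        except (NoTransitionError, ValueError):
            area_det = None

    return SynchronizedCell(
        calcium_t=np.asarray(calcium_t, dtype=np.float64) - t0,
        calcium_values=np.asarray(calcium_values, dtype=np.float64),
        area_t=None if area_t is None else np.asarray(area_t, dtype=np.float64) - t0,
        area_values=None if area_values is None else np.asarray(area_values, dtype=np.float64),
        force_t=None if force_t is None else np.asarray(force_t, dtype=np.float64) - t0,
        force_values=None if force_values is None else np.asarray(force_values, dtype=np.float64),
        calcium_transition=TransitionDetection(
            ca.t1_s - t0, ca.t2_s - t0, ca.f_t1, ca.f_t2, 0.0
        ),
        area_transition=None if area_det is None else TransitionDetection(
            area_det.t1_s - t0, area_det.t2_s - t0, area_det.f_t1, area_det.f_t2,
            area_det.t_median_s - t0,
        ),
        lag_area_s=lag,
        cycle_period_s=cycle_period_s,
    )


def coupling_points(
    cell: SynchronizedCell,
    window_s: tuple[float, float] = DEFAULT_COUPLING_WINDOW_S,
) -> np.ndarray:
    """(area µm², normalized ratio) pairs at the cycle times inside a window.

    One pair per illumination-cycle time strictly inside ``window_s`` on
    the synchronized axis (t = 0 at the calcium half-rise), ordered by
    time; at a 4 s cadence the default (−50, +100) s window yields 37
    pairs.  Both traces are linearly interpolated at the cycle times.
    Returns an (n, 2) array of (area, ratio) pairs.
    """
    if cell.area_t is None or cell.area_values is None:
        raise ValueError("cell has no area trace")
    # cycle grid anchored at the frame nearest t = 0
    anchor = float(cell.calcium_t[np.argmin(np.abs(cell.calcium_t))])
    anchor = anchor - round(anchor / cell.cycle_period_s) * cell.cycle_period_s
    times = cycle_frame_times(anchor, window_s, cell.cycle_period_s)
    # only report pairs where both traces actually have samples
    lo = max(cell.calcium_t[0], cell.area_t[0])
    hi = min(cell.calcium_t[-1], cell.area_t[-1])
    times = times[(times >= lo) & (times <= hi)]
    if len(times) == 0:
        return np.empty((0, 2))
    area = np.interp(times, cell.area_t, cell.area_values)
    ratio = np.interp(times, cell.calcium_t, cell.calcium_values)
    return np.column_stack([area, ratio])
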