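"""Cohort-level QC accounting, synchronized medians, and comparisons.

Single-cell recordings on the platform fail for well-defined reasons —
multiple cells or debris on the cantilever, premature bilayer contact,
dead cells, an elevated basal Fura-2 ratio, excessive movement,
insufficient TCR signal-to-noise, or absence of a calcium flux — and the
exclusion accounting must close exactly: category percentages plus the
acceptance fraction sum to 100%.  Accepted cells are synchronized on the
calcium half-rise and summarized as pointwise median traces with
bootstrap confidence bands; distributions are compared with the
two-sided two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import EXCLUSION_CATEGORIES
from .event_detection import SynchronizedCell

__all__ = [
    "QCRules",
    "CellRecord",
    "CohortSummary",
    "apply_qc",
    "exclusion_table",
    "acceptance_fraction",
    "median_trace_ci",
    "compare_distributions",
]

CONDITIONS = ("high+ICAM1+B71", "high+B71", "low")

#: fixed priority used to assign the single primary exclusion reason when
#: several flags are raised (ordered as in the platform's workflow)
EXCLUSION_PRIORITY = EXCLUSION_CATEGORIES


@dataclass(frozen=True)
class QCRules:
    """Thresholds operationalizing the exclusion categories.

    ``max_basal_ratio``: absolute basal Fura-2 ratio above which the cell
    counts as pre-activated (the indicator ratio, not the normalized
    trace).  ``min_flux_fold``: minimum normalized peak for a calcium
    flux.  ``min_tcr_snr``: minimum TCR contrast (cell minus background,
    in background-SD units).  ``max_movement_um``: maximum RMS excursion
    of the cell centroid.  ``min_mobile_fraction``: bilayer-QC gate from
    the fluorescence-recovery measurement, supplied as an annotation.
    """

    max_basal_ratio: float = 1.3
    min_flux_fold: float = 1.4
    min_tcr_snr: float = 5.0
    max_movement_um: float = 1.0
    min_mobile_fraction: float = 0.80
    basal_window_s: tuple[float, float] = (0.0, 16.0)


@dataclass
class CellRecord:
    """One cell's traces, QC flags and condition label."""

    cell_id: str
    condition: str
    calcium_t: np.ndarray | None = None
    calcium_ratio: np.ndarray | None = None
    calcium_normalized: np.ndarray | None = None
    area_t: np.ndarray | None = None
    area_um2: np.ndarray | None = None
    force_t: np.ndarray | None = None
    force_nN: np.ndarray | None = None
    tcr_snr: float | None = None
    movement_um: float | None = None
    mobile_fraction: float | None = None
    manual_flags: dict[str, bool] = field(default_factory=dict)
    qc_flags: dict[str, bool] = field(default_factory=dict)
    exclusion_reason: str | None = None
    synchronized: SynchronizedCell | None = None


def _flag_cell(cell: CellRecord, rules: QCRules) -> dict[str, bool]:
    from .event_detection import detect_transition, NoTransitionError

    flags = {c: bool(cell.manual_flags.get(c, False)) for c in EXCLUSION_CATEGORIES}

    if cell.calcium_t is not None and cell.calcium_ratio is not None:
        lo, hi = rules.basal_window_s
        basal_sel = (cell.calcium_t >= lo) & (cell.calcium_t <= hi)
        basal = cell.calcium_ratio[basal_sel]
        basal = basal[np.isfinite(basal)]
        if basal.size and basal.mean() > rules.max_basal_ratio:
            flags["elevated_baseline"] = True
        # calcium flux: a detectable rising transition with sufficient fold
        ratio = cell.calcium_ratio[np.isfinite(cell.calcium_ratio)]
        fold = ratio.max() / basal.mean() if basal.size and basal.mean() > 0 else 1.0
        has_transition = True
        try:
            detect_transition(cell.calcium_t, cell.calcium_ratio, "rise")
        except (NoTransitionError, ValueError):
            has_transition = False
        if not has_transition or fold < rules.min_flux_fold:
            flags["no_calcium_flux"] = True

    if cell.tcr_snr is not None and cell.tcr_snr < rules.min_tcr_snr:
        flags["insufficient_snr"] = True
    if cell.movement_um is not None and cell.movement_um > rules.max_movement_um:
        flags["excessive_movement"] = True
    if cell.mobile_fraction is not None and cell.mobile_fraction < rules.min_mobile_fraction:
        # a failed bilayer invalidates the recording wholesale
        flags["insufficient_snr"] = True
    return flags


def apply_qc(
    cells: list[CellRecord], rules: QCRules = QCRules()
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Flag every cell, assign one primary exclusion reason, tabulate.

    Returns the accepted cells and an exclusion table with one row per
    category plus an "accepted" row; percentages sum to 100 exactly.
    Flags derive from the traces and annotations; manually annotated
    categories (e.g. multiple cells on the cantilever) enter through
    ``manual_flags``.
    """
    accepted: list[CellRecord] = []
    for cell in cells:
        cell.qc_flags = _flag_cell(cell, rules)
        cell.exclusion_reason = next(
            (c for c in EXCLUSION_PRIORITY if cell.qc_flags.get(c)), None
        )
        if cell.exclusion_reason is None:
            accepted.append(cell)
    table = exclusion_table([c.exclusion_reason for c in cells])
    return accepted, table


def exclusion_table(reasons: list[str | None]) -> pd.DataFrame:
    """Per-category counts/percentages; accepted = 100% − Σ exclusions."""
    n = len(reasons)
    rows = []
    for cat in EXCLUSION_CATEGORIES:
        count = sum(r == cat for r in reasons)
        rows.append({"category": cat, "n": count, "percent": 100.0 * count / n if n else 0.0})
    n_acc = sum(r is None for r in reasons)
    rows.append({"category": "accepted", "n": n_acc,
                 "percent": 100.0 - sum(r["percent"] for r in rows)})
    return pd.DataFrame(rows)


def acceptance_fraction(exclusion_percentages: list[float] | np.ndarray) -> float:
    """Acceptance percentage implied by per-category exclusion percentages."""
    return 100.0 - float(np.sum(exclusion_percentages))


@dataclass
class CohortSummary:
    """Synchronized median trace with a bootstrap confidence band."""

    time_s: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_cells: int
    level: float
    n_boot: int


def median_trace_ci(
    times: list[np.ndarray],
    values: list[np.ndarray],
    grid_s: np.ndarray | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
) -> CohortSummary:
    """Pointwise median of synchronized traces with a percentile-bootstrap CI.

    Traces are linearly interpolated onto a common time grid (default: the
    overlap of all traces at the median sampling step).  The bootstrap
    resamples whole cells with replacement (1000 subsamples by default),
    respecting within-cell correlation; the band is the percentile
    interval of the resampled pointwise medians.  Deterministic for a
    fixed seed.
    """
    if len(times) != len(values):
        raise ValueError("times and values lists must have equal length")
    n_cells = len(times)
    if n_cells < 3:
        raise ValueError("need at least 3 traces for a meaningful band")
    if grid_s is None:
        lo = max(float(t[0]) for t in times)
        hi = min(float(t[-1]) for t in times)
        if hi <= lo:
            raise ValueError("traces share no common time span")
        step = float(np.median([np.median(np.diff(t)) for t in times]))
        grid_s = np.arange(lo, hi + step / 2, step)
    mat = np.vstack([np.interp(grid_s, t, v) for t, v in zip(times, values)])
    med = np.median(mat, axis=0)

    rng = np.random.default_rng(seed)
    boot_meds = np.empty((n_boot, len(grid_s)))
    for b in range(n_boot):
        idx = rng.integers(0, n_cells, size=n_cells)
        boot_meds[b] = np.median(mat[idx], axis=0)
    alpha = 1.0 - level
    ci_low = np.quantile(boot_meds, alpha / 2, axis=0)
    ci_high = np.quantile(boot_meds, 1 - alpha / 2, axis=0)
    return CohortSummary(np.asarray(grid_s), med, ci_low, ci_high, n_cells, level, n_boot)


def compare_distributions(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test (statistic D, p-value)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
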