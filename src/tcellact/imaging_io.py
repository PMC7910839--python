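"""Image-stack and AFM-trace I/O with acquisition timing.

The experimental platform records three image channels on a fixed
illumination cycle (two Fura-2 excitation channels in epi configuration,
one TCR channel in TIRF configuration with two frames per cycle) and one
cantilever-deflection trace sampled at high rate.  This module holds the
containers for those recordings, the multi-page TIFF / CSV readers and
writers, and the arithmetic of the illumination cycle's frame timing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionMetadata",
    "ImageStack",
    "ForceTraceRaw",
    "FormatError",
    "read_stack",
    "write_stack",
    "read_force_trace",
    "write_force_trace",
    "cycle_frame_times",
]

#: Camera pixel size in the object plane, µm per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.160
#: Illumination-cycle period, s.
DEFAULT_CYCLE_PERIOD_S = 4.0
#: Cantilever-deflection sampling rate, Hz.
DEFAULT_AFM_RATE_HZ = 10_000.0

CHANNELS = ("ca340", "ca375", "tcr")


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Static acquisition parameters shared by all frames of a recording."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S
    afm_rate_hz: float = DEFAULT_AFM_RATE_HZ
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.cycle_period_s <= 0 or self.afm_rate_hz <= 0:
            raise ValueError("acquisition metadata values must be positive")
        if self.channel is not None and self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")


@dataclass
class ImageStack:
    """Ordered sequence of single-channel frames with per-frame timestamps.

    ``frames`` has shape (n_frames, n_rows, n_cols) in camera counts;
    ``timestamps_s`` is strictly increasing with one entry per frame.
    Pixel coordinates are 0-based (row, col) with pixel centers at integer
    coordinates.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    metadata: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n_frames, rows, cols) array")
        if len(self.timestamps_s) != len(self.frames):
            raise FormatError("one timestamp per frame required")
        if len(self.timestamps_s) > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise FormatError("timestamps must be strictly increasing")
        if np.any(self.frames < 0):
            raise FormatError("camera counts must be non-negative")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]


@dataclass
class ForceTraceRaw:
    """Uniformly sampled cantilever force trace.

    Sign convention: negative = cell pulls toward the surface, positive =
    cell pushes away from it.  The same convention is kept after drift
    correction, so pulling events appear at negative force throughout.
    """

    time_s: np.ndarray
    deflection_nN: np.ndarray
    metadata: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.deflection_nN = np.asarray(self.deflection_nN, dtype=np.float64)
        if self.time_s.shape != self.deflection_nN.shape or self.time_s.ndim != 1:
            raise FormatError("time and deflection must be equal-length 1-D arrays")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise FormatError("time samples must be strictly increasing")
            # sampling must be uniform at the stated rate within 1%
            nominal = 1.0 / self.metadata.afm_rate_hz
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise FormatError(
                    f"sampling non-uniform or off-rate: expected {nominal:.3e} s intervals"
                )

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def rate_hz(self) -> float:
        return self.metadata.afm_rate_hz


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF plus a JSON timing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = {
        "timestamps_s": stack.timestamps_s.tolist(),
        "pixel_size_um": stack.metadata.pixel_size_um,
        "cycle_period_s": stack.metadata.cycle_period_s,
        "channel": stack.metadata.channel,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_stack(
    path: str | Path,
    channel: str | None = None,
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> ImageStack:
    """Read a multi-page TIFF stack.

    Per-frame timestamps come from the JSON sidecar written by
    :func:`write_stack`; without a sidecar they are synthesized as
    ``i * cycle_period_s`` (frame index 0 = first acquired cycle).
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:  # single-page file
        frames = frames[np.newaxis]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2-D frames, got shape {frames.shape}")
    if frames.size == 0:
        raise FormatError(f"empty TIFF stack: {path}")

    sidecar_path = path.with_suffix(path.suffix + ".json")
    timestamps = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        timestamps = np.asarray(sidecar.get("timestamps_s"), dtype=np.float64)
        pixel_size_um = float(sidecar.get("pixel_size_um", pixel_size_um))
        cycle_period_s = float(sidecar.get("cycle_period_s", cycle_period_s))
        channel = channel or sidecar.get("channel")
    if timestamps is None or len(timestamps) != len(frames):
        timestamps = np.arange(len(frames), dtype=np.float64) * cycle_period_s

    meta = AcquisitionMetadata(
        pixel_size_um=pixel_size_um, cycle_period_s=cycle_period_s, channel=channel
    )
    return ImageStack(frames=frames, timestamps_s=timestamps, metadata=meta)


# ---------------------------------------------------------------------------
# AFM traces
# ---------------------------------------------------------------------------

def write_force_trace(path: str | Path, trace: ForceTraceRaw) -> None:
    """Write a force trace as a two-column CSV (time_s, force_nN)."""
    pd.DataFrame({"time_s": trace.time_s, "force_nN": trace.deflection_nN}).to_csv(
        Path(path), index=False
    )


def read_force_trace(
    path: str | Path, afm_rate_hz: float = DEFAULT_AFM_RATE_HZ
) -> ForceTraceRaw:
    """Read a delimited time/force table; validates uniform sampling."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read force trace {path}: {exc}") from exc
    cols = {c.lower().strip(): c for c in table.columns}
    tcol = next((cols[k] for k in ("time_s", "time", "t") if k in cols), None)
    fcol = next((cols[k] for k in ("force_nn", "force", "deflection_nn") if k in cols), None)
    if tcol is None or fcol is None:
        raise FormatError(f"{path}: expected time_s and force_nN columns, got {list(table.columns)}")
    time_s = table[tcol].to_numpy(dtype=np.float64)
    force = table[fcol].to_numpy(dtype=np.float64)
    if len(time_s) > 1 and np.any(np.diff(time_s) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    meta = AcquisitionMetadata(afm_rate_hz=afm_rate_hz)
    return ForceTraceRaw(time_s=time_s, deflection_nN=force, metadata=meta)


# ---------------------------------------------------------------------------
# Illumination-cycle timing
# ---------------------------------------------------------------------------

def cycle_frame_times(
    t_ref_s: float,
    window_s: tuple[float, float],
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S,
) -> np.ndarray:
    """Frame times ``t_ref_s + k * cycle_period_s`` strictly inside a window.

    The window is open at both ends: a frame exactly on an endpoint is
    excluded.  With a frame at the reference time, the (−50, +100) s window
    at a 4 s cadence contains exactly 37 frame times (−48 … +96 s).

    Parameters
    ----------
    t_ref_s : reference time coinciding with one frame.
    window_s : (lo, hi) open interval in the same time axis as ``t_ref_s``.
    cycle_period_s : spacing between frames; must be positive.
    """
    if cycle_period_s <= 0:
        raise ValueError("cycle_period_s must be positive")
    lo, hi = window_s
    if hi <= lo:
        return np.empty(0, dtype=np.float64)
    # integer k with lo < t_ref + k*p < hi (strict at both ends); start one
    # step outside the bracket and walk in, so exact-integer ratios cannot
    # skip a valid frame
    k_lo = int(np.floor((lo - t_ref_s) / cycle_period_s)) - 1
    while t_ref_s + k_lo * cycle_period_s <= lo:
        k_lo += 1
    k_hi = int(np.ceil((hi - t_ref_s) / cycle_period_s)) + 1
    while t_ref_s + k_hi * cycle_period_s >= hi:
        k_hi -= 1
    if k_hi < k_lo:
        return np.empty(0, dtype=np.float64)
    k = np.arange(k_lo, k_hi + 1)
    return t_ref_s + k * cycle_period_s


def replace_metadata(stack: ImageStack, **kwargs) -> ImageStack:
    """Return a copy of ``stack`` with updated metadata fields."""
    return ImageStack(
        frames=stack.frames.copy(),
        timestamps_s=stack.timestamps_s.copy(),
        metadata=replace(stack.metadata, **kwargs),
    )
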