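"""Ratiometric Fura-2 calcium analysis.

The calcium readout is the per-cycle mean of the pixel-wise ratio of the
background-subtracted 340 nm and 375 nm excitation images, taken over a
circular region of interest (default radius 3.2 µm) around the cell
center, and normalized by the mean pre-activation (basal) ratio.  The
ratio is independent of dye load, so the normalized trace reports the
fold change of intracellular calcium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging_io import ImageStack

__all__ = [
    "CalciumTrace",
    "subtract_background",
    "ratio_image",
    "roi_mean",
    "normalize_trace",
    "intensity_centroid",
    "calcium_trace",
]

#: ROI radius around the cell center, µm (chosen conservatively so the
#: analyzed region lies entirely within the T-cell).
DEFAULT_ROI_RADIUS_UM = 3.2
#: Border width (px) used for the per-frame scalar background estimate.
BACKGROUND_BORDER_PX = 10
#: Pixels whose 375 nm signal falls below this multiple of the read-noise
#: scale are invalidated rather than producing unstable ratios.
DENOMINATOR_FLOOR_SIGMAS = 5.0


@dataclass
class CalciumTrace:
    """Per-cycle ROI-mean Fura-2 ratio for one cell."""

    timestamps_s: np.ndarray
    ratio: np.ndarray
    normalized: np.ndarray | None = None
    n_valid_pixels: np.ndarray | None = None
    roi_center_px: tuple[float, float] | None = None
    roi_radius_um: float = DEFAULT_ROI_RADIUS_UM

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
        self.ratio = np.asarray(self.ratio, dtype=np.float64)
        if self.timestamps_s.shape != self.ratio.shape:
            raise ValueError("timestamps and ratio must have equal length")


def estimate_border_background(frame: np.ndarray, border_px: int = BACKGROUND_BORDER_PX) -> float:
    """Median of a border ring of the frame — the default background proxy."""
    b = min(border_px, min(frame.shape) // 2)
    mask = np.zeros(frame.shape, dtype=bool)
    mask[:b, :] = mask[-b:, :] = True
    mask[:, :b] = mask[:, -b:] = True
    return float(np.median(frame[mask]))


def subtract_background(
    stack: ImageStack,
    method: str | float = "border-median",
    border_px: int = BACKGROUND_BORDER_PX,
) -> ImageStack:
    """Remove a per-frame scalar background from every frame.

    ``method`` is either the string ``"border-median"`` (median of a
    10-px frame border, per frame) or a fixed scalar background in counts.
    Frames whose background estimate reaches the frame maximum carry no
    signal; they are masked to NaN with a warning rather than going
    negative everywhere.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    out = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        if isinstance(method, str):
            if method != "border-median":
                raise ValueError(f"unknown background method {method!r}")
            bg = estimate_border_background(frame, border_px)
        else:
            bg = float(method)
        if bg >= frame.max():
            warnings.warn(f"frame {i}: background {bg:.1f} >= frame maximum; frame masked")
            out[i] = np.nan
        else:
            out[i] = frame - bg
    # bypass validation: subtracted frames are legitimately negative/NaN
    result = ImageStack.__new__(ImageStack)
    result.frames = out
    result.timestamps_s = stack.timestamps_s.copy()
    result.metadata = stack.metadata
    return result


def ratio_image(
    frame340: np.ndarray,
    frame375: np.ndarray,
    floor: float | None = None,
    read_noise_counts: float = 10.0,
) -> np.ndarray:
    """Pixel-wise 340/375 excitation ratio of background-subtracted frames.

    Pixels whose 375 nm (denominator) value is at or below the floor
    (default 5 × the read-noise scale) are returned as NaN and excluded
    from downstream ROI means.
    """
    frame340 = np.asarray(frame340, dtype=np.float64)
    frame375 = np.asarray(frame375, dtype=np.float64)
    if frame340.shape != frame375.shape:
        raise ValueError("340 and 375 frames must share one shape")
    if floor is None:
        floor = DENOMINATOR_FLOOR_SIGMAS * read_noise_counts
    valid = frame375 > floor
    out = np.full(frame340.shape, np.nan)
    np.divide(frame340, frame375, out=out, where=valid)
    return out


def roi_mean(
    ratio: np.ndarray,
    center_px: tuple[float, float],
    radius_um: float = DEFAULT_ROI_RADIUS_UM,
    pixel_size_um: float = 0.160,
) -> float:
    """Mean of valid ratio pixels whose centers lie within the ROI circle.

    Returns NaN when the circle contains no valid pixel.  Raises if the
    center is outside the image.
    """
    ratio = np.asarray(ratio, dtype=np.float64)
    r0, c0 = center_px
    if not (0 <= r0 <= ratio.shape[0] - 1 and 0 <= c0 <= ratio.shape[1] - 1):
        raise ValueError(f"ROI center {center_px} outside image {ratio.shape}")
    radius_px = radius_um / pixel_size_um
    rr, cc = np.indices(ratio.shape)
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    vals = ratio[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def normalize_trace(
    trace: CalciumTrace, basal_window: tuple[float, float]
) -> CalciumTrace:
    """Divide the ratio trace by its mean over the basal (pre-contact) window."""
    lo, hi = basal_window
    in_window = (trace.timestamps_s >= lo) & (trace.timestamps_s <= hi)
    basal = trace.ratio[in_window]
    basal = basal[np.isfinite(basal)]
    if basal.size < 3:
        raise ValueError("basal window must contain at least 3 valid samples")
    basal_mean = basal.mean()
    if basal_mean <= 0:
        raise ValueError("basal mean ratio must be positive")
    return CalciumTrace(
        timestamps_s=trace.timestamps_s,
        ratio=trace.ratio,
        normalized=trace.ratio / basal_mean,
        n_valid_pixels=trace.n_valid_pixels,
        roi_center_px=trace.roi_center_px,
        roi_radius_um=trace.roi_radius_um,
    )


def intensity_centroid(frame: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid, used as the default cell-center estimate."""
    frame = np.clip(np.asarray(frame, dtype=np.float64), 0, None)
    total = frame.sum()
    if total <= 0:
        return ((frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0)
    rr, cc = np.indices(frame.shape)
    return (float((rr * frame).sum() / total), float((cc * frame).sum() / total))


def calcium_trace(
    stack340: ImageStack,
    stack375: ImageStack,
    center_px: tuple[float, float] | None = None,
    roi_radius_um: float = DEFAULT_ROI_RADIUS_UM,
    basal_window: tuple[float, float] | None = None,
    background: str | float = "border-median",
    read_noise_counts: float = 10.0,
) -> CalciumTrace:
    """Full per-cell calcium pipeline: background → ratio → ROI mean → normalize.

    The cell center defaults to the intensity-weighted centroid of the
    first background-subtracted 340 nm frame and is held fixed for the
    whole trace.  When ``basal_window`` is given the trace is normalized
    by its mean ratio over that window.
    """
    if len(stack340) != len(stack375):
        raise ValueError("340 and 375 stacks must have equal frame counts")
    s340 = subtract_background(stack340, background)
    s375 = subtract_background(stack375, background)
    px = stack340.metadata.pixel_size_um
    if center_px is None:
        center_px = intensity_centroid(np.nan_to_num(s340.frames[0]))
    ratios = np.empty(len(s340))
    n_valid = np.empty(len(s340), dtype=int)
    for i in range(len(s340)):
        rimg = ratio_image(s340.frames[i], s375.frames[i], read_noise_counts=read_noise_counts)
        ratios[i] = roi_mean(rimg, center_px, roi_radius_um, px)
        rr, cc = np.indices(rimg.shape)
        inside = (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= (roi_radius_um / px) ** 2
        n_valid[i] = int(np.isfinite(rimg[inside]).sum())
    trace = CalciumTrace(
        timestamps_s=stack340.timestamps_s,
        ratio=ratios,
        n_valid_pixels=n_valid,
        roi_center_px=center_px,
        roi_radius_um=roi_radius_um,
    )
    if basal_window is not None:
        trace = normalize_trace(trace, basal_window)
    return trace
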