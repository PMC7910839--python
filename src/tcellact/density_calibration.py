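"""Ligand surface-density calibration from single-molecule photometry.

The areal density of fluorescent ligand on a supported lipid bilayer is
obtained by dividing the bulk fluorescence signal (counts per pixel,
background-subtracted) by the mean integrated brightness of a single
fluorophore, measured on a sparsely labeled bilayer where individual
emitters are well separated.  Emitter localization follows the
Crocker–Grier recipe (band-pass filtering, dilation-based local maxima,
intensity-centroid refinement); brightness is measured by aperture
photometry in a 7-px-diameter foreground circle with an annular local
background, excluding ring pixels affected by neighboring signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MoleculeDetection",
    "DensityEstimate",
    "detect_molecules",
    "aperture_photometry",
    "estimate_density",
    "calibrate_density",
]

#: Foreground circle diameter (px) for photometry.
FG_DIAMETER_PX = 7
#: Background ring radii (px): from the aperture edge to the outer radius.
RING_INNER_PX = 3.5
RING_OUTER_PX = 6.0


@dataclass(frozen=True)
class MoleculeDetection:
    """One localized emitter with aperture-photometry results."""

    position_px: tuple[float, float]             # sub-pixel (row, col)
    integrated_counts: float                     # background-subtracted sum
    local_background_counts_per_px: float


@dataclass(frozen=True)
class DensityEstimate:
    """Ligand density from bulk / single-molecule brightness division."""

    molecules_per_um2: float
    mean_single_brightness_counts: float
    mean_bulk_counts_per_px: float
    n_molecules_used: int


def _bandpass(image: np.ndarray, feature_size_px: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass: keep spot-scale structure."""
    img = np.asarray(image, dtype=np.float64)
    low = ndimage.gaussian_filter(img, sigma=feature_size_px / 2.0)
    background = ndimage.gaussian_filter(img, sigma=feature_size_px * 2.0)
    return low - background


def detect_molecules(
    image: np.ndarray,
    feature_size_px: float = 2.0,
    percentile: float = 99.5,
    threshold_sigmas: float = 8.0,
    min_separation_px: float = float(FG_DIAMETER_PX),
    border_px: float = RING_OUTER_PX,
    max_second_moment_px2: float = 2.6,
) -> list[MoleculeDetection]:
    """Locate well-separated single emitters in a sparse field.

    Candidates are local maxima of the band-passed image above the given
    intensity percentile; positions are refined to sub-pixel precision by
    the intensity centroid of a small neighborhood.  Detections closer
    than ``min_separation_px`` (one aperture diameter) to each other, or
    within ``border_px`` + aperture of the image border, are discarded so
    photometry apertures never overlap or clip.
    """
    image = np.asarray(image, dtype=np.float64)
    bp = _bandpass(image, feature_size_px)
    footprint = np.ones((5, 5), dtype=bool)
    is_max = bp == ndimage.grey_dilation(bp, footprint=footprint)
    # absolute floor (robust noise scale) keeps blank images detection-free;
    # the percentile cut keeps only the brightest maxima in busy fields
    noise_scale = 1.4826 * float(np.median(np.abs(bp - np.median(bp))))
    cutoff = max(np.percentile(bp, percentile), threshold_sigmas * noise_scale)
    cand = np.argwhere(is_max & (bp > cutoff))
    if len(cand) == 0:
        return []

    # sub-pixel refinement: intensity centroid in a (2w+1)² neighborhood
    w = int(np.ceil(feature_size_px))
    positions = []
    for r, c in cand:
        r0, r1 = max(0, r - w), min(image.shape[0], r + w + 1)
        c0, c1 = max(0, c - w), min(image.shape[1], c + w + 1)
        patch = bp[r0:r1, c0:c1]
        patch = np.clip(patch, 0, None)
        total = patch.sum()
        if total <= 0:
            positions.append((float(r), float(c)))
            continue
        rr, cc = np.indices(patch.shape)
        positions.append((r0 + float((rr * patch).sum() / total),
                          c0 + float((cc * patch).sum() / total)))
    positions = np.asarray(positions)

    # drop detections too close to each other (both of a close pair go)
    n = len(positions)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(positions[i] - positions[j])) < min_separation_px:
                keep[i] = keep[j] = False
    # drop detections whose aperture+ring would clip the border
    margin = border_px + RING_INNER_PX
    inside = (
        (positions[:, 0] >= margin)
        & (positions[:, 0] <= image.shape[0] - 1 - margin)
        & (positions[:, 1] >= margin)
        & (positions[:, 1] <= image.shape[1] - 1 - margin)
    )
    kept = positions[keep & inside]
    all_positions = [tuple(p) for p in positions]
    detections = [
        aperture_photometry(image, tuple(p), other_positions=all_positions)
        for p in kept
    ]
    # single-emitter shape screen: an unresolved emitter pair is wider than
    # the PSF; a sigma = 1 px Gaussian truncated at the 3.5 px aperture has
    # a radial second moment of ~2.0 px^2, so anything above
    # max_second_moment_px2 is rejected as non-single
    singles = []
    rr, cc = np.indices(image.shape)
    for det in detections:
        r0, c0 = det.position_px
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        fg = d2 <= (FG_DIAMETER_PX / 2.0) ** 2
        weights = np.clip(image[fg] - det.local_background_counts_per_px, 0, None)
        total = weights.sum()
        if total <= 0:
            continue
        if float((weights * d2[fg]).sum() / total) <= max_second_moment_px2:
            singles.append(det)
    return singles


def aperture_photometry(
    image: np.ndarray,
    position: tuple[float, float],
    fg_diameter_px: float = FG_DIAMETER_PX,
    ring_inner_px: float = RING_INNER_PX,
    ring_outer_px: float = RING_OUTER_PX,
    other_positions: list[tuple[float, float]] | None = None,
) -> MoleculeDetection:
    """Integrated brightness of one emitter by circular-aperture photometry.

    All pixel values within the foreground circle (pixel centers within
    fg_diameter/2 of the position) are summed; the local background is the
    per-pixel mean over a surrounding ring, excluding any ring pixel lying
    within an aperture radius of another detection; the background is then
    subtracted from the foreground sum pixel-wise.
    """
    image = np.asarray(image, dtype=np.float64)
    r0, c0 = position
    fg_radius = fg_diameter_px / 2.0
    margin = ring_outer_px
    if not (margin <= r0 <= image.shape[0] - 1 - margin
            and margin <= c0 <= image.shape[1] - 1 - margin):
        raise ValueError(f"aperture at {position} clipped by image border")
    rr, cc = np.indices(image.shape)
    d = np.hypot(rr - r0, cc - c0)
    fg = d <= fg_radius
    ring = (d > ring_inner_px) & (d <= ring_outer_px)
    if other_positions is not None:
        for (orow, ocol) in other_positions:
            if (orow, ocol) == (r0, c0):
                continue
            od = np.hypot(rr - orow, cc - ocol)
            ring &= od > fg_radius
    if not ring.any():
        raise ValueError("no usable background-ring pixels")
    bg = float(image[ring].mean())
    integrated = float(image[fg].sum() - bg * fg.sum())
    return MoleculeDetection((float(r0), float(c0)), integrated, bg)


def estimate_density(
    bulk: np.ndarray,
    sparse_detections: list[MoleculeDetection],
    pixel_size_um: float = 0.160,
    min_detections: int = 10,
) -> DensityEstimate:
    """Density = (bulk counts per pixel) / (single-molecule counts) / pixel area.

    ``bulk`` must already be background-subtracted.  Requires at least
    ``min_detections`` single-molecule measurements for a stable mean
    brightness.
    """
    if len(sparse_detections) < min_detections:
        raise ValueError(
            f"need >= {min_detections} single-molecule detections, got {len(sparse_detections)}"
        )
    values = np.array([d.integrated_counts for d in sparse_detections])
    # unresolved emitter pairs (~2x flux) and clipped/partial signals are
    # not single molecules; screen against the cohort median before averaging
    med = float(np.median(values))
    values = values[(values > 0.5 * med) & (values < 2.0 * med)]
    if values.size == 0:
        raise ValueError("no detections survive the single-molecule brightness screen")
    brightness = float(np.mean(values))
    if brightness <= 0:
        raise ValueError("mean single-molecule brightness must be positive")
    bulk_per_px = float(np.mean(np.asarray(bulk, dtype=np.float64)))
    density = (bulk_per_px / brightness) / pixel_size_um**2
    return DensityEstimate(
        molecules_per_um2=density,
        mean_single_brightness_counts=brightness,
        mean_bulk_counts_per_px=bulk_per_px,
        n_molecules_used=int(values.size),
    )


def calibrate_density(
    bulk_image: np.ndarray,
    sparse_image: np.ndarray,
    pixel_size_um: float = 0.160,
    bulk_background: float | str = "from-sparse",
    border_px: int = 10,
    **detect_kwargs,
) -> DensityEstimate:
    """End-to-end calibration from a bulk and a sparse calibration image.

    The bulk background defaults to the mean of the per-detection local
    backgrounds measured on the sparse image (same camera and
    illumination); pass a float to override.  The bulk signal is averaged
    over the full field minus a border.
    """
    detections = detect_molecules(np.asarray(sparse_image, dtype=np.float64), **detect_kwargs)
    if bulk_background == "from-sparse":
        if not detections:
            raise ValueError("no single-molecule detections to estimate background from")
        bg = float(np.mean([d.local_background_counts_per_px for d in detections]))
    else:
        bg = float(bulk_background)
    bulk = np.asarray(bulk_image, dtype=np.float64)
    b = border_px
    interior = bulk[b:-b, b:-b] if b > 0 else bulk
    return estimate_density(interior - bg, detections, pixel_size_um)
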