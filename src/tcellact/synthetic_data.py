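"""Synthetic multimodal T-cell recordings with known ground truth.

Emulates the phenomenology of a single T-cell lowered onto an activating
supported lipid bilayer (SLB): a pre-spreading "tip-toeing" phase of
transient microvillar point contacts in the TCR/TIRF channel, a sudden
sigmoidal spread of the close-contact area, a sigmoidal rise of the
Fura-2 excitation ratio from its basal level, and a cantilever deflection
trace carrying slow drift, white noise and nN-scale pull/push events.
Calibration fields of Gaussian emitters with a fixed integrated
brightness over a flat background mimic the sparse and bulk SLB images
used for ligand-density quantification.

All randomness flows from a single seed; identical scenarios produce
identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .imaging_io import (
    AcquisitionMetadata,
    ForceTraceRaw,
    ImageStack,
    DEFAULT_CYCLE_PERIOD_S,
    DEFAULT_PIXEL_SIZE_UM,
    DEFAULT_AFM_RATE_HZ,
    write_stack,
    write_force_trace,
)

__all__ = [
    "NoiseModel",
    "ForceEvent",
    "SyntheticScenario",
    "SyntheticDataset",
    "CONDITION_PRESETS",
    "EXCLUSION_CATEGORIES",
    "generate_cell",
    "generate_calibration_images",
    "generate_cohort",
    "write_dataset",
]


def logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass(frozen=True)
class NoiseModel:
    """Camera and cantilever noise scales.

    The camera model is Gaussian read noise plus an intensity-proportional
    variance term standing in for shot noise: var = read² + shot·mean.
    """

    read_noise_counts: float = 10.0
    shot_noise_scale: float = 1.0
    deflection_rms_nN: float = 0.05


@dataclass(frozen=True)
class ForceEvent:
    """One pull (negative amplitude) or push (positive) episode.

    Rendered as a sin² pulse so the peak force equals ``amplitude_nN``
    exactly at ``onset_s + duration_s / 2``.
    """

    onset_s: float
    amplitude_nN: float
    duration_s: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.amplitude_nN))


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters of one synthetic cell recording."""

    seed: int = 0
    # timing
    duration_s: float = 400.0
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S
    contact_time_s: float = 20.0       # first T-cell/SLB contact (TCR signal appears)
    t_activation_s: float = 120.0      # true calcium half-rise time
    # calcium
    basal_ratio: float = 0.8
    ratio_fold: float = 3.0
    ca_rise_s: float = 6.0             # logistic timescale of the ratio rise
    # contact area
    area_plateau_um2: float = 50.0
    area_rise_s: float = 8.0           # logistic timescale of spreading
    area_lag_s: float = 4.0            # area half-rise lags calcium half-rise by this
    n_microvilli: int = 8
    # forces
    force_events: tuple[ForceEvent, ...] = (ForceEvent(140.0, -1.5, 40.0),)
    drift_coeffs: tuple[float, ...] = (0.2, 0.01)   # nN, nN/s, ... ascending powers of t
    # imaging geometry
    img_size_px: int = 128
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    cell_radius_um: float = 5.0
    background_counts: float = 100.0
    ca375_signal_counts: float = 400.0   # cell-interior 375 nm excitation signal
    tcr_signal_counts: float = 300.0     # close-contact TCR signal above background
    movement_step_px: float = 0.0        # per-cycle RMS random walk of the cell center
    # noise / calibration
    noise: NoiseModel = field(default_factory=NoiseModel)
    afm_rate_hz: float = DEFAULT_AFM_RATE_HZ
    emitter_density_per_um2: float = 5.0
    single_brightness_counts: float = 5000.0

    def __post_init__(self) -> None:
        if min(self.duration_s, self.cycle_period_s, self.ca_rise_s, self.area_rise_s) <= 0:
            raise ValueError("timescales must be positive")
        if self.basal_ratio <= 0:
            raise ValueError("basal_ratio must be positive")
        if self.ratio_fold < 1:
            raise ValueError("ratio_fold must be >= 1")
        if self.emitter_density_per_um2 < 0:
            raise ValueError("emitter density must be non-negative")

    # -- programmed time courses (ground truth) --

    def ratio_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Programmed Fura-2 ratio: logistic rise from the basal level."""
        z = (np.asarray(t, dtype=np.float64) - self.t_activation_s) / self.ca_rise_s
        return self.basal_ratio * (1.0 + (self.ratio_fold - 1.0) * logistic(z))

    def area_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Programmed close-contact area (µm²), half-rise lagging calcium."""
        t_half = self.t_activation_s + self.area_lag_s
        z = (np.asarray(t, dtype=np.float64) - t_half) / self.area_rise_s
        return self.area_plateau_um2 * logistic(z)


@dataclass
class SyntheticDataset:
    """One synthetic cell: image stacks per channel, force trace, ground truth."""

    stacks: dict[str, ImageStack]
    force: ForceTraceRaw | None
    ground_truth: SyntheticScenario
    cell_id: str = "cell-0"
    condition: str = "high+ICAM1+B71"
    true_exclusion: str | None = None    # injected QC defect category, if any


# presets for the three stimulation conditions used on the platform
CONDITION_PRESETS: dict[str, dict] = {
    # high pMHC density + adhesion (ICAM-1) + costimulation (B7-1): strong
    # activation, large spread area, nN pulls
    "high+ICAM1+B71": dict(
        area_plateau_um2=50.0, ratio_fold=3.0, t_activation_s=120.0,
        force_events=(ForceEvent(140.0, -1.5, 40.0),),
    ),
    # no ICAM-1: reduced spreading, pushes as well as pulls
    "high+B71": dict(
        area_plateau_um2=30.0, ratio_fold=3.0, t_activation_s=140.0,
        force_events=(ForceEvent(100.0, 0.8, 30.0), ForceEvent(160.0, -1.0, 40.0)),
    ),
    # low pMHC only: delayed, weaker calcium, little spreading, sub-nN forces
    "low": dict(
        area_plateau_um2=8.0, ratio_fold=1.8, t_activation_s=200.0,
        force_events=(ForceEvent(180.0, -0.2, 60.0),),
    ),
}

EXCLUSION_CATEGORIES = (
    "multiple_or_noncell_material",
    "premature_contact",
    "not_alive",
    "elevated_baseline",
    "excessive_movement",
    "insufficient_snr",
    "no_calcium_flux",
)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.indices((n, n), dtype=np.float64)
    return rr, cc


def _soft_disc(rr, cc, center, radius_px):
    """Anti-aliased disc mask in [0, 1] with a 1-px edge ramp."""
    d = np.hypot(rr - center[0], cc - center[1])
    return np.clip(radius_px + 0.5 - d, 0.0, 1.0)


def _gaussian_spot(rr, cc, center, integrated_counts, sigma_px):
    amp = integrated_counts / (2.0 * np.pi * sigma_px**2)
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return amp * np.exp(-d2 / (2.0 * sigma_px**2))


def _camera_noise(rng: np.random.Generator, mean_img: np.ndarray, noise: NoiseModel) -> np.ndarray:
    var = noise.read_noise_counts**2 + noise.shot_noise_scale * np.clip(mean_img, 0, None)
    img = mean_img + rng.standard_normal(mean_img.shape) * np.sqrt(var)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# single-cell generator
# ---------------------------------------------------------------------------

def generate_cell(
    scenario: SyntheticScenario,
    modalities: tuple[str, ...] = ("calcium", "tcr", "force"),
) -> SyntheticDataset:
    """Render one synthetic cell recording.

    The 340 nm and 375 nm stacks share one frame per illumination cycle at
    t = i·cycle_period; inside the cell footprint the background-subtracted
    340/375 ratio follows the programmed logistic.  The TCR stack holds two
    frames per cycle showing microvillar puncta from first contact onward
    and a spreading disc whose area follows the programmed curve.  The
    force trace is drift polynomial + white noise + sin² pull/push pulses.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_cycles = int(np.floor(sc.duration_s / sc.cycle_period_s))
    t_cycles = np.arange(n_cycles) * sc.cycle_period_s
    n = sc.img_size_px
    rr, cc = _grid(n)
    px = sc.pixel_size_um
    center0 = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
    cell_r_px = sc.cell_radius_um / px
    meta = dict(pixel_size_um=px, cycle_period_s=sc.cycle_period_s)

    # cell-center trajectory (random walk; scale 0 => static)
    steps = rng.standard_normal((n_cycles, 2)) * sc.movement_step_px
    centers = center0 + np.cumsum(steps, axis=0)
    centers = np.clip(centers, cell_r_px, n - 1 - cell_r_px)

    stacks: dict[str, ImageStack] = {}

    if "calcium" in modalities:
        ratio_t = np.asarray(sc.ratio_at(t_cycles))
        f340 = np.empty((n_cycles, n, n))
        f375 = np.empty((n_cycles, n, n))
        for i in range(n_cycles):
            cell = _soft_disc(rr, cc, centers[i], cell_r_px)
            m375 = sc.background_counts + sc.ca375_signal_counts * cell
            m340 = sc.background_counts + ratio_t[i] * sc.ca375_signal_counts * cell
            f375[i] = _camera_noise(rng, m375, sc.noise)
            f340[i] = _camera_noise(rng, m340, sc.noise)
        stacks["ca340"] = ImageStack(f340, t_cycles.copy(),
                                     AcquisitionMetadata(channel="ca340", **meta))
        stacks["ca375"] = ImageStack(f375, t_cycles.copy(),
                                     AcquisitionMetadata(channel="ca375", **meta))

    if "tcr" in modalities:
        # two TIRF frames per cycle (red laser fires before and after the
        # 375 nm exposure within each cycle)
        t_tcr = np.sort(np.concatenate([t_cycles + 2.501, t_cycles + 2.653]))
        area_t = np.asarray(sc.area_at(t_cycles))
        disc_r_px = np.sqrt(np.clip(area_t, 0, None) / np.pi) / px
        # microvillar puncta random-walk inside the cell footprint
        mv_pos = centers[0] + rng.standard_normal((sc.n_microvilli, 2)) * (cell_r_px / 3)
        frames = np.empty((2 * n_cycles, n, n))
        for i in range(n_cycles):
            t = t_cycles[i]
            mean = np.full((n, n), sc.background_counts)
            if t >= sc.contact_time_s:
                mv_pos = mv_pos + rng.standard_normal(mv_pos.shape) * 1.0
                # keep puncta within the cell footprint
                off = mv_pos - centers[i]
                d = np.hypot(off[:, 0], off[:, 1])
                too_far = d > 0.8 * cell_r_px
                mv_pos[too_far] = centers[i] + off[too_far] * (
                    0.8 * cell_r_px / d[too_far, None]
                )
                for p in mv_pos:
                    mean += _gaussian_spot(rr, cc, p, sc.tcr_signal_counts * 12.0, 1.3)
                if disc_r_px[i] > 0.5:
                    mean += sc.tcr_signal_counts * _soft_disc(rr, cc, centers[i], disc_r_px[i])
            frames[2 * i] = _camera_noise(rng, mean, sc.noise)
            frames[2 * i + 1] = _camera_noise(rng, mean, sc.noise)
        stacks["tcr"] = ImageStack(frames, t_tcr,
                                   AcquisitionMetadata(channel="tcr", **meta))

    force = None
    if "force" in modalities:
        t = np.arange(int(sc.duration_s * sc.afm_rate_hz)) / sc.afm_rate_hz
        f = np.polynomial.polynomial.polyval(t, np.asarray(sc.drift_coeffs))
        for ev in sc.force_events:
            in_ev = (t >= ev.onset_s) & (t < ev.onset_s + ev.duration_s)
            phase = (t[in_ev] - ev.onset_s) / ev.duration_s
            f[in_ev] += ev.amplitude_nN * np.sin(np.pi * phase) ** 2
        f += rng.standard_normal(t.shape) * sc.noise.deflection_rms_nN
        force = ForceTraceRaw(
            t, f, AcquisitionMetadata(afm_rate_hz=sc.afm_rate_hz, **meta)
        )

    return SyntheticDataset(stacks=stacks, force=force, ground_truth=sc)


# ---------------------------------------------------------------------------
# calibration-image generator
# ---------------------------------------------------------------------------

def generate_calibration_images(
    density_per_um2: float,
    single_brightness_counts: float = 5000.0,
    fov_um: float = 20.48,
    seed: int = 0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    sparse_density_per_um2: float = 0.1,
    background_counts: float = 100.0,
    spot_sigma_px: float = 1.0,
    noise: NoiseModel = NoiseModel(),
    gain: float = 1.0,
) -> tuple[ImageStack, ImageStack]:
    """Bulk and sparse SLB calibration images.

    The sparse image carries a Poisson number of well-separated emitters
    (fixed integrated brightness, Gaussian PSF) over a flat background and
    is used to measure the single-molecule brightness.  The bulk image has
    per-pixel mean = density · pixel_area · brightness + background and
    represents the ligand density to be quantified.  ``gain`` scales both
    images identically (density estimation must be invariant to it).
    """
    if density_per_um2 < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(fov_um / pixel_size_um))
    rr, cc = _grid(n)
    px_area = pixel_size_um**2
    meta = AcquisitionMetadata(pixel_size_um=pixel_size_um)

    bulk_mean = np.full((n, n), background_counts + density_per_um2 * px_area * single_brightness_counts)
    bulk = _camera_noise(rng, bulk_mean, noise) * gain

    # the sparse field cannot be denser than the bilayer it samples
    n_emitters = rng.poisson(min(sparse_density_per_um2, density_per_um2) * fov_um**2)
    sparse_mean = np.full((n, n), background_counts)
    for _ in range(n_emitters):
        pos = rng.uniform(0, n - 1, size=2)
        sparse_mean += _gaussian_spot(rr, cc, pos, single_brightness_counts, spot_sigma_px)
    sparse = _camera_noise(rng, sparse_mean, noise) * gain

    bulk_stack = ImageStack(bulk[np.newaxis], np.array([0.0]), meta)
    sparse_stack = ImageStack(sparse[np.newaxis], np.array([0.0]), meta)
    return bulk_stack, sparse_stack


# ---------------------------------------------------------------------------
# cohort generator with injected QC defects
# ---------------------------------------------------------------------------

def _inject_defect(sc: SyntheticScenario, category: str) -> SyntheticScenario:
    """Realize one exclusion category as a concrete signal modification."""
    if category == "elevated_baseline":
        return replace(sc, basal_ratio=sc.basal_ratio * 2.5)
    if category == "no_calcium_flux":
        return replace(sc, ratio_fold=1.0)
    if category == "insufficient_snr":
        return replace(sc, tcr_signal_counts=sc.noise.read_noise_counts * 0.5)
    if category == "excessive_movement":
        return replace(sc, movement_step_px=3.0)
    if category == "multiple_or_noncell_material":
        # a second cell's worth of signal: doubled footprint brightness
        return replace(sc, ca375_signal_counts=sc.ca375_signal_counts * 2.2)
    if category == "premature_contact":
        return replace(sc, contact_time_s=0.0)
    if category == "not_alive":
        # dead cells never flux and show a depressed, flat ratio
        return replace(sc, ratio_fold=1.0, basal_ratio=sc.basal_ratio * 0.5)
    raise ValueError(f"unknown exclusion category {category!r}")


def generate_cohort(
    n_cells: int,
    condition: str = "high+ICAM1+B71",
    exclusion_mix: dict[str, float] | None = None,
    seed: int = 0,
    scenario_template: SyntheticScenario | None = None,
    modalities: tuple[str, ...] = ("calcium", "tcr"),
) -> list[SyntheticDataset]:
    """Generate ``n_cells`` datasets, a fraction carrying injected defects.

    ``exclusion_mix`` maps exclusion categories to probabilities (sum ≤ 1);
    the remainder are clean cells with randomized activation times.  Each
    dataset carries its ground-truth exclusion label.
    """
    exclusion_mix = dict(exclusion_mix or {})
    unknown = set(exclusion_mix) - set(EXCLUSION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown exclusion categories: {sorted(unknown)}")
    p_total = sum(exclusion_mix.values())
    if p_total > 1.0 + 1e-12:
        raise ValueError("exclusion probabilities must sum to <= 1")

    base = scenario_template or SyntheticScenario()
    preset = CONDITION_PRESETS.get(condition, {})
    base = replace(base, **preset)
    rng = np.random.default_rng(seed)
    cats = list(exclusion_mix)
    probs = np.array([exclusion_mix[c] for c in cats] + [1.0 - p_total])

    cohort: list[SyntheticDataset] = []
    for i in range(n_cells):
        pick = rng.choice(len(probs), p=probs)
        category = cats[pick] if pick < len(cats) else None
        # randomize the activation time cell-to-cell
        jitter = rng.uniform(-0.15, 0.15) * base.t_activation_s
        sc = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            t_activation_s=base.t_activation_s + jitter,
        )
        if category is not None:
            sc = _inject_defect(sc, category)
        ds = generate_cell(sc, modalities=modalities)
        ds.cell_id = f"cell-{i}"
        ds.condition = condition
        ds.true_exclusion = category
        cohort.append(ds)
    return cohort


# ---------------------------------------------------------------------------
# serialization (mirrors what imaging_io reads)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write stacks as TIFF(+sidecar), force as CSV, ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for channel, stack in dataset.stacks.items():
        p = outdir / f"{dataset.cell_id}_{channel}.tif"
        write_stack(p, stack)
        paths[channel] = str(p)
    if dataset.force is not None:
        p = outdir / f"{dataset.cell_id}_force.csv"
        write_force_trace(p, dataset.force)
        paths["force"] = str(p)
    gt = asdict(dataset.ground_truth)
    gt["force_events"] = [asdict(ev) for ev in dataset.ground_truth.force_events]
    gt["condition"] = dataset.condition
    gt["true_exclusion"] = dataset.true_exclusion
    p = outdir / f"{dataset.cell_id}_truth.json"
    p.write_text(json.dumps(gt, indent=2))
    paths["ground_truth"] = str(p)
    return paths
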