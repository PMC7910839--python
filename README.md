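# tcellact

Analysis pipeline for multimodal single T-cell activation recordings:
simultaneous ratiometric calcium imaging, TIRF contact-area microscopy, and
AFM force spectroscopy of individual T-cells brought into contact with
antigen-presenting supported lipid bilayers (SLBs).

## Who this is for

Experimental platforms that lower a single T-cell, glued to a tipless AFM
cantilever, onto a ligand-functionalized SLB can record three signals in
parallel on a shared illumination cycle (default 4 s):

- **calcium** — Fura-2 excitation image pairs (340 nm / 375 nm, epi
  configuration); the background-subtracted pixel ratio reports intracellular
  calcium independently of dye load,
- **contact area** — TIRF images of fluorescently labeled TCR (two frames per
  cycle); because TIRF excites only ~100 nm above the coverslip, signal
  reports close membrane–bilayer contact,
- **force** — cantilever deflection at 10 kHz; negative = the cell pulls
  toward the surface, positive = it pushes away.

This package provides the downstream analysis for such recordings: per-cell
traces, event-time statistics, cross-modal synchronization, cohort QC and
statistics, single-molecule calibration of the SLB ligand density, and a
synthetic-data generator with known ground truth that makes every stage
testable without instrument data.

## The statistics at the core

**Half-maximal transition time.** For a trace f(t) with minimum f(t₁) and
maximum f(t₂), t₁ < t₂, the event time t_median is where f crosses the
half-amplitude level (f(t₁)+f(t₂))/2; with multiple crossings, the one
closest to t₂ is used, linearly interpolated between samples. All modalities
are synchronized by shifting time axes so the *calcium* t_median sits at
t = 0; the area-vs-calcium lag and the per-cell parametric coupling (37
cycle-time points in the open window (−50, +100) s at 4 s cadence) follow
from that shared axis.

**Pipeline per modality.**

- Calcium: per-frame scalar background subtraction → pixel-wise 340/375
  ratio (low-denominator pixels invalidated) → mean over a 3.2 µm-radius ROI
  at the cell center → division by the mean basal (pre-contact) ratio.
- Area: average the two TIRF frames per cycle → Gaussian blur (5 px kernel)
  → user-defined threshold (default: pre-contact mean + 5 SD) → pixel count
  × pixel area (0.160 µm/px default).
- Force: cubic smoothing spline fit to the pre-contact deflection,
  subtracted from the whole trace (linear continuation beyond the fitted
  segment) → 1 s moving average → pooling into before / during / after
  calcium-flux windows (−50 ≤ t ≤ −16, −16 < t ≤ 16, 16 < t ≤ 50 s).
- Ligand density: molecules/µm² = (bulk counts per pixel) / (mean
  single-molecule integrated brightness) / pixel area, with emitters
  localized Crocker–Grier style and measured by 7-px aperture photometry
  with an annular local background.
- Cohort: exclusion accounting over seven categories (percentages plus
  acceptance sum to 100 exactly), pointwise median traces with 95%
  percentile-bootstrap bands (1000 resamples of whole cells), two-sided
  two-sample Kolmogorov–Smirnov comparisons.

## Worked example

```python
import numpy as np
from tcellact import (SyntheticScenario, generate_cell, calcium_trace,
                      area_trace, drift_correct, detect_transition, synchronize)

sc = SyntheticScenario(seed=1, t_activation_s=120.0, area_lag_s=4.0,
                       area_plateau_um2=50.0)
ds = generate_cell(sc)

ca = calcium_trace(ds.stacks["ca340"], ds.stacks["ca375"], basal_window=(0, 19.9))
ar = area_trace(ds.stacks["tcr"], threshold="auto", contact_time_s=20.0)
fo = drift_correct(ds.force, contact_time_s=20.0)

cell = synchronize(ca.timestamps_s, ca.normalized, ar.timestamps_s, ar.area_um2)
print("calcium half-rise (s):", round(detect_transition(ca.timestamps_s, ca.normalized).t_median_s, 2))
print("area lag (s):         ", round(cell.lag_area_s, 2))
print("plateau area (um^2):  ", round(float(np.median(ar.area_um2[-10:])), 1))
print("peak pull (nN):       ", round(float(fo.smoothed_force_nN.min()), 2))
```

prints

```
calcium half-rise (s): 119.96
area lag (s):          5.23
plateau area (um^2):   53.5
peak pull (nN):        -1.47
```

i.e. the detector finds the programmed 120 s activation within a fraction of
one 4 s cycle, the area half-rise lags calcium by roughly the programmed 4 s
(within the cycle resolution), the segmented plateau is within ~7% of the
programmed 50 µm², and the drift-corrected force recovers the injected
−1.5 nN pull.

A CLI wraps the same pipeline:

```bash
tcellact simulate --seed 1 --outdir synthetic/
tcellact analyze-cell --config run.yaml
tcellact calibrate-density bulk.tif sparse.tif
tcellact analyze-cohort --n-cells 20 --condition high+ICAM1+B71
```

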