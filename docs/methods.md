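# Methods

This note documents the models, defaults and design choices behind the
`tcellact` pipeline, in the order the method runs.

## Acquisition model

One illumination cycle (default 4 s) yields one 340 nm and one 375 nm
Fura-2 epi-fluorescence frame and two TCR TIRF frames; the AFM cantilever
deflection is sampled continuously at 10 kHz. Pixels are 0.160 µm in the
object plane. Timestamps are stored in seconds; frame index 0 is the first
acquired cycle; pixel coordinates are 0-based (row, col) with centers at
integer coordinates. The calcium pair of a cycle is stamped at the cycle
start; the two TIRF frames carry their within-cycle offsets (~2.50 and
~2.65 s, reflecting their position in the illumination sequence) and an
area cycle is stamped at the mean of its pair. Whether TIRF frames should
be referenced to LED-on or mid-exposure is not fixed by the hardware
description, so the reference is a configuration choice; at the event-time
resolution of one cycle it is immaterial.

Force sign convention: negative deflection = the cell pulls toward the
surface, positive = it pushes away. The same convention is kept for the
reported (drift-corrected) force. By action–reaction the normal force the
cell exerts on the bilayer mirrors the cantilever force; we deliberately do
not flip the sign between "raw" and "reported" traces, so pulling events
appear negative everywhere (histograms of pulling cells have their mass at
negative force).

## Calcium trace

Per frame, a scalar background (median of a 10-px border; a fixed scalar or
a dark value can be configured) is subtracted from both excitation channels;
a frame whose background estimate reaches its maximum carries no signal and
is masked with a warning. The pixel-wise 340/375 ratio is computed with a
denominator floor of 5× the read-noise scale — pixels below it are
invalidated rather than producing unstable ratios. The calcium signal is the
mean ratio over valid pixels whose centers lie within 3.2 µm (20 px at
default magnification) of the cell center; that radius is deliberately
conservative so the ROI stays inside the cell. The center defaults to the
intensity-weighted centroid of the first background-subtracted 340 nm frame
and is held fixed; an override is accepted. Traces are normalized by the
mean ratio over the basal window (from recording start to the manually
annotated first-contact time), so the basal mean of the normalized trace is
1 by construction.

The background is treated as a per-frame scalar; a full dark-image
subtraction would also fit the interface but adds nothing for the flat
backgrounds this pipeline targets.

## Contact area

The two TIRF frames of each cycle are averaged, blurred with a 5-px
Gaussian kernel (σ = kernel/5 px, the opencv sizing convention; σ is
configurable) and thresholded; area = above-threshold pixel count × pixel
area. The threshold is user-defined by design; the default rule is
pre-contact mean + 5 SD, with the statistics taken from the *raw*
pre-contact frames so the rule refers to the camera noise scale rather than
to blur-suppressed noise. No hole filling or connected-component filtering
is applied by default (all above-threshold pixels count); a
largest-component mode exists for noisy fields. Area is monotone
non-increasing in the threshold by construction.

## Force processing

Slow drift and offset are removed by a cubic least-squares spline fit to
the pre-contact segment (≥ 10 s required), with roughly one interior knot
per 10 s so the fit tracks drift but not noise; the fit runs on 10 Hz bin
means since drift lives on much longer timescales than the 10 kHz sampling.
The fitted baseline is subtracted from the entire trace; beyond the fitted
segment it is continued linearly at the end slope — extrapolating the slow
trend is the only way to correct the post-contact portion. Display and
pooling use a centered 1 s moving average (truncated at the edges; a flag
selects raw samples instead). Correction is idempotent to well under the
noise scale.

For population histograms, samples are pooled by time relative to the
calcium half-rise into before (−50 ≤ t ≤ −16 s), during (−16 < t ≤ 16 s)
and after (16 < t ≤ 50 s) windows, honoring those exact closed/open
endpoints (a sample at t = −16 s belongs to "before" only). Bins default to
0.1 nN from −4 to +4 nN and are configurable.

## Event times and synchronization

The half-maximal transition time is the trace's crossing of
(f(t₁)+f(t₂))/2, where f(t₁)/f(t₂) are the extremes with t₁ < t₂ (minimum
first for a rise; a maximum preceding the minimum means no rising
transition and is an error; a flat trace has no transition). Extremes are
located on a 3-sample median-filtered copy so a single noise spike cannot
define the amplitude (raw-extreme mode available). Among multiple
half-level crossings the one closest to t₂ is chosen — we read "ambiguity"
as multiple crossings; the alternative reading (ties in the extremes) is
covered by the stability property below. Sub-sample timing uses linear
interpolation between the bracketing samples (nearest-sample mode
available). The statistic is invariant under affine value transforms and
time shifts, and is stable: replacing either extreme by the
second-most-extreme sample moves t_median by less than one cycle on
sigmoidal traces.

"Time-point of activation" = the calcium t_median; all three time axes are
shifted so it sits at t = 0. The area lag is the difference of the area and
calcium transition times; cells without a detectable area increase (the
low-stimulus phenotype) keep a missing lag but remain in the cohort.
Coupling points pair the interpolated area and normalized ratio at every
illumination-cycle time strictly inside (−50, +100) s on the synchronized
axis; with a frame at t = 0 that open window contains exactly 37 cycle
times at the 4 s cadence. Window endpoints are open because that is the
only convention consistent with 37 points.

## Ligand-density calibration

Sparse-field emitters are localized Crocker–Grier style: difference-of-
Gaussians band-pass, dilation local maxima above both a percentile and a
robust (MAD-based) absolute floor, intensity-centroid sub-pixel refinement.
Detections closer than one aperture diameter (7 px) to each other or too
close to the border are discarded. Brightness is measured by aperture
photometry: sum over pixels within 3.5 px of the position, minus (ring mean
background × foreground pixel count), the ring spanning 3.5–6 px and
excluding pixels within an aperture radius of any other detection. Two
single-emitter screens guard the brightness statistic: a radial
second-moment cut (≤ 2.6 px²; a σ = 1 px spot truncated at the aperture has
~2.0 px², unresolved pairs are far wider) and a 0.5–2× median brightness
window. Density = (bulk counts per pixel, background-subtracted) / (mean
single-molecule brightness) / pixel area. The bulk signal is averaged over
the full field minus a 10-px border; its background defaults to the mean of
the sparse image's per-detection local backgrounds (same camera and
illumination), with a numeric override. The estimate is exactly invariant
under a global gain applied to both images. Trajectory linking is out of
scope — only localization is needed here.

## QC and cohort statistics

Exclusion categories and how they are operationalized:

| category | rule | default |
|---|---|---|
| multiple/non-cell material | operator annotation | — |
| premature contact | operator annotation | — |
| not alive | operator annotation | — |
| elevated basal Fura-2 | basal mean ratio above an absolute cap | > 1.3 |
| excessive movement | RMS centroid excursion | > 1.0 µm |
| insufficient SNR | TCR contrast in background-SD units | < 5 |
| no calcium flux | no rising transition, or normalized peak fold | < 1.4 |

The first three reflect what an operator sees at the instrument and enter
as annotations; the rest are computed from the traces. A failed
bilayer-mobility gate (mobile fraction < 80% from the recovery-after-
photobleaching measurement, supplied as an annotation) invalidates the
recording via the SNR flag. When several flags fire, one primary reason is
assigned by the fixed order above, so per-category percentages plus the
acceptance fraction always total 100%.

Median traces interpolate all synchronized cells onto a common grid and
take pointwise medians; the 95% band is the percentile interval over 1000
bootstrap resamples of whole cells (resampling cells, not time points,
preserves within-cell correlation). Distribution comparisons use the
two-sided two-sample Kolmogorov–Smirnov test (scipy). The
contact-to-flux-duration comparison uses the same KS test as everything
else; no separate test is defined for it.

## Synthetic-data generator

The generator emulates the phenomenology the pipeline must recover, not the
optics: a disc-shaped cell (default radius 5 µm in a 128×128 px field, so a
10 µm cell fits with margin); a Fura-2 ratio following
basal·(1 + (fold−1)·logistic((t−t_act)/τ)) inside the cell (defaults: basal
0.8, fold 3, τ = 6 s — the basal-to-peak magnitude is configurable and not
claimed to match any measured cell); "tip-toeing" as 2–4 px FWHM Gaussian
puncta random-walking inside the footprint from first contact; a contact
disc whose area follows a logistic with half-rise at t_act + lag (defaults:
plateau 50 µm², τ = 8 s, lag 4 s); a force trace = drift polynomial + white
noise (0.05 nN RMS) + sin² pull/push pulses whose peak equals the stated
amplitude. The camera model is Gaussian read noise (10 counts) plus
intensity-proportional variance; EMCCD gain statistics are omitted as
irrelevant to the analysis contracts. Calibration images place a Poisson
number of fixed-brightness Gaussian emitters (5000 counts, σ = 1 px) on a
flat background; the sparse field density is capped at 0.1 µm⁻² (and at the
bulk density) so emitters stay well separated. Condition presets
(high+ICAM1+B71, high+B71, low) vary plateau area, calcium fold/delay and
force amplitudes in the direction seen on the platform. Everything is
deterministic per seed.

What the generator does **not** emulate — evanescent-field depth effects,
microcluster substructure, cytoskeletal dynamics, spatially structured
background, photobleaching — means passing tests demonstrate the analysis
contracts (parameter recovery, invariances, accounting identities), not
performance on real microscopy data.

## Validation problem sizes

The packaged validation runs use: 100 cells (96×96 px, 300 s) for
transition-time recovery; one cell each for area and force recovery; sparse
calibration fields of ~40 emitters at densities 1, 5 and 100 µm⁻²; 200
replicate 30-cell cohorts (37-point traces, 1000 bootstrap resamples) for
confidence-band coverage; 1000 null repeats with 500-sample pairs for the
KS type-I rate. The KS null uses 500-sample pairs so the asymptotic
p-value approximation is accurate; at small equal sample sizes the exact
two-sample test is conservative (true size ≈ 3–4% at n = 50), which is a
property of the test, not of this implementation.

## Known limitations

- First contact is an input annotation (as on the instrument, where it is
  read off the appearance of TCR signal); no automatic detection.
- The per-frame scalar background model assumes flat illumination.
- The area threshold rule is a heuristic default for a quantity the
  workflow defines as user-chosen; different rules shift absolute areas by
  a few percent near the blurred edge.
- Proprietary instrument formats are not read; stacks are multi-page TIFF
  with a JSON timing sidecar, force traces are two-column CSV.
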