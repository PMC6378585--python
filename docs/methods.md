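# Methods

`parastorm` implements a desk-scale, frame-parallel single-molecule
localization microscopy (SMLM/dSTORM) pipeline: simulate or load a blinking
movie, localize every emitter in every frame, merge, filter, drift-correct,
merge repeat blinks, and render. This note records the models, the numerical
choices, and what the validation experiments do and do not demonstrate.

## Parallelization model

Frame-by-frame localization is embarrassingly parallel, but emitter activity
decays over a dSTORM acquisition (photobleaching), so splitting the stack
into contiguous blocks gives the first worker far more localizations — and
far more work — than the last. Frames are therefore dealt round-robin:
worker w of W processes frames w, w+W, w+2W, … Every worker then samples the
whole acquisition and the per-worker load is near-equal (the validation
experiment measures a max/min localization-count ratio of ~1.02–1.04 for
W = 4 on a movie decaying at 0.002/frame, against ~4.5 for contiguous
blocks).

Workers are isolated OS processes (a local process pool; a manifest-export
mode writes one YAML job description per worker for an external scheduler).
Each writes its own partial CSV, a config file naming its frame subset, and
a log. The merge is a stable sort of the concatenated partial tables by
frame number — each frame belongs to exactly one worker, so within-frame
order is the worker's deterministic detection order — followed by id
reassignment. Because every engine is deterministic, the merged raw CSV is
byte-identical for any worker count; the test suite asserts this for
W ∈ {1, 2, 4, 8} and all three engines.

Batch mode processes whole movies in independent slots (one movie's raw
data is only touched by one slot), each slot using its own internal
workers; it exists for arrays of fields of view where localization need not
finish as fast as possible for any single movie.

## Coordinate and camera conventions

Frames are numbered 1..n. Pixel (i, j) spans
[j·a, (j+1)·a] × [i·a, (i+1)·a] nm for pixel size a, so its centre is at
((j+0.5)·a, (i+0.5)·a); x grows with column, y with row. Raw counts convert
to photons as (ADU − baseline)·photons_per_adu, clipped below at zero.
Camera metadata comes from a YAML/JSON sidecar next to the movie (pixel
size also from the OME `PhysicalSizeX` attribute when present); an explicit
override always wins.

## Simulator

The generator emulates sparse dSTORM of filamentous structures:

- **Structure.** `filaments` (default): 3–8 random quadratic Bézier curves,
  emitters at ~15 nm arc spacing with 10 nm isotropic jitter — a stand-in
  for labelled microtubules. `uniform` and `grid` placements serve the
  quantitative tests. A 5-pixel margin keeps emitters inside the usable
  field.
- **Photophysics.** Independently per frame, each unbleached emitter turns
  ON with probability `p_on`; after an ON event it bleaches permanently
  with probability `p_bleach`. Expected ON events per frame decay
  geometrically at rate p_on·p_bleach — the approximately exponential
  fall-off of localization counts in long acquisitions. Re-blinking within
  a frame, triplet kinetics, and buffer chemistry are not modelled; `p_on`
  is constant over the acquisition.
- **Optics.** Each event renders as an integrated 2D Gaussian (per-pixel
  erf differences). In 3D mode the widths follow the astigmatic defocus
  curves σ(z) = σ0·√(1 + ((z−c)/d)²) per axis.
- **Camera.** Expected photons + uniform background → Poisson shot noise →
  additive Gaussian read noise → gain, baseline, rounding, uint16 clip.
- **Defaults** (typical dSTORM regime): 64×64 px at 100 nm/px, σ_PSF
  130 nm, 1000 photons/event (log-normal, shape 0.3), 10 background
  photons/px/frame, 1.6 e⁻ read noise, gain 0.5 photons/ADU, baseline
  100 ADU, p_on 0.02, p_bleach 0.1.
- **Drift** is linear at a configured (vx, vy) nm/frame; axial drift is not
  modelled.

Movies are written as OME-TIFF with a deterministic UUID derived from the
seed, so identical configs give byte-identical files. What passing tests on
this generator do *not* show: robustness to sCMOS pixel-dependent gain,
overlapping-emitter (high-density) imaging, non-stationary activation, or
real structured background.

## Detection

Difference-of-Gaussians band-pass (σ = 1.0/1.6 px, approximating the
wavelet front-ends common in SMLM software), then strict 8-neighbour local
maxima above k·1.4826·MAD of the filtered frame (k = 3 by default;
plateau ties keep the first pixel in row-major order). Candidates within
the ROI radius of the border are discarded. At k = 3 occasional shot-noise
maxima become candidates by design — downstream intensity/width filters
remove their fits; experiments that need detection-complete counting use a
brighter regime and k = 6.

## Localization engines

All engines work on photon-valued square ROIs (radius 3 px in 2D, 4 px for
astigmatic 3D — elliptical spots need the wider support).

**Gaussian fitting (NWLS, MLE).** Model μ_i = N·G_i(x, y, σx, σy) + b with
G the per-pixel integrated elliptical Gaussian (σx = σy in symmetric mode);
the integrated (erf) model stays correct at small σ/pixel ratios. Start
values: b = patch minimum, N = Σ(patch − b), (x, y) = background-subtracted
centroid, σ = 1.3 px prior. NWLS minimizes Σ wᵢ(yᵢ−μᵢ)² with wᵢ =
1/max(yᵢ, 1) (avoids division by zero in dark pixels); MLE minimizes the
Poisson deviance Σ(μᵢ − yᵢ ln μᵢ) with μ floored at 1e-6, using the
expected Fisher information as the Gauss–Newton matrix. Both use
Levenberg–Marquardt damping (λ×10 on rejection, ÷3 on acceptance), capped
at 50 iterations. Stopping: max relative parameter change < 1e-6 (a
negligible *proposed* step also counts — being at the optimum does not
depend on accepting the last step), or relative cost improvement ≤ 1e-9.
The cost-based stop matters because zero-count pixels make the Poisson
likelihood asymptotically flat in b (the optimum can sit at slightly
negative b since the camera conversion clips dark pixels at zero, inflating
zeros); without it, well-localized fits crawl past the iteration cap and
would be discarded. Divergence (centre outside the patch, σ outside
0.3–10 px, N ≤ 0) flags the result non-converged instead of raising.
`bkgstd` is the standard deviation of the fit residual on the ROI border
ring — the background-noise estimate the Thompson formula needs.

**Phasor.** After subtracting the patch minimum, the first Fourier
coefficients along each axis give the position from their phase
(local = −φ·W/2π) and a width proxy from their magnitude
(σ̂ = (W/π)·√(ln(ΣI/|P|)/2), the inverse of the Gaussian Fourier
magnitude). Non-iterative and deterministic; a single-pixel patch has
|P| = ΣI exactly and localizes to that pixel with a (clamped) zero width.

**Precision.** Lateral uncertainty uses the Thompson–Larson–Webb form
Δx² = (s² + a²/12)/N + 8π s⁴ b²/(a² N²) with s = √(σx σy) in nm, a the
pixel size, N the photon count, b the background standard deviation
(σ=130, a=100, N=1000, b=10 → 9.46 nm). No uncertainty is reported for
phasor fits. Validation: on the default regime (bound 5.17 nm with
b = √(10 + 1.6²)), matched MLE localizations reach ~1.16× the bound and
phasor ~1.23×; Mortensen-exact corrections are out of scope.

## Astigmatic 3D

Calibration fits σ0, c, d per axis (least squares) to bead-stack
(z, σx, σy) triplets, requiring ≥ 7 distinct z positions; degenerate
calibrations (coincident foci within 5 nm, flat curves, non-monotonic
√σx − √σy) are rejected. z lookup minimizes
(√σx − √σx,cal(z))² + (√σy − √σy,cal(z))² on a 1 nm grid with parabolic
refinement — the √σ metric de-emphasises the wide tails; out-of-range
widths clamp to the boundary with a large residual. The axial uncertainty
propagates the lateral width uncertainty through the calibration slope
Δz = Δ(√σ)/|d(√σx,cal − √σy,cal)/dz| at z*, capped at 1000 nm. The bundled
default calibration (σ0 = 130 nm, c = ∓200 nm, d = 400 nm, range
±500 nm) represents a typical cylindrical-lens configuration. Pipeline z
RMSE on the default photon budget is ~41 nm over ±400 nm; the forward
model round-trips through the lookup to < 0.001 nm.

## Postprocessing

Steps run in the configured order (default minphot → sigma → zunc → drift
→ merge; the order of the named filters is this package's choice, and the
sigma centiles are computed on the table as it stands when the step runs):

- **minphot** keeps intensity ≥ 1 photon (exactly 1 survives).
- **sigma** keeps widths inside the 10th–75th intercentile range,
  inclusive, with linear-interpolation percentiles (rank p·(n−1)); on
  σ = 1..20 the bounds are 2.9/15.25 and 13 of 20 records survive.
- **zunc** keeps axial uncertainty ≤ 500 nm (exactly 500 survives; records
  with no reported uncertainty, e.g. phasor, are kept); ignored for 2D.
- **drift**: frames split into 5 equal temporal bins, each rendered as a
  2D histogram at pixel/5 super-pixels; all bin *pairs* are FFT
  cross-correlated and the per-bin displacements are the least-squares
  consensus (redundant cross-correlation). The correlation is band-limited
  by a 2-super-pixel Gaussian before the 3×3-paraboloid sub-pixel peak —
  sparse histograms otherwise produce coincidence-noise argmax jitter of
  several super-pixels. Per-frame displacements interpolate linearly
  between bin centres with linear end extrapolation, and a second pass
  re-estimates on the corrected table (pass one removes the within-bin
  smear) before anchoring frame 1 at zero. On 1000 frames of (2, −1)
  nm/frame drift the recovered slope is within 0.5% and the residual RMS
  is 1–3 nm; single-pass bin-vs-first-bin estimation leaves 6–12 nm.
  A drift-summary graph is written alongside.
- **merge** chains localizations of one emitter across subsequent frames:
  a record joins the nearest open chain whose last frame precedes its own
  by ≤ 1 + max_gap (default gap 0) within 50 nm of the chain's
  photon-weighted centroid; same-frame records never merge. Merged
  records keep the first frame, sum photons, photon-weight positions and
  widths, recompute the lateral uncertainty from the merged photon count,
  and combine axial uncertainties in inverse quadrature.

Filters only remove rows and log before/after counts to the run log and
the table's provenance list.

## Rendering

Histogram, average-shifted-histogram (2 shifts/axis, 20 nm super-pixels by
default) and Gaussian-splat modes; histogram/ASH conserve mass exactly.
For 3D tables, a 2D projection colour-codes each super-pixel by the mean z
of its localizations, mapped linearly over −400..+400 nm (clamped) with
ASH intensity; empty pixels are black. Images are written as 32-bit float
TIFF plus an 8-bit PNG preview, tagged `_2D`/`_3D`. A scatter-plot mode is
deliberately omitted.

## Validation experiment sizes

The experiments behind `scripts/acceptance.py` and
`tests/test_acceptance.py` use 64×64 px movies: 500 frames (×3 engines ×4
worker counts) for parallel equivalence, 2000 frames at decay rate
0.002/frame for load balancing, 300 frames of fixed-1000-photon emitters
for precision, 1000 frames for drift, 250 frames for astigmatic 3D, 10⁴
emitters over 2000 frames for decay statistics, and a constructed
36-emitter grid with 3-frame ON runs (5000 photons/event over low
background, detection threshold k = 6 — a deliberately detection-complete
regime) for merge counting. These sizes are chosen so each experiment is
statistically meaningful at desk scale.

## Known limitations

Single-emitter fitting only (no multi-emitter/high-density deconvolution);
no sCMOS per-pixel noise model; no axial drift or fiducial-based
correction; phasor z assignment reuses the same defocus-curve machinery
with a phasor-tagged calibration rather than a method-specific model; the
process-pool backend assumes homogeneous workers.
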