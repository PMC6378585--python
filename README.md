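# parastorm

Frame-parallel single-molecule localization microscopy (SMLM) analysis,
self-contained at desk scale.

In SMLM (dSTORM, PALM), sparse subsets of fluorophores blink on and off
while a camera records thousands of frames; each isolated emitter is
localized to nanometre precision and the positions accumulate into a
super-resolved image. The localization stage dominates the processing time
but is embarrassingly parallel across frames — with one catch: emitter
activity decays roughly exponentially over the acquisition, so splitting
the stack into contiguous blocks overloads whichever worker gets the early
frames. `parastorm` deals frames round-robin instead (worker w of W takes
frames w, w+W, w+2W, …), runs the workers as isolated processes, and merges
their tables back into original frame order — bit-identically to a serial
run.

The package is aimed at people building or validating SMLM processing
chains: it bundles a synthetic dSTORM movie generator with ground truth,
three localization engines, astigmatic 3D, automated postprocessing and
rendering, so every stage is testable without microscope data.

## What's inside

- **Simulator** — blinking emitters on filament-like structures
  (per-frame activation `p_on`, post-event bleaching `p_bleach`, hence
  event rate ∝ exp(−p_on·p_bleach·t)), integrated-Gaussian PSF with
  optional astigmatism, Poisson + read noise camera, lateral drift;
  byte-reproducible OME-TIFF output plus ground-truth CSV.
- **Localization** — iterative fitting of the integrated Gaussian
  μᵢ = N·Gᵢ(x, y, σx, σy) + b by weighted least squares (NWLS) or Poisson
  maximum likelihood (MLE), both Levenberg–Marquardt; and non-iterative
  phasor localization from the phase of the ROI's first Fourier
  coefficients. Lateral precision via the Thompson formula
  Δx² = (s² + a²/12)/N + 8πs⁴b²/(a²N²).
- **Astigmatic 3D** — defocus curves σ(z) = σ0√(1 + ((z−c)/d)²) fitted per
  axis from bead stacks, inverted on a 1 nm grid to assign z to elliptical
  fits.
- **Parallel engine** — interleaved worker plans, process-pool execution,
  frame-order-preserving merge, batch mode for arrays of movies, and YAML
  worker manifests for external schedulers.
- **Postprocessing** — intensity ≥ 1 photon, 10th–75th intercentile width
  filter, z-uncertainty ≤ 500 nm, redundant-cross-correlation drift
  correction, consecutive-frame merging of repeat blinks.
- **Rendering** — histogram / average-shifted-histogram / Gaussian modes,
  and a mean-z colour-coded 2D projection for 3D tables.

Localization tables are ThunderSTORM-dialect CSV
(`"x [nm]"`, `"intensity [photon]"`, …), so they interoperate with the
wider SMLM tool ecosystem.

## Worked example

Simulate a 200-frame filament movie with drift, then process it with four
parallel workers and the automated postprocessing chain:

```
$ cat example_sim.yaml
n_frames: 200
n_emitters: 250
structure: filaments
p_on: 0.02
p_bleach: 0.1
drift_nm_per_frame: [1.0, -0.5]
seed: 42

$ parastorm simulate example_sim.yaml tubulin.ome.tif
wrote tubulin.ome.tif (200 frames, 831 ON events), truth tubulin.truth.csv

$ parastorm run tubulin.ome.tif --jobs-per-node 4 --engine mle \
      --post "minphot,sigma,drift,merge" --preview
tubulin.ome.tif: 941 raw localizations, outputs in 20260923T125202_6da3
```

The movie had 831 true ON events; the raw table holds 941 records (noise
candidates included — that is what the filters are for). All outputs land
in a job-numbered directory next to the movie:

```
20260923T125202_6da3/
  loc_raw.csv                              merged raw table
  loc_post_minphot-sigma-drift-merge.csv   postprocessed table (589 records)
  drift.png                                drift-correction summary graph
  preview_2D.png / preview_2D.tif          ASH rendering
  run.log                                  every processing step, timestamped
  workers/worker_<w>/                      per-worker CSVs, configs, logs
```

and the log shows what each step did:

```
filter sigma: kept 612/941
drift correction applied (200 frames)
merge consecutive (radius 50.0 nm, gap 0): 612 -> 589 records
```

Passing a calibration file as a second argument switches to astigmatic 3D
(`parastorm run movie.ome.tif cal.yaml`); `-b` processes a glob of movies
in batch mode, one slot per node. The same pipeline is available as a
library (`parastorm.process_movie`, `parastorm.localize_frames`, …).

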