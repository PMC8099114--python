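# Methods

This note documents the models, conventions and numerical choices behind
`chromodyn`, in the order data flows through the pipeline. Conventions:
arrays are `(z, y, x)`, 0-based, pixel centers at integer coordinates;
physical sizes in micrometres; times in minutes.

## Image conditioning (`preprocess`)

* **Brightest section.** "Largest signal intensity" is implemented as the
  largest *summed* plane intensity, not the largest single pixel; a single
  hot pixel should not pick the plane. Ties break to the lowest z index.
* **Self-normalization** divides by the image maximum, so downstream
  spectral analysis is invariant to overall intensity (laser power,
  detector gain).
* **Background subtraction** removes a scalar: either a fixed offset or an
  intensity percentile (default 5th). The percentile default is robust for
  photolabel images, where the vast majority of pixels are background; an
  estimate at or above the image maximum is rejected as an error rather
  than silently zeroing the image.
* **Isotropic resampling** uses trilinear interpolation (`scipy.ndimage.zoom`,
  `grid_mode=True`) onto a 0.368 µm grid. Physical extents are preserved to
  within one voxel; integrated intensity (sum × voxel volume) to within
  about 2% for stacks that are not dominated by their boundary voxels.
* **ROI cropping** defaults to 100×100 px windows; windows running over the
  frame edge are zero-padded and flagged rather than rejected.

## Granularity Index (`granularity`)

The GI is the mean FWHM of Gaussian fits to the two cardinal axes of the
centred 2D Fourier spectrum of the self-normalized brightest section.
Choices where more than one reading is defensible:

* The **magnitude** spectrum is fitted (not the power spectrum). Either
  satisfies the defining phenotype — broader spectrum for clumpier
  texture — and all tests assert internal consistency, monotonicity and
  invariances rather than absolute values.
* The cardinal profiles are the **single row/column through the DC bin**,
  symmetric about DC, with no band averaging and no window function
  (windowing is available via preprocessing upstream but off by default).
* The Gaussian `A·exp(−x²/2σ²) + c` is fitted by least squares with the
  **centre fixed at DC**; σ is initialized from the profile's second
  moment; the DC bin is included. Non-convergence raises with diagnostics.
* Axis FWHMs are converted from bins to **cycles/pixel** (dividing by the
  profile length) so values are comparable across image sizes; the GI is
  their mean. Since the paper-style readout is the ratio to the first time
  point, the unit cancels in `GISeries`.

The fit is validated against a brute-force enumeration over σ (with A and c
solved exactly per σ), and recovers σ = 3 profiles within 5% under 5%
additive noise.

## Circularity Index and 3D spread (`circularity`)

* Processing order is: MIP → background subtraction → division by max →
  mask at intensity > 0.25 → brightness-weighted PCA. Thresholding after
  max-normalization is deliberate and load-bearing.
* The CI ratioes the **covariance eigenvalues themselves** (variance
  units), not their square roots. Both satisfy the line → 0 / circle → 1
  anchors; the variance ratio is the documented choice.
* Labels with fewer than 2 pixels above threshold (or all at one
  coordinate) are an **error**, not CI = 1: real photolabels span many
  pixels, and a degenerate mask signals a failed acquisition. In cohort
  processing these errors become per-time-point QC flags.
* `eigen3d` resamples to the isotropic grid, max-normalizes, masks at
  > 0.1 and needs ≥ 4 voxels. Eigenvalues are in voxel² of the isotropic
  grid; a percent-of-trace view is provided for scale-free comparison.
* **Bin schemes.** The slice legend leaves (0.15, 0.25] unassigned; such
  values are labeled `medium` and flagged, and the flag count is carried
  through `cdf_and_bins`, because the originally intended rule is unknown.
  The in-vivo scheme has no gap. Boundary values land in the lower bin
  (`ci < low_edge` is low; `ci ≤ high_edge` is medium).

## Synthetic data (`synthetic`)

The simulator emulates the statistical structure the metrics assume, not
cell biology:

* **Nuclei** are ellipses (2D footprint) with an axial extent derived from
  the minor semi-axis; real nuclei are roughly round, and the container
  shape only needs to bound the label.
* **Pan-nucleosome texture** is `(1−g) + g·B`, where `B` is a field of
  randomly placed Gaussian blobs (σ 1.3–3.4 px, i.e. foci of roughly
  3–8 px diameter; ~0.03 blobs/px² of nucleus area) normalized to unit
  in-nucleus mean. `g ∈ [0, 1]` is the granularity control; GI is strictly
  increasing in `g` on average (verified over seeds).
* **Photolabels** are lines through the nucleus centre, clipped to the
  ellipse, on one focal plane; the anisotropic PSF extends them axially.
* **Rendering:** Gaussian PSF with defaults σ_xy = 1 px (≈ 0.2 µm at the
  0.215 µm default pixel size) and σ_z = 0.9 voxels (≈ 0.9 µm at 1 µm z
  steps), reflecting two-photon optics that are submicron laterally and
  ~2 µm axially (the axial physical width is validated to be ≥ the
  lateral). Noise is Poisson shot noise (200 expected photons at unit
  intensity) plus Gaussian read noise (σ = 0.01) on a 0.02 background.
  With these defaults a width-1 line still scores CI < 0.05.
* **Label evolution** operates on *quanta*: each labeled pixel is split
  into 4 sub-pixel point masses, transformed exactly, and re-deposited
  bilinearly (cloud-in-cell). Consequences: total mass is conserved up to
  boundary clipping; rigid rotations compose exactly at the point level
  (rasterization is the only closure error); diffusion is per-axis
  Gaussian steps with variance `2·D·dt`, radially reflected at the ellipse
  boundary so the stationary distribution is near-uniform and the CI
  converges to the filled-disk value. The directed flow is a deterministic
  swirl (70%) plus shear (30%) of magnitude `rate·dt` at the label's RMS
  radius — a minimal "clear trajectory" family, an artifact choice with no
  measured counterpart.
* **Cohorts** draw per-cell geometry, line orientation and a
  dynamic/stable fate (probability = the group's `fraction_dynamic`);
  dynamics start at the treatment time point. Default time grid
  (−60, 0, 60, 120) min with treatment at 0 mirrors an hourly revisit
  protocol with one baseline hour. Default diffusion rate 0.2 px²/min
  takes a dynamic cell's CI from ~0.02 to ~0.5–0.9 within two hours,
  matching the qualitative before/after contrast of activity-induced
  reorganization.
* **Behavior videos** are a smoothed random texture that translates 2
  px/frame during "moving" epochs and is static otherwise, plus σ = 1
  grey-level sensor noise — far below the default 25-grey-level change
  threshold, so scheduled epochs map onto scored stillness to within one
  frame at the boundaries.

What the simulator does **not** emulate: polymer mechanics of chromatin,
empirical PSFs, camera-specific noise, nuclear movement/drift,
segmentation errors, or animals (videos contain no body posture). Passing
tests therefore validate the *analysis* — its invariances, calibration and
power under the stated generative assumptions — not biological claims
about real tissue.

## Cohort statistics (`pipeline`)

The unit of analysis is the cell. Because each cell is measured repeatedly,
the default `anova_two_way` is a **mixed (split-plot) two-way ANOVA**
(pingouin `mixed_anova`): treatment between cells, time within cells. With
the simulator's cell-level random effects this keeps the interaction test
at its nominal size (measured 5.0% at α = 0.05 over 200 null cohorts),
whereas a fully pooled two-way ANOVA is conservative when within-cell
correlation is present; `blocked=False` provides the pooled variant for
comparison. Post-hoc: Welch t-tests for all group pairs within each time
level, Sidak-corrected over the whole family. Cells missing a time point
are excluded from paired pre/post tables (and counted) but retained in
per-time-point CDFs.

The validation study sizes are: power, 20 replicate cohorts of 40
cells/group at 4 time points (stable-dominated vs dynamic-dominated); null
calibration, 200 replicate cohorts of 40 cells/group at 2 time points with
identical groups; both on 48×48 px, 5-plane frames.

## Freezing scorer (`freezing`)

Frame pair *i* covers `[i/fps, (i+1)/fps)` and is still when its count of
significant motion pixels (|Δ| > `pixel_delta_threshold`, default 25 grey
levels) is ≤ `motion_count_threshold` (default 50 px). Maximal still runs
≥ `min_bout_s` (default 1 s) are freezing bouts; a run reaching the final
pair is extended to the end of the video so an all-still video scores
exactly 1. Bout time is attributed to periods by interval intersection, so
bouts may straddle period boundaries. The defaults are package choices —
no numeric thresholds are published for the original scorer, so reproducing
specific printed freezing percentages is out of scope; the scorer is
validated for exactness against scheduled synthetic videos instead.

## Known limitations

* GI absolute values depend on image size, windowing and spectrum choice;
  only normalized (t₀-relative) comparisons are meaningful across setups.
* The CI is undefined (raises) for near-empty masks; downstream code must
  handle QC flags.
* `eigen3d` invariance under rigid rotation holds to ~5% for the smallest
  eigenvalue, limited by interpolation of thin labels.
* The slice bin scheme cannot be reproduced exactly for CI values in the
  unassigned (0.15, 0.25] band; fractions involving it carry flags.
* Boundary reflection of diffusing quanta is radial in the ellipse's unit
  coordinates — an approximation to true specular reflection that slightly
  distorts the stationary density near highly eccentric boundaries.
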