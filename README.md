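# chromodyn

Quantification of nucleus-scale chromatin reorganization in time-lapse
fluorescence microscopy, plus the surrounding experimental pipeline:
simulation of labeled nuclei with known ground truth, cohort-level
statistics, and an automatic freezing scorer for fear-conditioning
behavior videos.

## The problem

Neuronal activity can trigger rapid, large-scale rearrangements of
chromatin inside the nucleus. Two imaging strategies make this visible:

* **pan-nucleosome labeling** (e.g. H2B::mCherry), where activity shows up
  as the fluorescent signal becoming clumpier and more granular; and
* **photolabeling** (e.g. H2B::PaGFP), where a thin fluorescent line is
  written across the nucleus and chromatin movement deforms it.

`chromodyn` implements the two bespoke metrics that turn these movies into
numbers, the 3D analysis that separates rigid nuclear rotation from genuine
chromatin redistribution, and the downstream group statistics.

## The metrics

**Granularity Index (GI).** For each nucleus stack, the brightest optical
section is self-normalized, its centred 2D Fourier magnitude spectrum is
computed, and a Gaussian `A·exp(−f²/2σ²) + c` is fitted along each of the
two cardinal frequency axes. The GI is the mean of the two full widths at
half maximum, `FWHM = 2√(2 ln 2)·σ` (reported in cycles/pixel). A clumpier
intensity distribution has a broader spectrum and a larger GI. Per-nucleus
time series are normalized to their first time point (`GI(t)/GI(t₀)`).

**Circularity Index (CI).** The maximum-intensity projection of a
photolabel stack is background-subtracted, normalized to its maximum, and
thresholded at intensity > 0.25. A brightness-weighted PCA of the remaining
pixel coordinates gives the 2×2 covariance
`C = Σᵢ wᵢ (rᵢ − c)(rᵢ − c)ᵀ / Σᵢ wᵢ`, and

&nbsp;&nbsp;&nbsp;&nbsp;CI = λ_minor / λ_major ∈ [0, 1],

which is 0 for an infinitely thin straight line and 1 for a circle, and is
invariant to intensity scaling, translation and rotation of the label.

**3D eigenvalue spread.** Stacks are resampled to an isotropic 0.368 µm
grid, thresholded at > 0.1, and the three eigenvalues of the 3D
brightness-weighted covariance are computed. A rigid rotation of the whole
label leaves the sorted triple unchanged; genuine three-dimensional
redistribution raises the smallest eigenvalue.

CI values are also classified into low/medium/high bins under two published
legend schemes (`slice_scheme`: < 0.05 / 0.05–0.15 / > 0.25, with the
unassigned 0.15–0.25 band flagged; `invivo_scheme`: < 0.1 / 0.1–0.2 / > 0.2).

## Worked example

```python
import chromodyn as cd

geometry = cd.NucleusGeometry(center=(32, 32), semi_axes=(20, 20))
render = cd.RenderParams(seed=4)
_, line_stack = cd.make_line_label(geometry, 1.5, orientation=0.4, render=render)
print(cd.compute_ci(line_stack).ci)
```

Running `python examples/circularity_index.py` prints:

```
thin line      CI = 0.006  (138 px above 0.25) -> bin 'low'
redistributed  CI = 0.817  (1002 px above 0.25) -> bin 'high'
```

A freshly photolabeled line scores near 0; after simulated diffusive
redistribution of the chromatin the label fills the nucleus and the CI
approaches 1. `examples/cohort_pipeline.py` runs the whole chain on a
simulated two-group cohort and prints the mixed two-way ANOVA
(treatment × time) with its interaction term — the statistical signature
of treatment-induced chromatin dynamics:

```
     source  df1   df2       F      p
  treatment  1.0  38.0  6.2129 0.0172
       time  3.0 114.0 25.0585 0.0000
interaction  3.0 114.0  5.9648 0.0008
```

The other examples cover the GI (`granularity_index.py`), the 3D
eigenvalue analysis (`eigen3d_label_spread.py`) and the freezing scorer
(`freezing_scorer.py`).

## Command line

A thin CLI wraps the library for shell use:

```bash
chromodyn simulate --config config.yaml --out-dir sim/
chromodyn pipeline --manifest sim/manifest.csv --out-dir results/
chromodyn ci --manifest sim/manifest.csv --out ci.csv
chromodyn freeze --video session.npy --fps 10 --schedule schedule.csv --out report.json
```

All subcommands accept a single YAML config (see `chromodyn/config.py` for
the schema); every run writes a log with the resolved configuration and
seed so it can be reproduced exactly.

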