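# microcyte

Label-free cell analytics from brightfield microscopy images: confluency,
cell counting, size, and live/dead viability, plus the growth-curve and
dose-response analytics built on top of them. The package targets cell
biologists who track proliferation and cytotoxicity from plain culture or
counting-chamber images instead of reagent-based assays, and method
developers who need an end-to-end, fully reproducible testbed: every model
here can be trained and evaluated against a bundled synthetic image
generator that emits exact ground truth.

## What it computes

* **Confluency** — a U-Net segments adherent-culture images into
  cell/background; confluency is `100 · |mask ∩ ROI| / |ROI|`. The
  full-scale topology is a 1024×1024×1 input, four encoder blocks of paired
  3×3 convolutions (64/128/256/512 filters, 2×2 max pooling, 0.5 dropout
  after the fourth), a 1024-filter bottleneck, a mirrored decoder with skip
  concatenations, and a two-filter 3×3 + 1×1 sigmoid head; a `base_scale`
  multiplier shrinks all widths for desk-scale training.
* **Cell counting** — a second network predicts a per-pixel cell
  probability p and a flow vector (∂y, ∂x) pointing at the owning cell's
  centre. Ground-truth flows come from heat diffusion seeded at each
  object's median pixel; at inference, foreground pixels are advected along
  the flows until they cluster at fixed points, and each cluster becomes one
  instance — which is what separates touching cells. Counts per etched
  chamber square convert to concentration via
  `cells/mL = mean count / (side² · depth · 10⁻³) · dilution`.
* **Cell size** — the count model's pooled bottleneck features (a
  256-value "style" vector at full scale) feed a linear regression on log
  diameter; the image is rescaled to the predicted size, re-segmented, and
  the median equivalent-area diameter `2·√(area/π)` is reported.
* **Viability** — a small U-Net variant (four 3×3 convolutions, two max
  poolings, three 2×2 transposed convolutions, 1×1 Tanh head) scores each
  pixel in [−1, 1]; after instance segmentation each object's mean score is
  thresholded at 0 into live/dead. Works for Trypan Blue and Erythrosin B
  staining.
* **Analytics** — MAE/MSE/RMSE, pixel and object-level
  precision/recall/F1 (greedy one-to-one IoU matching), OLS regression,
  exponential growth rate `gr = ln(Nt/N0)/t` with doubling time
  `Td = ln 2 / gr`, four-parameter logistic dose-response
  `y = bottom + (top − bottom) / (1 + 10^((log₁₀ d − log₁₀ IC50)·h))` with
  asymptotic IC50 confidence intervals, and bootstrap sampling plans for
  how many fields must be imaged before the mean confluency is stable.

The networks are implemented in a compact numpy engine (im2col
convolutions, manual backprop, Adam) so the whole package trains and runs
on a single CPU with no deep-learning framework.

## Worked example

```python
import microcyte as mc

# 1. render a hemocytometer square with known ground truth
spec = mc.SceneSpec(width_px=250, height_px=250, microns_per_px=2.0,
                    scene_kind="chamber", n_objects=40,
                    object_mix=[("cell", 18.0, 2.0, 1.0)],
                    grid=mc.ChamberGeometry(square_side_mm=0.5), seed=42)
scene = mc.render_chamber_scene(spec)

# 2. flow-field instance segmentation (ideal flows from the ground truth)
instances = mc.follow_flows(mc.masks_to_flows(scene.instance_map))

# 3. count and concentration (0.5 x 0.5 mm square, 0.1 mm depth)
geom = mc.ChamberGeometry(square_side_mm=0.5)
count = mc.count_cells(instances)
conc = mc.concentration([count], geom)

# 4. growth analytics and IC50
series = mc.simulate_growth_series(1e4, gr=0.55, timepoints=[0, 1, 2, 3, 4],
                                   cv_noise=0.03, seed=7)
dt = mc.doubling_time(series)
table = mc.simulate_dose_response(top=100, bottom=0, ic50=1.2, hill=1.0,
                                  doses=[0.1, 0.25, 0.5, 1, 2.5, 5, 10, 20],
                                  sd=3.0, replicates=3, seed=3)
fit = mc.fit_4pl(table)
```

Output:

```
rendered 40 cells, coverage 4.2%
segmented instances: 40
count 40, concentration 1.600e+06 cells/mL
growth rate 0.544/day, doubling time 1.27 days
IC50 1.18 nM (95% CI 0.93-1.50), R^2 0.989
```

The 40 rendered cells come back as exactly 40 instances; at 40 cells in a
0.5 × 0.5 mm × 0.1 mm square (2.5·10⁻⁵ mL) that is 1.6·10⁶ cells/mL. The
growth fit recovers the simulated 0.55/day rate within the injected 3%
noise, and the 4PL fit brackets the true IC50 of 1.2 nM.

A `microcyte` command-line tool wraps the same functionality
(`microcyte simulate|count|growth|dose|plan`, see `microcyte --help`).

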