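# Methods

This note records the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests demonstrate.

## Segmentation models

**Confluency U-Net.** Standard encoder–decoder with skip connections.
Full scale: input 1024×1024×1; encoder blocks of two 3×3 ReLU convolutions
with 64, 128, 256 and 512 filters, each followed by 2×2 max pooling, with
0.5 dropout after the fourth block; a bottleneck of two 3×3 convolutions
with 1024 filters and dropout; a decoder of 2×2 upsampling + 2×2
convolution (512→256→128→64), concatenation with the matching encoder
features, and two 3×3 convolutions per level; a head of one 3×3
convolution with two filters (ReLU) and a 1×1 sigmoid convolution.
Training uses Adam with binary cross-entropy. `base_scale` multiplies all
filter widths (rounded up), preserving the topology: at 0.25 the encoder is
16/32/64/128 with a 256-filter bottleneck.

Desk-scale choices: tests and the acceptance script train at `base_scale
0.125` on 96×96 fields, with dropout reduced to 0.1 and Adam at 3·10⁻³ —
at one-eighth width, 0.5 dropout removes too much of the remaining
capacity, and the reference learning rate of 10⁻⁴ is matched to full-width
training. Probability threshold 0.5 (exposed as config). Prediction
letterboxes any input (aspect-preserving resize, bottom/right zero pad)
onto the network input; the mask returns to native resolution by
nearest-neighbour, and padding never enters the ROI. Colour images are
converted to luma.

**Count model.** The same U-Net backbone emits three maps: cell
probability (sigmoid/BCE) and raw flow components dy, dx (L2 loss,
weight 5). The head differs deliberately from the confluency net: the
three signed output maps read the final decoder features directly through
the 1×1 convolution, because a two-filter ReLU stage cannot jointly
express one probability and two signed flow fields (with it, training
collapses to a constant prediction). Inputs are zero-centred (x − 0.5) to
keep the ReLU stacks active. The model records the median training object
diameter as its native diameter; images can be rescaled to that diameter
before prediction. A style vector — the L2-normalised global average pool
of the bottleneck activation (256 values at full scale, 128 at the desk
scale used here) — summarises the image for the size regression.

**Ground-truth flows** are built per object by iterated 9-point heat
diffusion seeded at the object's median pixel (clamped to the object),
`2·max(h, w) + 10` iterations on the padded bounding box; the flow is the
unit-normalised central-difference gradient of `log1p(T)`. **Integration**
advects every pixel with probability ≥ 0.5 for 200 Euler steps of length
0.6 along the bilinearly interpolated flow, normalised to unit vectors;
pixels whose local flow magnitude falls below 0.2 stop (they have reached
a sink). Landing bins with ≥ 3 arrivals are clustered with 8-connectivity;
every advected pixel takes its landing cluster's label (clusters are
dilated up to 3 px to catch near-miss landings). Holes are filled per
label, objects under `min_object_px` (default 12) are dropped, and
instances whose re-derived flows disagree with the input flows by a mean
squared vector error above 0.4 are discarded (on by default). Tie-breaks
on contested pixels go to the lowest label. These defaults reproduce the
generator's ground truth on 5–200-object chamber scenes with ≤ 2% count
error and mean matched IoU ≥ 0.9, and split touching discs into exactly
two instances.

**Viability net.** Four 3×3 ReLU convolutions (16/32/32/16 filters), max
pooling after the first two, then three 2×2 transposed convolutions
(32/16/8) and a 1×1 Tanh head. Two poolings shrink the map 4× while three
stride-2 upsamplings would grow it 8×; the only size-preserving reading is
to run the third transposed convolution at stride 1, which is what this
implementation does. The training target is +1 on dead-cell pixels, −1 on
live-cell pixels, 0 on background, with an L2 loss — the natural pairing
for a Tanh head. Per-object calls average the score field over the
object's pixels and threshold at 0 (configurable); classification is
applied strictly after instance segmentation and is identical for Trypan
Blue and Erythrosin B renderings.

## Size estimation

Two passes. Pass 1 rescales the image as if objects were at the default
diameter (30 px), segments, and computes the style vector; a linear
regression predicts log diameter from the style (log link keeps sizes
positive). Pass 2 rescales the image by native/d̂, re-segments, maps labels
back, and reports the median equivalent-area diameter 2·√(area/π). The
final number therefore comes from measured mask areas; the regression only
sets the working scale. OLS needs at least dim+1 style/diameter pairs;
below that a ridge penalty (λ = 10⁻³, intercept unpenalised) keeps the
normal equations solvable — the regime all desk-scale panels are in. The
style is taken in pass 1 only.

## Synthetic data

The generator emulates what the models must cope with, with exact labels:

* **Adherent fields** — irregular cells (ellipse axis ratio U(1, 1.8),
  boundary perturbed by Fourier modes 2–4, bright 1–2 px halo, smooth
  interior texture) on a noisy background (Gaussian σ = 0.02 plus a
  per-image linear illumination gradient). Cells are placed until pixel
  coverage reaches the target confluency; the closing cells are shrunk so
  the achieved coverage lands within ±2 points of the target (targets near
  100% stop at geometric saturation ≥ 98%).
* **Chamber scenes** — bright background with darker etched grid lines at
  the chamber pitch; live cells with bright interiors; dead cells with
  dye-filled interiors (dark blue for Trypan Blue, red-pink for
  Erythrosin B; the live/dead luma gap exceeds 0.2 so viability is
  learnable); beads with a dark refractive ring; debris as small dark
  high-eccentricity specks that are rendered but excluded from the labelled
  ground truth. Pairwise overlap is capped at 30% of the incoming object's
  area so touching-cell separation is exercised; the exact requested dead
  fraction is assigned (rounded count, seeded choice).
* **Defocus** — separable Gaussian blur with explicit truncated kernel
  support; σ = 0 is the identity. The augmentation grid spans kernel sizes
  {5, 9, 13, 15} × σ {0.0, 0.5, 1.0, 1.5, 2.0}.
* **Series** — exponential growth with multiplicative lognormal noise of a
  given CV; 4PL dose-response tables with additive Gaussian noise;
  dilution series whose per-field counts are Poisson with mean
  concentration × square volume / dilution factor.

Determinism: a scene seed feeds a `SeedSequence`; every object draws from
its own spawned stream, so object counts can change without reshuffling
earlier objects, and identical specs are bit-identical.

Mixed-resolution pools: confluency training renders scenes at 1×, 2×, 4×
and 10× the model size and downsamples them, emulating the spread of image
qualities a deployed model sees; this is what makes predictions stable
(< 2 points) when the same high-resolution image is presented at 80, 50,
20 or 8% of its original resolution.

What the generator does **not** model: physically accurate optics (point
spread, phase contrast transfer), fluorescence, apoptotic morphology
gradations, autofocus artefacts, or time-lapse correlation. Passing tests
therefore demonstrate that the pipeline is correct and learnable end to
end under controlled conditions — not that the desk-scale weights transfer
to real microscopes.

## Study conditions at desk scale

All trainings in the tests and the acceptance script run on one CPU in a
numpy engine, so the problem sizes are deliberately modest, chosen once:

* confluency: 60 train / 12 val / 16 test multiscale 96×96 fields,
  `base_scale` 0.125, 28 epochs, batch 4;
* counting: 80 train 64×64 chamber crops with per-scene object-diameter
  jitter (cells 14–26 µm, beads 10–20 µm, 10% beads, debris distractors),
  30 epochs, batch 2; evaluated on held-out 96×96 scenes and on 1×1 mm
  density strata (<50, 50–300, >300 objects per square);
* viability: 40 scenes per dye, 8 epochs; evaluated per object on
  mixed-ratio panels (10–90% dead) for each dye separately;
* size: 64 bead panels (6–16 µm) for the ridge regression, 20 held-out
  panels for the reported R²;
* dilution series: stock 2.5·10⁷ cells/mL over factors down to 1·10⁴
  cells/mL, 3 fields per step, 0.5 mm chamber squares, counted through
  ideal flows (isolating the counting/concentration arithmetic from model
  error);
* IC50 coverage: 1000 Monte-Carlo tables at the 8-dose panel
  (0.1–20 nM), additive noise SD 5, 3 replicates, asymptotic 95% CI.

The quality thresholds these conditions are tested against (pixel F1
≥ 0.90, instance precision/recall ≥ 0.90, viability accuracy ≥ 95%,
linearity R² ≥ 0.99, size R² ≥ 0.95, resolution deviation < 2 points) are
not scaled down.

## Numerical and design choices

* Instance matching is greedy one-to-one by descending IoU with threshold
  0.5. For disjoint label maps at this threshold the ≥ 0.5-IoU graph is
  already a matching, so greedy equals exhaustive matching (the tests
  verify this against brute force).
* Hemocytometer counting uses the top/left-include border rule: objects
  crossing the bottom or right ROI edge are excluded, those crossing the
  top or left are counted; ROIs are half-open pixel rectangles.
* The 4PL uses the log₁₀-dose parameterisation with hill > 0 meaning
  falling viability; fits that converge with a negative hill are flipped
  (top↔bottom) to the equivalent canonical form. Multi-start
  Levenberg–Marquardt (hill ∈ {1, 0.5, 2}); asymptotic CIs from the
  Jacobian with a t critical value. Zero doses sit at (smallest nonzero
  dose)/10 on the log axis, which biases a noise-free round trip by about
  1% — accepted as the cost of a finite log placement.
* Growth rate comes from OLS of ln N on t over all timepoints, which
  reduces exactly to ln(Nt/N0)/t for two points; non-positive slopes
  report an infinite doubling time with a flag.
* The sampling plan bootstraps the SD of the n-field mean (2000 resamples)
  and returns the smallest n under the target (default 5 percentage
  points); for i.i.d. fields it tracks the SD/√n closed form within one
  field. Vessel and field areas are inputs, not constants.
* Precision/recall with empty denominators report 0 with a degenerate
  flag rather than NaN.
* Small all-ReLU networks occasionally die at an unlucky initialisation
  (loss frozen from the first epoch). Training functions expose their loss
  history, and the acceptance pipeline retries such runs with a shifted,
  still deterministic, init seed (at most twice). The viability net trains
  at Adam 10⁻³ for 12 epochs, which was stable across inits where 3·10⁻³
  was not.
* Pixel coordinates are 0-based, origin top-left, y down; masks are
  boolean; instance labels are contiguous 1..K with 0 background.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-scale
  (1024-filter, 1024×1024) training is expressible but not practical —
  the architecture is validated at reduced width.
* `follow_flows` assumes mostly convex objects; long concave shapes can
  fragment because diffusion centres sit at the median pixel.
* The viability classifier reads colour contrast produced by exclusion
  dyes; unstained dead cells are out of scope.
* Ridge-regularised size regression trades a small bias for stability in
  the n ≪ dim regime; with enough panels OLS takes over automatically.
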