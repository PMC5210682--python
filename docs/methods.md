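# Methods

## Pipeline

A slide image passes through four stages:

1. **Luminance.** Multi-channel rasters collapse to grayscale with
   Rec. 601 weights (0.299 R + 0.587 G + 0.114 B), normalized to [0, 1].
2. **Binarization.** Otsu's threshold by default (maximizes between-class
   variance of the intensity histogram); a fixed threshold is available
   via config. A pixel is foreground iff its intensity is *strictly*
   above the threshold — the strict inequality is a deliberate,
   documented boundary convention (a constant image at exactly the fixed
   threshold is all background). A constant image degenerates Otsu's
   histogram; the result is an all-zero mask plus a warning rather than
   an error.
3. **Edge detection.** Default is the morphological inner boundary of
   the binary mask: a foreground pixel is an edge iff at least one of its
   4-neighbours is background or off-image. This is deterministic and
   parameter-free, which is why it is the default over a gradient
   detector whose Gaussian radius and hysteresis thresholds would be
   hidden knobs. 8-connectivity and a Canny-style detector on the
   grayscale image are config alternatives. 4-connectivity produces the
   thinner boundary, which matters at ε = 3 where thick edges saturate
   boxes.
4. **Box counting.** The edge map is partitioned into a non-overlapping
   grid of ε×ε boxes anchored at pixel (0, 0); boxes are half-open
   [x₀, x₀+ε). N(ε) is the number of grid boxes containing ≥ 1 set
   pixel; the dimension is the ordinary least-squares slope of
   log N(ε) vs log(1/ε) (natural logs; the slope is base-invariant).

### Numerical and boundary choices

* **Ragged boxes.** When the image side is not divisible by ε the
  partial boxes at the right/bottom edges are dropped (floor-division
  grid) by default; `include_partial=True` counts them. Both semantics
  are exact, tested against a naive grid scan; neither is "correct" in
  any deeper sense, so the choice is explicit rather than implicit. Note
  that with dropped partial boxes a sparse image can have N(ε) = 0 even
  when pixels exist in the ragged margin; the N(ε) ≥ 1 lower bound for
  non-empty images holds for the partial-inclusive grid.
* **Grid anchoring.** Counts depend on the grid origin; anchoring at
  (0, 0) is part of the contract, not hidden. Translation sensitivity of
  a few percent at coarse scales is expected and visible in the
  Sierpinski validation numbers.
* **Default scales.** ε = (3, 4) for slide-sized (700×460) images. With
  two points the OLS slope equals the analytic two-point slope to
  machine precision (tested). Multi-scale lists are fully supported and
  are what the synthetic validation fixtures use.
* **Range handling.** A true planar fractal dimension lies in [1, 2],
  but the finite two-point estimator can leave that range (a nearly
  empty image whose few pixels land in one ε=3 box but two ε=4 boxes
  yields a negative slope). Out-of-range estimates are reported raw with
  `in_range=False` and a warning — never clamped, because clamping hides
  data problems. The in-range test itself uses a 1e-9 tolerance at the
  bounds so that a solid block measures exactly 2.0 despite float
  rounding.
* **Zero counts.** Scales with N(ε) = 0 cannot enter the log fit; they
  are dropped and recorded in the result's warning. An image with no
  set pixels at any scale has no defined dimension and raises.
* **Integral image.** Entry (i, j) holds the count of set pixels in the
  rectangle (0,0)–(i,j) inclusive; any box count is four lookups with
  zero-extension above/left. Grid scans are vectorized over all grid
  anchors at once.

## Synthetic fractals

`render_fractal` produces deterministic 1-px-stroke rasters of curves
with closed-form dimensions, used to validate the estimator end to end:

* **line** (d = 1) and **filled_square** (d = 2) pin the exact bounds:
  on canvases divisible by both scales the two-point estimator returns
  them to machine precision.
* **koch_snowflake** (d = log 4/log 3 ≈ 1.2619): three Koch curves
  closing an equilateral triangle, bumps outward.
* **cesaro** (d = log 4 / log(2(1+cos a))): the generalized Koch motif
  with bump angle a; each segment becomes four of length
  1/(2(1+cos a)) with heading changes (+a, −2a, +a). a = 60° recovers
  the Koch curve; the dimension increases monotonically with a toward 2.
  No specific angle's value is asserted in tests — only monotonicity —
  because raster estimates at practical depths sit a few hundredths
  below the similarity dimension.
* **sierpinski** (d = log 3/log 2 ≈ 1.585): recursive triangle
  subdivision drawn as the outlines of the deepest-level triangles
  (ancestor edges are covered by descendant edges, so this is the full
  gasket wireframe).

**Rendering scale.** Motif curves are drawn *resolution-matched*: the
curve is scaled so its finest motif segment spans `step_px` (default
1.5 px), and rendering fails with "resolution exhausted" if that scale
would overflow the canvas. Canvas-fit rendering of a shallow iteration
leaves long straight segments — an iteration-5 snowflake fit to 2048 px
has ~7 px segments, and box counting at ε below that scale sees a
locally one-dimensional curve, biasing the slope toward 1 (measured
1.09 over ε ∈ {2..32}). Resolution-matching is the turtle-graphics
convention (fixed step, depth sets extent) and carries scaling structure
down to the stroke scale. The 1.5 px default was validated against the
closed forms: 1 px aliases the stroke (Koch reads 1.29), 2 px leaves
visible straight runs (1.24), 1.5 px reads 1.2609. The Sierpinski
gasket is the exception and is drawn canvas-fit: as an area recursion
its wireframe has structure at every scale from the canvas down to the
smallest triangle, so no matching is needed.

## Synthetic two-class populations

`generate_population` emulates the *feature distribution* of a slide
archive, not its appearance: each image is a union of short random
strokes (8–32 px) whose count is tuned by bisection until the measured
box-counting dimension at the default (3, 4) scales matches a per-image
target drawn from the class's Normal(mean, sd). Monotonicity of the
search comes from building every candidate image from a prefix of one
fixed, seeded stroke bank. Defaults: 40 images per class on a 256-px
canvas, benign mean 1.80, malignant mean 1.55, sd 0.05 — a
well-separated regime consistent with the direction of the benign >
malignant complexity difference reported for H&E stains at 40×, and
with per-class spreads of a few hundredths. Subtype labels cycle
A/F/PT/TA (benign) and DC/LC/MC/PC (malignant). Targets are clipped to
[1.05, 1.95]; a target above what the canvas can realize (the saturated
grid bounds the estimate near 2) raises "unattainable". All randomness
flows from one `numpy` Generator seeded by the spec.

What passing tests on these populations shows: the pipeline recovers a
planted fd separation and converts it into the expected classification
rates. What it does not show: anything about stain variation, nuclei
morphology, magnification effects, or whether real tumours separate —
those claims need real slides, for which the loaders and experiment
runners accept a BreaKHIS-style archive.

## Classification

* **Binary.** `FractalDimensionClassifier` wraps a linear SVM (C = 1.0,
  exposed) on the single fd feature. Its decision function is monotone
  in fd, so the model is stored and applied as a threshold plus an
  orientation (`threshold_ = −b/w`, `orientation_ = sign(w)`), which
  also makes the decision auditable. A tie — fd exactly at the
  threshold — is classified malignant by convention (measure-zero on
  real data, pinned for determinism). With one feature any monotone
  classifier is a threshold; the SVM is kept as the conventional choice
  and its implied threshold is tested against a brute-force
  accuracy-maximizing sweep.
* **Splits.** Stratified by label (or subtype), floor(fraction·n) per
  stratum to training, seeded shuffle. Seeds are mandatory: an unseeded
  random half is an irreproducible point estimate, so the experiment
  runner repeats over an explicit seed list and reports mean ± sd.
* **Metrics.** TP rate = correct malignant / malignant; TN rate likewise
  for benign; F1 = 2·TP·TN/(TP+TN), the harmonic mean of sensitivity
  and specificity — kept for fidelity to the convention this package
  reproduces, and flagged because it differs from the precision/recall
  F1. Rates round to 3 decimals in serialized output only; full
  precision is retained internally, and the rates are exactly
  recomputable from the stored confusion counts.
* **Multiclass (8 subtypes).** One-vs-one linear SVMs with majority
  voting (`SVC`'s native scheme). One-vs-rest was considered and is
  available, but on a single feature it is structurally degenerate:
  interior classes along the fd axis can never win the decision-function
  argmax, and perfectly separated 8-class data scores 0.25. Pairwise
  voting partitions the axis into per-class intervals and recovers
  separable data exactly. A nearest-class-mean baseline is included for
  sanity comparison. Subtypes present in evaluation but absent from
  training are counted as always-wrong with a warning.
* **Cross-subtype grid.** For each of the 4×4 (benign, malignant)
  subtype pairs: train on all records of those two subtypes, evaluate on
  all records of the six held-out subtypes, report per-pair TP/TN/F1 and
  the arithmetic mean of the 16 F1 values. This probes whether the fd
  threshold generalizes to tumour types never seen in training.

## Problem sizes

Validation fixtures run at the sizes quoted above (2048-px snowflake,
729-px gasket, ≤1024-px Cesàro curves); population tests use 12–20
images per class on 128–192-px canvases, and the classification
property tests use 150–300 Gaussian feature records per class. These
sizes put every statistical assertion's Monte-Carlo error well inside
its tolerance band while keeping the full suite under a minute.

## Known limitations

* Two-point (ε = 3, 4) estimates are scale-local: they measure edge
  density contrast between two grids, not asymptotic scaling, and can
  leave [1, 2] on degenerate images. That is faithful to the procedure
  being reproduced, and the multi-scale path exists for real dimension
  estimation.
* Grid anchoring at the origin makes counts translation-sensitive; no
  grid-offset averaging is performed (deliberately, to keep the
  estimator exactly reproducible).
* Default splits are image-level; slides from one patient can land on
  both sides. Patient directories are parsed and recorded, so
  leakage-safe grouping can be layered on, but it is not the default
  because the reproduced experimental design splits images.
* The stroke-texture population model matches fd distributions only; it
  is not a histology simulator.
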