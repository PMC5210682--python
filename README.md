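# fractodim

Box-counting fractal dimension of histopathology edge maps, and
benign-vs-malignant classification of breast-tumour slides from that
single feature.

Manual grading of H&E-stained histology slides suffers from inter- and
intra-observer variability. One line of work replaces subjective visual
assessment with a single quantitative image feature: the **fractal
dimension** of the slide's binarized, edge-detected structure. Benign
tissue, with its differentiated morphology and abundant extracellular
detail, tends to produce more complex edge maps (higher dimension) than
malignant tissue under H&E staining, so a one-dimensional threshold —
found by a support vector machine — separates the classes surprisingly
well at low magnification.

This package implements that pipeline end to end for anyone who wants to
reproduce, stress-test, or extend it: image preprocessing, a fast
integral-image box counter, synthetic fractal generators of known
dimension for validation, the classification experiments, and a CLI.

## The estimator

For a binary image, partition it into a non-overlapping grid of ε×ε
boxes anchored at the origin and count the boxes containing at least one
set pixel, N(ε). The box-counting dimension is

```
d_b = lim_{ε→0} log N(ε) / log(1/ε),
```

estimated in practice as the least-squares slope of log N(ε) against
log(1/ε) over a set of scales. For 700×460 slide images the default
scale pair is ε ∈ {3, 4}; larger boxes are too coarse for images that
small, and the two-point slope has the closed form
log(N₃/N₄) / log(4/3). An integral image (summed-area table) reduces
each box count to four table lookups.

Classification trains a linear SVM on the single fd feature (stratified
random half for training). Because the decision function of a 1-D
linear SVM is monotone, the fitted model is exactly a threshold plus an
orientation, both exposed as `threshold_` and `orientation_`. The
reported F1 is the harmonic mean of the true-positive rate (sensitivity,
malignant) and true-negative rate (specificity, benign):
`F1 = 2·TP·TN/(TP+TN)` — note this is *not* the precision/recall F1.

## Worked example

```python
from fractodim import (FractalSpec, PopulationSpec, SplitSpec, FDRecord,
                       render_fractal, fractal_dimension_of, generate_population,
                       split_records, train_binary, evaluate_binary)

# 1. validate the estimator on a curve of known dimension (log4/log3 ≈ 1.2619)
koch = render_fractal(FractalSpec(kind="koch_snowflake", iterations=5, size=2048))
result = fractal_dimension_of(koch, epsilons=[2, 4, 8, 16, 32], preprocessed=True)
print(f"Koch snowflake dimension: {result.dimension:.4f}")

# 2. two-class synthetic population -> fd feature table -> SVM threshold
pop = generate_population(PopulationSpec(n_per_class=20, seed=42))
records = [
    FDRecord(image_id=f"img{i:03d}", magnification="40x", label=label,
             subtype=subtype, fd=fractal_dimension_of(img, preprocessed=True).dimension)
    for i, (img, label, subtype) in enumerate(pop)
]
train, test = split_records(records, SplitSpec(fraction=0.5, seed=7))
model = train_binary(train)
report = evaluate_binary(model, test)
print(f"threshold: {model.threshold_:.3f}")
print(f"TP {report.tp_rate:.3f}  TN {report.tn_rate:.3f}  "
      f"F1 {report.f1:.3f}  accuracy {report.accuracy:.3f}")
```

Output:

```
Koch snowflake dimension: 1.2609
threshold: 1.665
TP 1.000  TN 1.000  F1 1.000  accuracy 1.000
```

The Koch estimate lands within 0.001 of the closed-form 1.2619. The
synthetic population puts benign slides at mean dimension 1.80 and
malignant at 1.55 (sd 0.05, a 5σ gap), so the learned cut at 1.665
separates the held-out half perfectly; with overlapping classes the
same code reports the corresponding error rates.

The CLI wraps the same steps:

```bash
fractodim synth-pop --n-per-class 40 --seed 0 --out-dir synthetic/
fractodim compute-fd --input synthetic/ --layout flat_csv --out fd.csv
fractodim classify --fd fd.csv --magnification 40x --seed 7 --out report.json
fractodim experiment --fd fd.csv --mode grid --out grid.csv
fractodim summarize --input synthetic/ --layout flat_csv
```

If you have the BreaKHIS archive on disk, point `compute-fd --input` at
its root (`--layout breakhis`) to build the real feature table; the
experiment commands then reproduce the published experimental design
(per-magnification binary splits, 8-subtype classification, and the 16
single-benign × single-malignant training-set grid).

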