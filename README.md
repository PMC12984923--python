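# entrosel

Entropy-based texture descriptors and metaheuristic wrapper feature
selection for binary classification of MRI regions of interest (tumor vs.
non-tumor brain tissue).

Tumor tissue in MRI shows higher structural irregularity and more
heterogeneous intensity distributions than healthy tissue. `entrosel`
quantifies that irregularity by flattening each standardized ROI into a 1-D
intensity signal and computing a bank of **39 entropy measures** — classical
(Shannon, approximate, sample, permutation, spectral), modern nonlinear
descriptors (dispersion, fuzzy, bubble, slope, attention, diversity, ...)
and ten cross-signal variants that relate a region to the complementary
region of the same image. The resulting high-dimensional descriptor is then
pruned by a **wrapper feature selector** driven by the superb fairy-wren
optimization algorithm (SFOA), with PSO, HHO and a compact puma-optimizer
variant as baselines, and classified with a k-nearest-neighbor model
(k = 1, Euclidean, standardized features; linear SVM for comparison) under
stratified 10-fold cross-validation.

## The optimization core

Candidate solutions are positions `X ∈ [0,1]^39`; coordinates above the 0.8
threshold select the corresponding feature (at least one feature is always
kept). Each candidate is scored by

```
fitness = α · (1 − Accuracy) + (1 − α) · Ns / Nt,        α = 0.99
```

where `Accuracy` is validation accuracy of a 1-NN classifier on the masked
table, `Ns` the number of selected features and `Nt = 39`. SFOA updates each
individual per iteration with one of three stages:

* **growth** `X ← X_t + rand · (X_t − X_{t−1})` — wide exploratory jumps,
* **breeding** `X ← X_b + C · p · (X_t − X_b)` with `C = 0.8` and maturity
  `p = FEs/MaxFES` — contraction toward the population best,
* **enemy avoidance** `X ← X_t + l · k · (X_b − X_t)` with a Lévy step `l`
  and flight coefficient `k = 0.2 · sin(π/2 − ω)`, `ω = (π/2) · FEs/MaxFES`
  — heavy-tailed escapes that shrink over the run,

with greedy acceptance, population 50 and 100 iterations by default.

Because the real scan collection and trained detector are external, the
package ships a first-class synthetic generator: smooth AR(1)-textured
"brain" tissue versus high-variance speckle "tumor" blobs, with YOLO-format
boxes, leak-free train/val/test splits, and a paper-emulation mode
(583/123/128 images, two ROIs per test image → a 256-row evaluation table).

## Worked example

Select features on a synthetic 60 + 60 sample benchmark and cross-validate
the selected subset:

```python
import numpy as np
from entrosel.entropy import FEATURE_IDS, build_feature_table
from entrosel.synthetic import SynthConfig, generate_pair_table
from entrosel.optimize import FitnessContext, OptimizerConfig, run_optimizer
from entrosel.classify import cross_validate

pairs = generate_pair_table(60, 256, SynthConfig(seed=42), seed=42)
df = build_feature_table(pairs)
x = df[list(FEATURE_IDS)].to_numpy(float)
y = (df["class"] == "tumor").astype(int).to_numpy()

ctx = FitnessContext(x, y, seed=42)
trace = run_optimizer(ctx, OptimizerConfig(population_size=20, max_iterations=30, seed=42))
print("selected:", trace.best_mask.selected_ids)
report = cross_validate(x[:, np.flatnonzero(trace.best_mask.bits)], y, folds=10, seed=42)
print(f"10-fold kNN accuracy = {report.accuracy:.4f}, AUC = {report.auc:.4f}")
```

prints

```
selected: ['F17']
10-fold kNN accuracy = 1.0000, AUC = 1.0000
```

i.e. on this synthetic benchmark the wrapper collapses the 39-dimensional
descriptor to a single feature (F17, fuzzy entropy at m = 2) that already
separates the planted tumor/background textures perfectly under 10-fold
cross-validation — the intended behavior of a size-penalized fitness when
one feature suffices.

The same flow is available from the shell:

```
entrosel simulate --mode quick --out data --seed 42
entrosel select --features features.csv --algorithm sfoa --seed 42 --out selection.json
entrosel classify --features features.csv --mask selection.json --model knn --out report.json
entrosel run --config config.yaml        # full pipeline from one YAML file
```

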