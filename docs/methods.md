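# Methods

## Problem and pipeline

`entrosel` classifies MRI regions of interest as tumor or non-tumor tissue
from 1-D entropy descriptors. The stages are: ROI standardization (Gaussian
denoise, bilinear resize, intensity rescale to [0, 255]); row-major raster
flattening to a 1-D signal; extraction of a fixed-order 39-feature entropy
vector; wrapper feature selection over the 39-dimensional binary space by a
population metaheuristic scored with a kNN; and final stratified 10-fold
cross-validated classification with confusion-matrix metrics and ROC/AUC.

## Preprocessing

* Denoising convolves with a normalized 2-D Gaussian (default sigma 1.0 px,
  truncated at 4 sigma, reflective borders); sigma 0 is the identity.
* Resizing uses bilinear interpolation with align-corners mapping so corner
  samples are preserved; the standard ROI size is 64 x 64 (configurable).
  These two defaults are implementation choices — no standardized ROI
  resolution or denoising bandwidth is prescribed by the task itself.
* YOLO center-format boxes are denormalized by rounding half up into
  0-based half-open pixel intervals; crops smaller than 2 x 2 are rejected.
* Intensities are linearly rescaled per ROI to [0, 255] so histogram-based
  measures see a fixed support; a constant ROI maps to all zeros.
* Raster order is row-major from the top-left; flattening is a bijection and
  is inverted exactly by `unflatten_signal`.

## The 39-feature entropy bank

Features F1–F26 are single-signal measures, F27–F39 cross measures feeding
on (primary, reference). The reference is the complementary-region signal
of the same source image (tumor ROI <-> non-tumor ROI); an image
contributing a single ROI self-references. Unequal lengths are truncated to
the shorter signal and flagged.

Tolerance for template-matching measures (approximate, sample, fuzzy,
composite multiscale, and the cross variants) is r = 0.2 x SD of the
primary signal, the standard literature default. Range entropy (RangeEn-B)
is the one exception: its template distance is the normalized range ratio
(max|diff| − min|diff|)/(max|diff| + min|diff|) in [0, 1], so r is a fixed
ratio 0.2 — an amplitude-scaled tolerance would make every template pair
match and degenerate the measure.

Embedding and quantization defaults (all overridable per feature):
tau = 1 everywhere; permutation m = 3; dispersion m = 2 with c = 6
normal-CDF classes; distribution entropy m = 2 with 512 distance bins;
bubble entropy m = 10 (Renyi-2 swap-count entropy); cosine-similarity
entropy m = 2, angular tolerance 0.1; corrected conditional entropy m = 2
with 6 uniform quantization bins; diversity entropy m = 2 with 5 cosine
bins; entropy-of-entropy 5-sample windows and 5 amplitude levels; gridded
distribution entropy on a 3 x 3 Poincare grid; phase entropy over 4 sectors
of the second-order difference plot; slope entropy m = 2 with thresholds
5.0 and 0.001 intensity units; Shannon entropy over 256 bins on [0, 255].
Each default follows the measure's original publication; none is tuned to
the classification task.

Degenerate-case conventions:

* "m = 0" approximate/sample entropy is taken literally through the
  generalized formulas: zero-length templates all match, so ApEn(0) = −Phi^1
  and SampEn(0) uses all ordered point pairs as the denominator.
* A sample-entropy ratio with a zero count returns the finite cap
  ln(B) + ln(N − m) with a "capped" flag instead of infinity, keeping
  feature vectors finite.
* Spectral entropy excludes the DC bin; the all-zero signal is invalid,
  while a non-zero constant signal (all power at DC) is defined as 0.
* Cross-approximate and cross-Kolmogorov entropy have no self-match
  guarantee and can be non-finite when the two regions' intensity ranges do
  not overlap within r; such values are flagged and imputed at table level
  with the feature's column median. Cross-Kolmogorov entropy — a K2-style
  estimator ln(C_m/C_{m+1}) on cross correlation sums — is the least
  standardized measure in the bank and is included for completeness.

Every measure is verified against an explicit brute-force loop
implementation on short signals to 1e-9 in the test suite, and extraction
is bit-deterministic.

## Wrapper feature selection

Positions live in [0,1]^39 and are binarized at threshold 0.8; if no
coordinate exceeds the threshold the single largest coordinate is kept
(lowest index on ties), so every mask selects at least one feature. The
objective is fitness = alpha (1 − Accuracy) + (1 − alpha) Ns/Nt with
alpha = 0.99 — the weighting is an implementation default (standard in
wrapper selection); accuracy comes from a 1-NN on a stratified 30% held-out
validation split fixed by the context seed (k-fold optional). The budget is
MaxFES = N x iterations with initialization evaluations counted on top.

SFOA interpretation choices (the update stages themselves are in the
README): each individual draws u ~ U(0,1) per iteration and applies growth
(u < 1/3), breeding (u < 2/3) or enemy avoidance; the growth-stage `rand`
is a single scalar per update applied to all coordinates (configurable to
per-coordinate); at the first iteration the previous position equals the
initial position, making growth a no-op there; the Levy exponent is
beta = 1.5 via the Mantegna algorithm; updates are clipped to the unit box
and accepted greedily, so best-fitness traces are non-increasing.

Baselines share initialization, binarization and the fitness path:

* **PSO** — canonical global-best form, inertia 0.9 -> 0.4 linearly,
  c1 = c2 = 2.0.
* **HHO** — linearly decaying escape energy with the standard
  soft/hard-besiege and progressive Levy-dive branches.
* **PO** (version `entrosel-compact-1`) — a compact re-implementation of
  the puma optimizer's two-phase logic: exploration (full random leaps and
  three-member differential moves) and exploitation (Levy-scaled ambush
  toward the best, noisy sprints), with the phase chosen by an
  exponentially smoothed score of recent improvement and greedy acceptance.
  It is not a line-by-line port of the published algorithm and is versioned
  accordingly.

## Classification and evaluation

kNN uses k = 1, Euclidean distance, uniform weights, on features
standardized with training statistics only (zero-SD columns map to zero and
are flagged). Vote ties at even k fall back to the nearest neighbor; equal
distances break toward the lower training index. Because raw 1-NN votes
give a degenerate two-point ROC, the ROC score is the signed distance
margin d(nearest negative) − d(nearest positive). The SVM comparison is a
soft-margin linear SVM at box constraint 1 on standardized features
(scikit-learn backend).

Precision, recall and F1 are macro-averaged over the two classes (each
class treated as positive in turn, averaged with equal weight); accuracy is
(TP+TN)/total. Cross-validation is stratified with a seeded shuffle,
standardization is fit inside each training fold, every sample is predicted
exactly once, and AUC comes from a trapezoidal threshold sweep that equals
the pairwise rank statistic (ties 1/2) — an equivalence the tests check on
random fixtures.

## Synthetic data

The generator plants the class structure the feature bank is meant to
detect: non-tumor tissue is a smooth AR(1) texture (coefficient 0.95,
innovation SD 8, lightly blurred) on a brain-like elliptical disk; tumor
tissue is an elliptical blob of speckle texture (white noise SD 40 mixed
50/50 with sparse exponential bursts, rate 0.15, scale 90) at a higher mean
level. These are the simplest processes that make entropy descriptors
class-discriminative while keeping the amplitude ranges overlapping. Each
image yields one non-tumor box, tumor images additionally a tumor box;
images are split train/val/test (0.70/0.15/0.15) by a seeded shuffle before
any ROI extraction, and no source image crosses splits. Paper-emulation
mode fixes 583/123/128 tumor-bearing images with within-image
tumor/background pairing, so the test split yields a 256-row table. Every
artifact is reproducible from (config, seed); each image uses a child RNG
keyed by (seed, index) so any single split can be materialized without
generating the rest.

What the generator does **not** emulate: anatomical structure, scanner
noise physics, partial-volume effects, inter-patient variability, detector
localization error, or any correlation structure beyond first order.
Passing tests therefore demonstrate the correctness and discriminative
machinery of the pipeline, not clinical performance on real MRI.

## Problem sizes and numerical choices

The test suite and examples run the generator at desk scale as the
package's own default study conditions: signals of length 256 for feature
benchmarks, 60 + 60 sample tables, selection budgets of population 20 with
30 iterations for recovery experiments (population 50 / 100 iterations
remain the configured defaults), and 24–64 px ROIs. Histogram edge cases
use left-inclusive bins with the maximum value folded into the last bin;
all stochastic components consume explicit `numpy` Generators, and repeated
runs with the same seeds are bit-identical.

## Known limitations

* The cross-measure pairing rule (complementary region of the same image)
  is one of several defensible choices; it is configurable at the data
  layer, not asserted as canonical.
* Chronically non-finite cross measures (F27–F29, F34–F35 on well-separated
  intensity ranges) carry no information after median imputation; they are
  retained to keep the fixed 39-feature contract.
* The PO baseline is a compact variant, suitable as a comparison point but
  not as a reference implementation of the published algorithm.
* Wrapper fitness uses a single held-out split for speed; selection
  variance across seeds is therefore larger than a full CV-scored wrapper
  would give.
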