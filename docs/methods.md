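# Methods

`thgqc` implements a tissue-to-inference pipeline for glioma vs. non-tumor
classification of third-harmonic-generation (THG) microscopy images:
frequency-domain quality screening, a fully-convolutional binary
classifier trained under case-level Monte-Carlo cross-validation,
Youden-calibrated evaluation, and sliding-window semantic overlays of
stitched mosaics. A phantom generator supplies synthetic data with known
ground truth so every stage can be exercised end to end on one CPU.

## The imaging problem

THG microscopy of fresh brain tissue produces a "shadow contrast":
myelinated fibers appear as bright curves on a mid-gray parenchyma
background, neuronal cell bodies as dark holes with dimly visible nuclei.
Glioma tissue shows an elevated density of cell bodies. Images come as
single 2-D shots, depth stacks (z-stacks) and large stitched mosaics,
saved as 16-bit TIFF. Because THG generation is limited by the admissible
laser power, signal falls off with imaging depth; deep stack slices sink
into the detector noise floor while still inheriting their case's weak
(diagnosis-level) label. Left in a training set, such images act as
label noise.

## Quality screening

For each image the 2-D discrete Fourier transform of the mean-subtracted
pixels is taken; each coefficient gets a radial frequency normalized so
1.0 is the Nyquist frequency of the shorter axis. The *tail* is the set
of power values (squared magnitudes) at radius `>= 1 - freq_frac`, DC
excluded. Seven descriptive statistics are computed per tail (mean,
inverse mean, standard deviation, inverse standard deviation, coefficient
of variation, kurtosis, skewness); the exclusion rule acts on the
**Pearson kurtosis** m4/m2² (3 for a Gaussian): an image is excluded from
training when its tail kurtosis exceeds the cutoff. A condition is a
(freq_frac, cutoff) pair; the canonical sweep uses (none, none), (0.4,
10), (0.4, 5), (0.2, 10), (0.2, 5), (0.1, 10), (0.1, 5).

Why kurtosis indicates noise here: for a signal-dominated, band-limited
image the tail carries little power with a homogeneous distribution; for
a noise-dominated image the tail is a mixture of exponentially
distributed power values whose scale varies across the band whenever the
noise is not perfectly white, and scale mixtures of exponentials are
leptokurtic (pure white Gaussian noise gives exactly exponential tail
power, kurtosis 9; any coloration pushes kurtosis higher).

Numerical choices: statistics use population moments on raw power
(log-power and a 1-D azimuthally averaged spectrum are available as
variants); a zero-variance tail yields NaN kurtosis and is excluded by
default; the radial 2-D tail makes the statistic exactly invariant to
90-degree rotations and to intensity rescaling. The test set is never
filtered. Kurtosis estimates are noisy below roughly 100x100 px (the
tail then holds only ~1-2k heavy-tailed values), so quality screening in
the desk-scale experiments uses 96 px fields.

## Phantom generator

Appearance-level emulation, not optics simulation. Structures: dark
anti-aliased discs (cell bodies, radius 3-6 um by default) with a dim
concentric nucleus, placed by a Poisson process at 300 (normal) vs. 1200
(tumor) cells/mm²; bright curvilinear fibers as smoothed random walks;
a Gaussian PSF blur (0.4 um) keeps structures band-limited. Overlapping
cell bodies darken by maximum coverage, not additively, so the noise-free
signal stays strictly positive. Depth is modelled by scaling the whole
detected signal by exp(-decay x depth).

Noise: (a) photon shot noise as stationary Gaussian noise with the
variance of a Poisson count at the field-mean photon rate (default 300
photons/pixel per unit intensity) — white, and decaying with depth
together with the signal; (b) a depth-independent detector floor on a
dark pedestal (offset 0.08): white sigma 0.010 plus a correlated
component sigma 0.035 smoothed over 0.35 um. Two deliberate departures
from per-pixel physicality matter: per-pixel Poisson rates modulated by
the structure would correlate neighbouring spectrum coefficients and
destabilize small-field kurtosis, and without the pedestal deep
noise-dominated slices clip at zero, whose rectification whitens the
spectrum tail. Both effects were verified numerically; with the chosen
model, shallow slices have tail kurtosis near the white-noise value of 9
and deep slices drift to 12-16 as the colored floor takes over, which
reproduces the observed rise of kurtosis with stack depth (mean Spearman
correlation ~0.7-0.8 over seeded 256 px stacks at decay 0.04/um).

What the phantoms do *not* emulate: real THG texture and speckle,
vasculature and necrosis, stitching seams in mosaics, inter-patient
heterogeneity, and any quantitative biology (the density defaults are
free parameters chosen so a 256 px field holds a handful of cells, not
claims about tissue). Passing tests therefore show the pipeline's
machinery is correct and that the kurtosis rule behaves as designed under
this noise model — not that the classifier would reach any particular
accuracy on clinical data.

## Classifier

Six blocks: four of (5x5 convolution, batch normalization, ReLU, 2x2 max
pooling) with 32/64/128/256 channels, then 1x1 convolution to 64
channels with batch norm and ReLU, then 1x1 convolution to 1 channel and
global average pooling; a sigmoid squashes the pooled logit
(pool-then-squash). Convolutions use "same" zero padding so any input of
at least 16x16 px (four pooling halvings) is accepted; odd extents are
floor-divided at pooling. All kernels are L2-regularized (factor 0.01,
kernels only) and He-uniform initialized. Default parameter count
(convolution weights + biases): 832 + 51,264 + 204,928 + 819,456 +
16,448 + 65 = 1,092,993.

The network, batch normalization and SGD with momentum are implemented
directly on NumPy (NHWC layout; convolution as k² channel-mixing matmuls
over shifted views, so the work stays in BLAS; float64 mode exists for
gradient checking, and the backward pass is verified against finite
differences). Batch-norm inference uses running statistics with
configurable momentum; the desk-scale configuration uses momentum 0.5 so
the running statistics converge within the few dozen optimizer steps of
a small run (with the conventional 0.9-0.99 the inference-mode statistics
lag the weights, which miscalibrates the validation loss that drives
checkpointing and early stopping).

## Training protocol

Monte-Carlo cross-validation at the case level: each split's validation
fold holds 1 randomly chosen negative (histologically normal) case and 4
positive (glioma) cases; no case appears on both sides of a split. Each
epoch — in both the training and validation phase — balances the classes
by oversampling the minority with replacement, augments every sampled
image freshly (contrast U(0.8, 1.2) about the image mean, brightness
U(-0.1, 0.1), rotation U(0°, 360°) with reflect padding; values clipped
to [0, 1]) and zero-pads per batch to the batch's largest extent.
Validation scoring is per-image and unpadded. Optimizer: SGD, momentum
0.9; the learning rate shrinks by 0.2 when the validation loss fails to
improve by 1e-4 for 5 epochs; early stopping after 10 epochs without
improvement; the checkpoint is the epoch with the lowest validation
loss, whose accuracy (threshold 0.5) and AUC are what a sweep reports.
Full-scale defaults are learning rate 1e-4 and up to 200 epochs.

In the condition-sweep experiment the exclusion rule filters only the
training side of each split; validation folds are never filtered, so
every condition is validated on identical unfiltered folds and the
comparison is paired across conditions. (A `filter_validation=True` mode
also cleans validation folds per condition — it raises the attainable
validation AUC for good rules, but at desk scale a strict rule's folds
shrink to a couple of images, whose AUC estimates are too coarse and
optimistic to compare conditions honestly.)

## Evaluation

ROC and precision-recall curves sweep the unique score values (decision
rule: score >= threshold is positive; ties enter simultaneously); AUC by
trapezoidal integration, average precision by step interpolation (its
no-skill baseline equals prevalence — 0.48 for 60 positives of 124).
The operating point maximizes Youden's J = sensitivity + specificity - 1
over the model's own test-set ROC thresholds, ties broken toward the
lowest qualifying threshold (deriving the threshold from the evaluation
data itself is optimistic; a fixed-0.5 mode is provided). Ensembles are
summarized by vertical curve averaging on a common abscissa grid with
population variance; the reported ensemble AUC/AP is the mean of member
scalars, not the area of the mean curve.

## Overlays

A sliding window (default 256 px, stride 8; stride 1 for the smoothest
maps) scores every full window position; each covered pixel accumulates
the window score (float sum + integer count, so the conservation
identity "sum of mean_score x coverage = sum of window scores x window
area" holds to float precision); partial edge windows are skipped.
Thresholding the mean map (tumor where score >= threshold; uncovered
pixels are background) yields a two-class mask scored against a
reference mask with the per-class Jaccard index; a class absent from
both masks reports NaN.

## Desk-scale experiment sizes

The full-scale study shape (12,500 training images up to 1000x1000 px,
10 splits per condition, ~120-epoch runs) is reduced to CPU scale while
preserving each phenomenon; these are the package's own problem sizes,
stated in `thgqc.experiments`:

* **Learnability**: 48 px fields, cell radius 1.5-3 um, densities scaled
  inversely with field area (2,600 vs. 20,800 cells/mm², i.e. ~1.5 vs.
  ~12 cells per field), 9 cases / 54 images, 12 epochs, batch 16,
  learning rate 0.02. The same trained model drives the boundary-mosaic
  overlay check (256x512 px mosaic, 96 px windows, stride 16, threshold
  at the model's own Youden operating point from its validation fold).
* **Condition sweep**: 96 px fields (stable kurtosis), 9 cases x 9
  images each (3 single shots + one 6-slice stack at decay 0.06/um per
  case, so roughly a third of the pool is noise-dominated), with
  case-level rendering heterogeneity (background, contrast and density
  jittered ±25% per case — the inter-patient variability that makes
  generalization require a diversity of training cases); 3 splits with
  1+1-case validation folds, 6 epochs; conditions none / (0.2, 13)
  moderate / (0.2, 8.5) over-strict (>80% pool exclusion). Moderate
  exclusion removes most noise-dominated slices and raises mean
  validation AUC; the over-strict rule strands training on a handful of
  images from few cases and falls far below the unfiltered baseline.
* **Depth trend**: 10 stacks of 8 slices at the full 256 px defaults,
  decay 0.04/um.

## Known limitations

* The NumPy network is single-threaded BLAS-bound; it is sized for
  experiments of tens of images, not for the full-scale study.
* Kurtosis screening is unreliable for fields much below ~100 px.
* The phantom noise model is a design choice that reproduces the
  qualitative depth-kurtosis behaviour; real detector noise differs in
  detail, and absolute kurtosis cutoffs do not transfer between the
  phantom and any real instrument.
* Youden thresholds derived from the test data overstate deployed
  accuracy; the fixed-threshold mode should be used for honest
  prospective estimates.
* The permuted-label control is not expected to land exactly at AUC 0.5
  on ~50 images: a random permutation retains a chance correlation of
  order 1/sqrt(n) with the true labels, the same permutation defines
  both the training target and the evaluation labels, and whichever sign
  the chance correlation takes is learnable and scored consistently —
  so the control's AUC is biased above 0.5 at small n (typically
  0.55-0.7 here). The check is that it collapses far below the true-label
  AUC, not that it hits 0.5 exactly.
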