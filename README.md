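# thgqc

Quality-filtered deep-learning classification of third-harmonic-generation
(THG) microscopy images of brain tissue.

THG microscopy images fresh, unstained brain tissue in seconds: myelinated
fibers appear as bright curves, neuronal cell bodies as dark holes with
dimly visible nuclei, and glioma tissue shows an elevated cell-body
density. A classifier that flags tumor tissue in such images in real time
could give a neurosurgeon histology-level feedback during resection. Two
practical obstacles stand between raw acquisitions and a usable
classifier, and this package implements the pipeline that addresses both:

1. **Noise exclusion.** THG signal decays with imaging depth, so deep
   stack slices degrade into detector noise while still inheriting their
   patient's diagnosis as a (weak) label. `thgqc` screens every training
   image by the **kurtosis of its power-spectrum tail** — the
   distribution of 2-D Fourier power over the top fraction (e.g. 20%) of
   the radial frequency range. White-noise tails are exponential
   (Pearson kurtosis 9); colored noise floors push kurtosis higher, so
   noise-dominated images stand out and are excluded when their kurtosis
   exceeds a cutoff. Exclusion conditions (frequency fraction × cutoff)
   are compared by Monte-Carlo cross-validated training.
2. **Classification.** A 6-block fully-convolutional network — four
   blocks of 5×5 conv / batch norm / ReLU / 2×2 max-pool with 32, 64,
   128, 256 channels, a 1×1×64 conv block, and a final 1×1×1 conv with
   global average pooling and a sigmoid — emits one tumor score per
   image of *any* size ≥ 16×16 px (1,092,993 convolution parameters).
   Training balances classes by minority oversampling with fresh
   contrast/brightness/rotation augmentation each epoch; splits are by
   patient case, never by image. Evaluation reports ROC-AUC, average
   precision, and Youden-calibrated accuracy/sensitivity/specificity;
   mosaics are segmented by sliding-window scoring with per-pixel
   averaging and scored against reference masks with the Jaccard index.

A phantom generator renders THG-like tissue images (dark cell bodies
with dim nuclei, bright curvilinear fibers, depth-dependent signal loss,
boundary mosaics, imbalanced multi-case datasets) with known ground
truth, so the whole pipeline is testable end to end on one CPU. The
network and its training loop are implemented directly on NumPy.

## Worked example

```bash
python examples/simulate_phantoms.py
```

prints (seed 0):

```
normal:  2 cell bodies rendered (Poisson mean 4.9), fiber coverage 3.5%
tumor : 17 cell bodies rendered (Poisson mean 19.7), fiber coverage 3.0%

depth stack (10 um steps), tail kurtosis per slice:
  slice 0 (signal x1.00): kurtosis   8.4
  slice 1 (signal x0.67): kurtosis   9.0
  ...
  slice 6 (signal x0.09): kurtosis  11.6
  slice 7 (signal x0.06): kurtosis  14.7
rising kurtosis marks slices sinking into the noise floor; the exclusion
rule drops them from training.
```

The tumor field holds ~4× the cell bodies of the normal field (the
ground truth a classifier learns), and the spectral-tail kurtosis rises
from ≈9 (white shot noise) toward 12–16 as depth attenuates the signal
into the colored detector floor — the behaviour the quality filter keys
on. Further examples: `examples/quality_screening.py` (the 7-condition
exclusion sweep), `examples/train_and_evaluate.py` (training, ROC/Youden
metrics), `examples/segment_mosaic.py` (boundary-mosaic overlay + IOU).

The `thgqc` command mirrors the pipeline stages
(`simulate`, `preprocess`, `qc`, `train`, `sweep`, `evaluate`,
`segment`, `run`, `model-info`); `thgqc run --config experiment.yaml`
executes everything from one YAML file.

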