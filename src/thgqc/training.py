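"""Monte-Carlo cross-validation training of the classifier.

Splitting is by *case*, never by image: a validation fold holds 1 randomly
drawn negative-class (histologically normal) case and 4 positive-class
(glioma) cases, and no case contributes images to both sides — the
case-level split is what keeps weakly labeled images of one patient from
leaking across folds. Each training condition gets ``n_splits``
independent draws, one trained model each.

Within an epoch both phases see class-balanced streams: the minority class
is oversampled with replacement until the classes are equal, every sampled
image receives a fresh random contrast/brightness/rotation augmentation,
and images are zero-padded per batch to the batch's largest extent.
Optimization is SGD with momentum; the learning rate shrinks by
``plateau_factor`` whenever the validation loss stops improving, and early
stopping returns the parameters from the epoch with the lowest validation
loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from thgqc.evaluation import ScoredSet, metrics_at_threshold, roc_auc
from thgqc.fcn_model import FCNClassifier, FCNConfig, build_fcn
from thgqc.io_manifest import LABEL_NORMAL, LABEL_TUMOR, CaseManifest
from thgqc.nn import SGDMomentum, bce_with_logits, sigmoid
from thgqc.quality import QualityCondition, apply_quality_condition

logger = logging.getLogger(__name__)


class Sample(NamedTuple):
    """One training example: unit-scaled pixels, binary label, provenance."""

    pixels: np.ndarray  # float32 in [0, 1]
    label: int  # 1 = tumor, 0 = normal
    case_id: str
    image_id: str


def samples_from_records(records: Sequence) -> list[Sample]:
    """Convert ImageRecords to training samples (tumor = positive class)."""
    out = []
    for i, rec in enumerate(records):
        top = 2.0**rec.bit_depth - 1.0
        out.append(Sample(
            pixels=(rec.pixels / top).astype(np.float32),
            label=1 if rec.label == LABEL_TUMOR else 0,
            case_id=rec.case_id,
            image_id=f"{rec.case_id}/{i}",
        ))
    return out


@dataclass(frozen=True)
class SplitSpec:
    """One Monte-Carlo train/validation split at the case level."""

    split_id: int
    train_case_ids: frozenset[str]
    val_case_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_case_ids & self.val_case_ids:
            raise ValueError("train and validation cases overlap")


@dataclass
class TrainConfig:
    """Optimizer schedule and augmentation ranges.

    Defaults are the full-scale settings (SGD, momentum 0.9, initial
    learning rate 1e-4, plateau factor 0.2, early-stop patience 10,
    batches of 32, up to 200 epochs). Desk-scale experiments shrink
    ``max_epochs``/``batch_size`` and raise ``learning_rate`` to keep the
    optimization step count meaningful.
    """

    learning_rate: float = 1e-4
    momentum: float = 0.9
    plateau_factor: float = 0.2
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    early_stop_patience: int = 10
    batch_size: int = 32
    max_epochs: int = 200
    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    rotation_degrees: tuple[float, float] = (0.0, 360.0)
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patience values must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch curves plus the checkpoint of the best epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch]

    @property
    def best_val_auc(self) -> float:
        return self.val_auc[self.best_epoch]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "val_auc": self.val_auc,
            "learning_rate": self.learning_rates,
        })


def make_mc_splits(manifest: CaseManifest, n_splits: int, seed: int,
                   n_val_negative: int = 1, n_val_positive: int = 4
                   ) -> list[SplitSpec]:
    """Draw ``n_splits`` random case-level train/validation splits.

    Each split's validation fold holds ``n_val_negative`` normal cases and
    ``n_val_positive`` tumor cases, drawn independently per split (splits
    may therefore repeat cases across draws). Deterministic under ``seed``.
    """
    train_rows = manifest.rows_for_role("train")
    by_class: dict[str, list[str]] = {"epilepsy": [], "glioma": []}
    for case_id in sorted(train_rows["case_id"].unique()):
        diag = train_rows.loc[train_rows["case_id"] == case_id,
                              "diagnosis"].iloc[0]
        by_class[diag].append(case_id)
    n_neg, n_pos = len(by_class["epilepsy"]), len(by_class["glioma"])
    if n_neg < n_val_negative + 1 or n_pos < n_val_positive + 1:
        raise ValueError(
            f"need at least {n_val_negative + 1} negative and "
            f"{n_val_positive + 1} positive cases for validation folds of "
            f"{n_val_negative}+{n_val_positive}; got {n_neg}+{n_pos}"
        )
    rng = np.random.default_rng(seed)
    splits = []
    all_cases = set(by_class["epilepsy"]) | set(by_class["glioma"])
    for k in range(n_splits):
        val = set(rng.choice(by_class["epilepsy"], n_val_negative,
                             replace=False))
        val |= set(rng.choice(by_class["glioma"], n_val_positive,
                              replace=False))
        splits.append(SplitSpec(
            split_id=k,
            train_case_ids=frozenset(all_cases - val),
            val_case_ids=frozenset(val),
            seed=seed,
        ))
    return splits


def augment_image(pixels: np.ndarray, rng: np.random.Generator,
                  config: TrainConfig) -> np.ndarray:
    """Random contrast, brightness and rotation; output clipped to [0, 1].

    Contrast scales deviations from the image mean; rotation is around the
    image centre with reflect padding (right-angle rotations take the
    exact array-rotation path).
    """
    c_lo, c_hi = config.contrast_range
    b_lo, b_hi = config.brightness_range
    r_lo, r_hi = config.rotation_degrees
    if c_hi <= 0 and b_hi < 0:
        logger.warning("augmentation ranges force an all-black output")
    c = rng.uniform(c_lo, c_hi)
    b = rng.uniform(b_lo, b_hi)
    angle = rng.uniform(r_lo, r_hi)
    out = pixels.astype(np.float32)
    quarter, rem = divmod(angle, 90.0)
    if math.isclose(rem, 0.0, abs_tol=1e-9):
        out = np.rot90(out, k=int(quarter) % 4)
    elif angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1,
                             mode="reflect")
    if c != 1.0:
        out = out.mean() + c * (out - out.mean())
    if b != 0.0:
        out = out + b
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _balanced_indices(labels: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Oversample the minority class with replacement to equal counts."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to balance an epoch")
    n = max(len(pos), len(neg))
    take_pos = pos if len(pos) == n else rng.choice(pos, n, replace=True)
    take_neg = neg if len(neg) == n else rng.choice(neg, n, replace=True)
    idx = np.concatenate([take_pos, take_neg])
    rng.shuffle(idx)
    return idx


def pad_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    """Zero-pad images (top-left anchored) to the batch's max extent."""
    h = max(im.shape[0] for im in images)
    w = max(im.shape[1] for im in images)
    out = np.zeros((len(images), h, w), dtype=np.float32)
    for i, im in enumerate(images):
        out[i, : im.shape[0], : im.shape[1]] = im
    return out


def make_epoch_stream(samples: Sequence[Sample], rng: np.random.Generator,
                      batch_size: int, config: TrainConfig
                      ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """One epoch of balanced, freshly augmented, zero-padded batches."""
    labels = np.array([s.label for s in samples])
    idx = _balanced_indices(labels, rng)
    for start in range(0, len(idx), batch_size):
        chunk = idx[start:start + batch_size]
        imgs = []
        for i in chunk:
            px = samples[i].pixels
            if config.augment:
                px = augment_image(px, rng, config)
            imgs.append(px)
        yield pad_batch(imgs), labels[chunk].astype(np.float32)


def _evaluate_stream(model: FCNClassifier, samples: Sequence[Sample],
                     rng: np.random.Generator, config: TrainConfig
                     ) -> tuple[float, float, float]:
    """Balanced validation pass: (loss, accuracy@0.5, AUC).

    Mirrors the training stream (balancing and augmentation in the
    validation phase too); scoring is per-image and unpadded, in inference
    mode.
    """
    labels = np.array([s.label for s in samples])
    idx = _balanced_indices(labels, rng)
    imgs = []
    for i in idx:
        px = samples[i].pixels
        if config.augment:
            px = augment_image(px, rng, config)
        imgs.append(px)
    scores = np.empty(len(idx))
    by_shape: dict[tuple[int, int], list[int]] = {}
    for n, im in enumerate(imgs):
        by_shape.setdefault(im.shape, []).append(n)
    for pos in by_shape.values():
        for start in range(0, len(pos), config.batch_size):
            chunk = pos[start:start + config.batch_size]
            z = model.forward_logits(np.stack([imgs[n] for n in chunk]),
                                     train=False)
            scores[chunk] = z
    y = labels[idx]
    loss, _ = bce_with_logits(scores, y)
    p = sigmoid(scores)
    acc = float(np.mean((p >= 0.5).astype(int) == y))
    try:
        auc = roc_auc(ScoredSet(scores=p, labels=y)).auc
    except ValueError:
        auc = float("nan")
    return loss, acc, auc


def train_model(model: FCNClassifier, train_samples: Sequence[Sample],
                val_samples: Sequence[Sample], config: TrainConfig
                ) -> tuple[FCNClassifier, TrainHistory]:
    """Optimize ``model``; returns it restored to the best-epoch checkpoint.

    The checkpoint criterion is the balanced-validation binary
    cross-entropy; accuracy (threshold 0.5) and AUC are recorded at every
    epoch so the values at the lowest validation loss can be reported.
    """
    if not train_samples:
        raise ValueError("no training data (all images excluded?)")
    if not val_samples:
        raise ValueError("empty validation fold")
    rng = np.random.default_rng(config.seed)
    opt = SGDMomentum(model.layers, lr=config.learning_rate,
                      momentum=config.momentum)
    history = TrainHistory()
    best_state = model.copy_state()
    best_loss = math.inf
    plateau_wait = 0
    stop_wait = 0
    for epoch in range(config.max_epochs):
        losses = []
        for xb, yb in make_epoch_stream(train_samples, rng,
                                        config.batch_size, config):
            z = model.forward_logits(xb, train=True)
            loss, dz = bce_with_logits(z, yb)
            model.backward(dz)
            opt.step()
            losses.append(loss + model.l2_penalty())
        val_loss, val_acc, val_auc = _evaluate_stream(
            model, val_samples, rng, config
        )
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.val_auc.append(val_auc)
        history.learning_rates.append(opt.lr)
        improved = val_loss < best_loss - config.plateau_min_delta
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.copy_state()
            history.best_epoch = epoch
        if improved:
            plateau_wait = 0
            stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                plateau_wait = 0
                logger.info("epoch %d: lr reduced to %g", epoch, opt.lr)
            if stop_wait >= config.early_stop_patience:
                logger.info("epoch %d: early stopping", epoch)
                break
    history.stopped_epoch = len(history.val_loss) - 1
    model.load_state_arrays(best_state)
    return model, history


@dataclass
class ConditionResult:
    """Per-condition summary over Monte-Carlo splits."""

    condition: QualityCondition
    n_excluded: int
    n_images: int
    val_accuracies: list[float]
    val_aucs: list[float]
    histories: list[TrainHistory]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.val_accuracies))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.val_aucs))


def _filter_by_condition(samples: list[Sample],
                         condition: QualityCondition) -> tuple[list[Sample], int]:
    report = apply_quality_condition(
        [s.pixels for s in samples], condition,
        image_ids=[s.image_id for s in samples],
    )
    excluded = report.excluded_ids
    kept = [s for s in samples if s.image_id not in excluded]
    return kept, len(excluded)


def run_condition_experiment(
    train_samples: list[Sample],
    conditions: Sequence[QualityCondition],
    n_splits: int,
    seed: int,
    train_config: TrainConfig,
    fcn_config: FCNConfig = FCNConfig(),
    n_val_negative: int = 1,
    n_val_positive: int = 4,
    filter_validation: bool = False,
) -> list[ConditionResult]:
    """Train ``n_splits`` models per quality condition and summarize.

    By default only the *training side* of each split is filtered by the
    exclusion rule — the validation fold is never touched — so every
    condition is validated on identical unfiltered folds (splits are
    shared across conditions, making the comparison paired). With
    ``filter_validation=True`` the rule is instead applied to the whole
    pool before splits are drawn, so validation folds are cleaned per
    condition and each condition draws splits from its own filtered pool.
    The pool-level exclusion count is reported either way. A condition
    that eliminates all training data of one class raises, naming the
    condition.
    """
    def pool_manifest(samples):
        rows = [{"image_path": s.image_id, "case_id": s.case_id,
                 "diagnosis": "glioma" if s.label else "epilepsy",
                 "split_role": "train"} for s in samples]
        return CaseManifest(pd.DataFrame(rows))

    shared_splits = None
    if not filter_validation:
        shared_splits = make_mc_splits(pool_manifest(train_samples),
                                       n_splits, seed,
                                       n_val_negative=n_val_negative,
                                       n_val_positive=n_val_positive)
    results = []
    for cond in conditions:
        kept, n_excluded = _filter_by_condition(train_samples, cond)
        kept_ids = {s.image_id for s in kept}
        if filter_validation:
            if {s.label for s in kept} != {0, 1}:
                raise ValueError(
                    f"quality condition {cond} leaves no usable data "
                    f"({len(kept)} of {len(train_samples)} images kept)"
                )
            splits = make_mc_splits(pool_manifest(kept), n_splits, seed,
                                    n_val_negative=n_val_negative,
                                    n_val_positive=n_val_positive)
        else:
            splits = shared_splits
        accs, aucs, hists = [], [], []
        for split in splits:
            tr = [s for s in train_samples
                  if s.case_id in split.train_case_ids
                  and s.image_id in kept_ids]
            if filter_validation:
                va = [s for s in train_samples
                      if s.case_id in split.val_case_ids
                      and s.image_id in kept_ids]
            else:
                va = [s for s in train_samples
                      if s.case_id in split.val_case_ids]
            if {s.label for s in tr} != {0, 1}:
                raise ValueError(
                    f"quality condition {cond} leaves no usable training "
                    f"data in split {split.split_id} "
                    f"({len(tr)} images kept)"
                )
            model = build_fcn(fcn_config, seed=seed * 1000 + split.split_id)
            cfg = replace(train_config, seed=seed * 1000 + split.split_id)
            _, hist = train_model(model, tr, va, cfg)
            accs.append(hist.best_val_accuracy)
            aucs.append(hist.best_val_auc)
            hists.append(hist)
            logger.info("condition %s split %d: acc %.3f auc %.3f",
                        cond, split.split_id, accs[-1], aucs[-1])
        results.append(ConditionResult(
            condition=cond, n_excluded=n_excluded,
            n_images=len(train_samples),
            val_accuracies=accs, val_aucs=aucs, histories=hists,
        ))
    return results


def experiment_summary(results: Sequence[ConditionResult]) -> pd.DataFrame:
    """Tabulate per-condition mean +- std validation metrics."""
    rows = []
    best = max(range(len(results)), key=lambda i: results[i].mean_auc)
    for i, res in enumerate(results):
        rows.append({
            "condition": str(res.condition),
            "n_excluded": res.n_excluded,
            "fraction_excluded": res.n_excluded / res.n_images,
            "val_accuracy_mean": res.mean_accuracy,
            "val_accuracy_std": float(np.std(res.val_accuracies)),
            "val_auc_mean": res.mean_auc,
            "val_auc_std": float(np.std(res.val_aucs)),
            "best": i == best,
        })
    return pd.DataFrame(rows)
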