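"""One-configuration orchestration of the full tissue-to-inference pipeline.

Stages: simulate (phantom dataset) -> preprocess -> qc (condition sweep
report) -> train (Monte-Carlo condition experiment) -> evaluate (held-out
metrics) -> segment (boundary-mosaic overlay). Each stage communicates
with the next only through file artifacts in the output directory, so a
run is resumable per stage; every random stage derives its stream from
the master seed plus a fixed per-stage offset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from thgqc import phantoms, quality, training
from thgqc.evaluation import ScoredSet, evaluate_ensemble
from thgqc.fcn_model import FCNConfig, build_fcn
from thgqc.io_manifest import read_manifest, write_overlay
from thgqc.overlay import (
    binarize_overlay,
    jaccard_per_class,
    sliding_window_scores,
)
from thgqc.preprocess import PreprocessConfig, preprocess_image
from thgqc.quality import QualityCondition

logger = logging.getLogger(__name__)

#: fixed per-stage seed offsets (master seed + offset -> stage stream)
STAGE_SEEDS = {"simulate": 11, "train": 23, "segment": 37}


@dataclass
class ExperimentConfig:
    """Everything one pipeline run needs, serializable to/from YAML."""

    out_dir: str = "thgqc-run"
    manifest: Optional[str] = None  # None -> simulate phantoms
    seed: int = 0
    phantom: phantoms.PhantomParams = field(
        default_factory=phantoms.PhantomParams)
    dataset: phantoms.DatasetSpec = field(default_factory=phantoms.DatasetSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    conditions: list[tuple[Optional[float], Optional[float]]] = field(
        default_factory=lambda: list(quality.DEFAULT_CONDITIONS))
    fcn: FCNConfig = field(default_factory=FCNConfig)
    train: training.TrainConfig = field(default_factory=training.TrainConfig)
    n_splits: int = 10
    n_val_negative: int = 1
    n_val_positive: int = 4
    overlay_window: int = 256
    overlay_stride: int = 8

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        for key, sub in (("phantom", phantoms.PhantomParams),
                         ("dataset", phantoms.DatasetSpec),
                         ("preprocess", PreprocessConfig),
                         ("fcn", FCNConfig),
                         ("train", training.TrainConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = _build_dataclass(sub, kwargs[key])
        if "conditions" in kwargs:
            kwargs["conditions"] = [tuple(c) for c in kwargs["conditions"]]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build_dataclass(cls, raw: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    clean = {}
    for k, v in raw.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        clean[k] = tuple(v) if isinstance(v, list) else v
    return cls(**clean)


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML/JSON dumping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: ExperimentConfig) -> Path:
    """Execute every stage; returns the artifact directory.

    Artifacts: ``manifest.csv`` + TIFFs (simulate), ``qc_sweep.csv``,
    ``condition_results.csv``, ``metrics.json``, overlay TIFFs and
    ``overlay_iou.json``, plus ``run_manifest.json`` listing all outputs
    with the configuration hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("pipeline start; config hash %s", config.config_hash())
    artifacts: dict[str, str] = {}

    # -- stage: simulate / load ------------------------------------------
    if config.manifest is None:
        seed = config.seed + STAGE_SEEDS["simulate"]
        logger.info("simulate: seed %d", seed)
        spec = dataclasses.replace(config.dataset, seed=seed)
        manifest = phantoms.generate_dataset(spec, config.phantom,
                                             out / "data", overwrite=True)
        artifacts["manifest"] = str(out / "data" / "manifest.csv")
    else:
        manifest = read_manifest(config.manifest)
        artifacts["manifest"] = str(config.manifest)

    # -- stage: preprocess ------------------------------------------------
    records = [preprocess_image(r, config.preprocess)
               for r in manifest.load_images(role="train")]
    samples = training.samples_from_records(records)

    # -- stage: qc sweep ---------------------------------------------------
    conditions = [QualityCondition(*c) for c in config.conditions]
    reports = quality.condition_sweep([s.pixels for s in samples], conditions,
                                      image_ids=[s.image_id for s in samples])
    sweep = quality.sweep_summary(reports)
    sweep.to_csv(out / "qc_sweep.csv", index=False)
    artifacts["qc_sweep"] = str(out / "qc_sweep.csv")
    logger.info("qc sweep:\n%s", sweep)

    # -- stage: train ------------------------------------------------------
    seed = config.seed + STAGE_SEEDS["train"]
    logger.info("train: seed %d", seed)
    results = training.run_condition_experiment(
        samples, conditions, config.n_splits, seed, config.train,
        fcn_config=config.fcn, n_val_negative=config.n_val_negative,
        n_val_positive=config.n_val_positive,
    )
    table = training.experiment_summary(results)
    table.to_csv(out / "condition_results.csv", index=False)
    artifacts["condition_results"] = str(out / "condition_results.csv")
    logger.info("condition results:\n%s", table)

    # -- stage: evaluate ---------------------------------------------------
    best = results[int(table["val_auc_mean"].idxmax())]
    test_rows = manifest.rows_for_role("test")
    if len(test_rows):
        test_records = [preprocess_image(manifest.load_image(row),
                                         config.preprocess)
                        for _, row in test_rows.iterrows()]
        test_samples = training.samples_from_records(test_records)
        scored_sets = []
        for k in range(len(best.histories)):
            model = _retrain_best(best, k, samples, seed, config)
            scores = model.predict_scores([s.pixels for s in test_samples])
            scored_sets.append(ScoredSet(
                scores=scores,
                labels=np.array([s.label for s in test_samples]),
            ))
        metrics = evaluate_ensemble(scored_sets)
        metrics.pop("roc_bundle", None)
        metrics.pop("pr_bundle", None)
        with open(out / "metrics.json", "w") as fh:
            json.dump(_plain(metrics), fh, indent=2)
        artifacts["metrics"] = str(out / "metrics.json")

    # -- stage: segment ----------------------------------------------------
    seg_seed = config.seed + STAGE_SEEDS["segment"]
    rng = np.random.default_rng(seg_seed)
    mosaic_params = dataclasses.replace(
        config.phantom,
        height=max(config.phantom.height, 2 * config.overlay_window),
        width=max(config.phantom.width, 4 * config.overlay_window),
    )
    mosaic = phantoms.render_boundary_mosaic(mosaic_params, rng)
    model = _retrain_best(best, 0, samples, seed, config)
    smap = sliding_window_scores(mosaic, model, config.overlay_window,
                                 config.overlay_stride)
    pred = binarize_overlay(smap, 0.5)
    write_overlay(out / "overlay_scores.tif",
                  np.nan_to_num(smap.mean_score, nan=0.0), pred)
    iou = jaccard_per_class(pred, mosaic.reference_mask)
    with open(out / "overlay_iou.json", "w") as fh:
        json.dump({"iou_normal": iou.iou_normal,
                   "iou_tumor": iou.iou_tumor}, fh, indent=2)
    artifacts["overlay"] = str(out / "overlay_scores.tif")
    artifacts["overlay_iou"] = str(out / "overlay_iou.json")

    with open(out / "run_manifest.json", "w") as fh:
        json.dump({"config_hash": config.config_hash(),
                   "artifacts": artifacts}, fh, indent=2)
    config.to_yaml(out / "config.yaml")
    logger.info("pipeline done: %s", out)
    return out


def _retrain_best(result: training.ConditionResult, split_idx: int,
                  samples: list[training.Sample], seed: int,
                  config: ExperimentConfig):
    """Reproduce the trained model of one split of one condition.

    Deterministic retraining from the recorded seeds stands in for
    checkpoint files so pipeline stages stay file-light; the split seed
    arithmetic matches run_condition_experiment.
    """
    kept, _ = training._filter_by_condition(samples, result.condition)
    kept_ids = {s.image_id for s in kept}
    rows = [{"image_path": s.image_id, "case_id": s.case_id,
             "diagnosis": "glioma" if s.label else "epilepsy",
             "split_role": "train"} for s in samples]
    from thgqc.io_manifest import CaseManifest
    manifest = CaseManifest(pd.DataFrame(rows))
    splits = training.make_mc_splits(
        manifest, split_idx + 1, seed,
        n_val_negative=config.n_val_negative,
        n_val_positive=config.n_val_positive)
    split = splits[split_idx]
    tr = [s for s in samples if s.case_id in split.train_case_ids
          and s.image_id in kept_ids]
    va = [s for s in samples if s.case_id in split.val_case_ids]
    model = build_fcn(config.fcn, seed=seed * 1000 + split.split_id)
    cfg = dataclasses.replace(config.train,
                              seed=seed * 1000 + split.split_id)
    model, _ = training.train_model(model, tr, va, cfg)
    return model


def _setup_logging(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("thgqc")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
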