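"""End-to-end orchestration: simulate/ingest -> preprocess -> extract ->
select -> classify, with machine-readable outputs.

Stage order mirrors the framework the package implements: region boxes
(synthetic or supplied) are cropped and standardized, raster-scanned into
1-D signals, expanded into the 39-feature entropy table, reduced by a
metaheuristic wrapper selector and finally classified with kNN (or SVM)
under stratified 10-fold cross-validation.  Every JSON output echoes its
config and seed; re-running with identical config reproduces all numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as clf
from .entropy.registry import (
    SamplePair,
    build_feature_table,
    read_feature_table,
    write_feature_table,
)
from .errors import EntroselError, InvalidArgumentError
from .optimize import FitnessContext, OptimizerConfig, binarize_mask, run_optimizer
from .preprocess import (
    DEFAULT_ROI_SIZE,
    DEFAULT_SIGMA,
    RegionClass,
    crop_roi,
    flatten_to_signal,
    standardize_roi,
)
from .synthetic import SynthConfig, generate_dataset

log = logging.getLogger("entrosel")


@dataclass
class PipelineConfig:
    mode: str = "quick"  # "quick" | "paper"
    seed: int = 0
    out_dir: str = "entrosel_run"
    roi_size: int = DEFAULT_ROI_SIZE
    sigma: float = DEFAULT_SIGMA
    run_selection: bool = True
    algorithm: str = "sfoa"
    alpha: float = 0.99
    population_size: int = 50
    max_iterations: int = 100
    classifier: str = "knn"
    folds: int = 10
    synth: SynthConfig | None = None
    eval_scope: str | None = None  # "test" (paper default) or "all" (quick default)

    def __post_init__(self) -> None:
        if self.mode not in ("quick", "paper"):
            raise InvalidArgumentError("mode must be 'quick' or 'paper'")
        if self.synth is None:
            self.synth = SynthConfig(seed=self.seed)
        elif isinstance(self.synth, dict):  # YAML configs arrive as plain dicts
            self.synth = SynthConfig(**self.synth)
        if self.eval_scope is None:
            self.eval_scope = "test" if self.mode == "paper" else "all"


def collect_roi_pairs(images, boxes, manifest, subset: str | None = None,
                      roi_size: int = DEFAULT_ROI_SIZE, sigma: float = DEFAULT_SIGMA):
    """Crop, standardize and flatten ROIs into sample pairs.

    Within an image the tumor ROI and the non-tumor ROI reference each other
    (the complementary-region pairing); an image with a single ROI falls back
    to self-reference.
    """
    ids = manifest.splits[subset] if subset else [i for s in manifest.splits.values() for i in s]
    pairs: list[SamplePair] = []
    for sid in ids:
        if sid not in images:
            continue
        img = images[sid]
        signals = {}
        for box in boxes[sid]:
            patch = crop_roi(img, box)
            patch = standardize_roi(patch, roi_size=roi_size, sigma=sigma)
            signals[box.region_class] = flatten_to_signal(patch)
        for cls, sig in signals.items():
            other = RegionClass.NON_TUMOR if cls is RegionClass.TUMOR else RegionClass.TUMOR
            ref = signals.get(other, sig)
            pairs.append(SamplePair(sig, ref, cls, source_image_id=sid))
    return pairs


def _labels(df) -> np.ndarray:
    return (df["class"] == RegionClass.TUMOR.value).astype(int).to_numpy()


def _feature_matrix(df) -> np.ndarray:
    from .entropy.registry import FEATURE_IDS

    return df[list(FEATURE_IDS)].to_numpy(dtype=float)


def select_features(df, config: PipelineConfig, algorithm: str | None = None):
    """Run the wrapper selector on a feature table; returns (trace, ctx)."""
    ctx = FitnessContext(_feature_matrix(df), _labels(df), alpha=config.alpha,
                         seed=config.seed)
    opt = OptimizerConfig(algorithm=algorithm or config.algorithm,
                          population_size=config.population_size,
                          max_iterations=config.max_iterations,
                          alpha=config.alpha, seed=config.seed)
    return run_optimizer(ctx, opt), ctx


def _report_dict(report: clf.EvaluationReport) -> dict:
    cm = report.confusion
    return {
        "confusion_matrix": {"TP": cm.tp, "TN": cm.tn, "FP": cm.fp, "FN": cm.fn},
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "per_class_recall": report.per_class_recall,
        "auc": report.auc,
        "roc_points": report.roc_points,
        "fold_accuracies": report.fold_accuracies,
        "seed": report.seed,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; writes features.csv, selection.json, report.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings = {}
    try:
        t0 = time.perf_counter()
        paper = config.mode == "paper"
        subset = config.eval_scope if config.eval_scope == "test" else None
        images, boxes, manifest = generate_dataset(config.synth, paper_mode=paper,
                                                   subset=subset)
        timings["simulate"] = time.perf_counter() - t0
        log.info("simulate: %d images (mode=%s seed=%d)", len(images), config.mode, config.seed)

        t0 = time.perf_counter()
        pairs = collect_roi_pairs(images, boxes, manifest, subset=subset,
                                  roi_size=config.roi_size, sigma=config.sigma)
        timings["preprocess"] = time.perf_counter() - t0
        log.info("preprocess: %d ROI pairs", len(pairs))

        t0 = time.perf_counter()
        df = build_feature_table(pairs)
        write_feature_table(df, out / "features.csv")
        timings["extract"] = time.perf_counter() - t0
        log.info("extract: table %s", df.shape)

        if config.run_selection:
            t0 = time.perf_counter()
            trace, _ = select_features(df, config)
            mask = trace.best_mask
            selection = {
                "algorithm": trace.algorithm,
                "config": {"population_size": config.population_size,
                           "max_iterations": config.max_iterations,
                           "alpha": config.alpha, "threshold": 0.8,
                           "seed": config.seed},
                "selected_features": mask.selected_ids,
                "n_selected": mask.selected_count,
                "best_fitness": trace.best_fitness,
                "convergence": trace.best_fitness_per_iteration,
                "evaluations_used": trace.evaluations_used,
            }
            (out / "selection.json").write_text(json.dumps(selection, indent=2))
            timings["select"] = time.perf_counter() - t0
            cols = np.flatnonzero(mask.bits)
        else:
            mask = binarize_mask(np.ones(39) * 0.9, 0.8)  # all 39 features
            cols = np.flatnonzero(mask.bits)
            selection = {"algorithm": None, "selected_features": mask.selected_ids,
                         "n_selected": mask.selected_count}

        t0 = time.perf_counter()
        spec = clf.ClassifierSpec(kind=config.classifier)
        report = clf.cross_validate(_feature_matrix(df)[:, cols], _labels(df),
                                    spec, folds=config.folds, seed=config.seed)
        timings["classify"] = time.perf_counter() - t0

        result = {
            "config": {k: v for k, v in dataclasses.asdict(config).items() if k != "synth"},
            "n_samples": int(len(df)),
            "n_selected": int(mask.selected_count),
            "selected_features": mask.selected_ids,
            "evaluation": _report_dict(report),
            "timings_s": timings,
            "seed": config.seed,
        }
        (out / "report.json").write_text(json.dumps(result, indent=2))
        log.info("classify: accuracy=%.4f auc=%.4f", report.accuracy, report.auc)
        return result
    except EntroselError as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def compare_optimizers(df, config: PipelineConfig,
                       algorithms: tuple[str, ...] = ("sfoa", "pso", "hho", "po")) -> list[dict]:
    """Run each wrapper selector on the same table + seed; one row per algorithm."""
    if len(algorithms) < 2:
        raise InvalidArgumentError("need at least two algorithms to compare")
    rows = []
    for algo in algorithms:
        trace, _ = select_features(df, config, algorithm=algo)
        mask = trace.best_mask
        spec = clf.ClassifierSpec(kind=config.classifier)
        report = clf.cross_validate(_feature_matrix(df)[:, np.flatnonzero(mask.bits)],
                                    _labels(df), spec, folds=config.folds, seed=config.seed)
        rows.append({
            "algorithm": algo,
            "n_selected": mask.selected_count,
            "selected_features": mask.selected_ids,
            "best_fitness": trace.best_fitness,
            "accuracy": report.accuracy,
            "convergence": trace.best_fitness_per_iteration,
        })
    return rows


def load_feature_table(path) -> "tuple[np.ndarray, np.ndarray]":
    """Read a features.csv into (X, y) with tumor = 1."""
    df = read_feature_table(path)
    return _feature_matrix(df), _labels(df)
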