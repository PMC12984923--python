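"""Shared wrapper-selection machinery for all optimizers.

The search space is [0,1]^39; a continuous position is thresholded (cut-off
0.8) into a binary selection mask, the masked feature table is scored with a
kNN on a held-out validation split (or quick k-fold), and the scalar
objective trades accuracy against subset size:

    fitness = alpha * (1 - accuracy) + (1 - alpha) * Ns / Nt     (lower is better)

alpha defaults to 0.99, the standard wrapper-selection weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..classify import ClassifierSpec, cross_validate, knn_predict, standardize
from ..errors import InvalidArgumentError, InvalidInputError


@dataclass
class OptimizerConfig:
    algorithm: str = "sfoa"  # sfoa | pso | hho | po
    population_size: int = 50
    max_iterations: int = 100
    dimension: int = 39
    threshold: float = 0.8
    breeding_c: float = 0.8
    alpha: float = 0.99
    levy_beta: float = 1.5
    stage_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    rand_mode: str = "scalar"  # growth-stage rand: one scalar draw or per-coordinate
    seed: int = 0
    # PSO
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    cognitive: float = 2.0
    social: float = 2.0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise InvalidArgumentError("population_size must be >= 2")
        if not 0 < self.threshold < 1:
            raise InvalidArgumentError("threshold must lie in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise InvalidArgumentError("alpha must lie in (0, 1]")
        if self.algorithm not in ("sfoa", "pso", "hho", "po"):
            raise InvalidArgumentError(f"unknown algorithm {self.algorithm!r}")

    @property
    def max_fes(self) -> int:
        return self.population_size * self.max_iterations


@dataclass
class SelectionMask:
    bits: np.ndarray
    fallback_used: bool = False

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def selected_ids(self) -> list[str]:
        return [f"F{i + 1}" for i in np.flatnonzero(self.bits)]


@dataclass
class OptimizationTrace:
    algorithm: str
    best_fitness_per_iteration: list[float]
    evaluations_used: int
    max_fes: int
    best_position: np.ndarray
    best_mask: SelectionMask
    best_fitness: float


@dataclass
class FitnessContext:
    """Feature table + labels + validation scheme used inside the wrapper."""

    features: np.ndarray
    labels: np.ndarray
    alpha: float = 0.99
    n_neighbors: int = 1
    validation: str = "holdout"  # "holdout" or "kfold"
    holdout_fraction: float = 0.3
    n_folds: int = 5
    seed: int = 0
    _train_idx: np.ndarray = field(init=False, repr=False, default=None)
    _val_idx: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.size:
            raise InvalidInputError("features and labels are inconsistent")
        if np.unique(self.labels).size != 2:
            raise InvalidInputError("labels must be binary")
        if self.validation == "holdout":
            self._train_idx, self._val_idx = self._stratified_holdout()

    def _stratified_holdout(self) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        train, val = [], []
        for cls in np.unique(self.labels):
            idx = np.flatnonzero(self.labels == cls)
            idx = rng.permutation(idx)
            n_val = max(1, int(round(self.holdout_fraction * idx.size)))
            val.extend(idx[:n_val])
            train.extend(idx[n_val:])
        return np.sort(np.asarray(train)), np.sort(np.asarray(val))

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def binarize_mask(position: np.ndarray, threshold: float = 0.8) -> SelectionMask:
    """bit_j = 1 iff coordinate_j > threshold; argmax fallback keeps Ns >= 1.

    Ties in the fallback resolve to the lowest index (numpy argmax).
    """
    if not 0 < threshold < 1:
        raise InvalidArgumentError("threshold must lie in (0, 1)")
    position = np.asarray(position, dtype=float)
    bits = (position > threshold).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(position))] = 1
        return SelectionMask(bits, fallback_used=True)
    return SelectionMask(bits)


def fitness(accuracy: float, ns: int, nt: int, alpha: float = 0.99) -> float:
    """alpha*(1-accuracy) + (1-alpha)*Ns/Nt; lower is better, range [0, 1]."""
    if ns > nt:
        raise InvalidArgumentError("Ns cannot exceed Nt")
    if not 0 <= accuracy <= 1:
        raise InvalidArgumentError("accuracy must lie in [0, 1]")
    return alpha * (1.0 - accuracy) + (1.0 - alpha) * (ns / nt)


def evaluate_mask(mask: SelectionMask, ctx: FitnessContext) -> float:
    """Score a selection mask: restrict columns, classify, plug into fitness."""
    cols = np.flatnonzero(mask.bits)
    if cols.size == 0:
        raise InvalidInputError("mask selects no features")
    sub = ctx.features[:, cols]
    if ctx.validation == "holdout":
        tr, va = ctx._train_idx, ctx._val_idx
        tr_x, va_x, _ = standardize(sub[tr], sub[va])
        pred, _ = knn_predict(tr_x, ctx.labels[tr], va_x, ctx.n_neighbors)
        accuracy = float((pred == ctx.labels[va]).mean())
    else:
        report = cross_validate(sub, ctx.labels, ClassifierSpec(n_neighbors=ctx.n_neighbors),
                                folds=ctx.n_folds, seed=ctx.seed)
        accuracy = report.accuracy
    return fitness(accuracy, mask.selected_count, ctx.n_features, ctx.alpha)


def evaluate_position(position: np.ndarray, ctx: FitnessContext, threshold: float) -> float:
    return evaluate_mask(binarize_mask(position, threshold), ctx)


def initialize_population(config: OptimizerConfig, rng: np.random.Generator) -> np.ndarray:
    """N positions uniform on [0,1]^D."""
    return rng.uniform(0.0, 1.0, size=(config.population_size, config.dimension))


def run_optimizer(ctx: FitnessContext, config: OptimizerConfig) -> OptimizationTrace:
    """Run the configured algorithm and return its trace.

    All algorithms share initialization, binarization, the fitness path and
    the MaxFES = N x max_iterations budget (initialization evaluations are
    counted on top); they differ only in the position-update rule.
    """
    from . import baselines, sfoa

    runners = {
        "sfoa": sfoa.run_sfoa,
        "pso": baselines.run_pso,
        "hho": baselines.run_hho,
        "po": baselines.run_po,
    }
    return runners[config.algorithm](ctx, config)
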