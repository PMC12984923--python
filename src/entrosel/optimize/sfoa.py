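"""Superb fairy-wren optimization algorithm (SFOA).

A population metaheuristic with three behavioral stages applied per
individual per iteration:

* growth (juvenile learning) — a wide jump along the direction the
  individual moved last iteration: X_new = X_t + rand * (X_t - X_{t-1});
* breeding/feeding (cooperative care) — contraction toward the population
  best, intensifying with the maturity factor p = FEs/MaxFES:
  X_new = X_b + C * p * (X_t - X_b) with the constant coefficient C = 0.8;
* enemy avoidance — a Levy-flight escape toward/past the best scaled by the
  adaptive flight coefficient k = 0.2 * sin(pi/2 - omega),
  omega = (pi/2) * FEs/MaxFES: X_new = X_t + l * k * (X_b - X_t).

Updates are clipped to [0,1]^D and accepted greedily (only on fitness
improvement), so the best-fitness trace is non-increasing.
"""

from __future__ import annotations

import math

import numpy as np

from ..errors import InvalidArgumentError
from .core import (
    FitnessContext,
    OptimizationTrace,
    OptimizerConfig,
    binarize_mask,
    evaluate_position,
    initialize_population,
)


def maturity(fes: int, max_fes: int) -> float:
    """Maturity factor p = FEs / MaxFES in [0, 1]."""
    if max_fes <= 0:
        raise InvalidArgumentError("max_fes must be > 0")
    if not 0 <= fes <= max_fes:
        raise InvalidArgumentError("need 0 <= fes <= max_fes")
    return fes / max_fes


def flight_coefficient(fes: int, max_fes: int) -> float:
    """Adaptive flight coefficient k = 0.2 * sin(pi/2 - omega), omega = (pi/2)*p.

    Decays monotonically from 0.2 at the start of the run to 0 at budget
    exhaustion.
    """
    omega = (math.pi / 2.0) * maturity(fes, max_fes)
    return 0.2 * math.sin(math.pi / 2.0 - omega)


def levy_step(rng: np.random.Generator, beta: float = 1.5) -> float:
    """Mantegna-algorithm Levy draw u / |v|^(1/beta), heavy-tailed."""
    if not 0 < beta <= 2:
        raise InvalidArgumentError("beta must lie in (0, 2]")
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1 + beta) / 2.0) * beta * 2 ** ((beta - 1) / 2.0)
    sigma_u = (num / den) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u)
    v = rng.normal(0.0, 1.0)
    return u / abs(v) ** (1.0 / beta)


def growth_update(current: np.ndarray, previous: np.ndarray, rng: np.random.Generator,
                  rand_mode: str = "scalar") -> np.ndarray:
    """X_new = X_t + rand * (X_t - X_{t-1}), clipped to [0, 1].

    ``rand`` is a single U(0,1) scalar applied to every coordinate
    (vector-scaling reading) unless ``rand_mode == 'vector'``.
    """
    if rand_mode == "scalar":
        rand = rng.random()
    else:
        rand = rng.random(current.shape)
    return np.clip(current + rand * (current - previous), 0.0, 1.0)


def breeding_update(current: np.ndarray, best: np.ndarray, p: float, c: float = 0.8) -> np.ndarray:
    """X_new = X_b + C * p * (X_t - X_b), clipped to [0, 1]."""
    if not 0 <= p <= 1:
        raise InvalidArgumentError("p must lie in [0, 1]")
    return np.clip(np.asarray(best, dtype=float) + c * p * (np.asarray(current, dtype=float) - best),
                   0.0, 1.0)


def enemies_update(current: np.ndarray, best: np.ndarray, fes: int, max_fes: int,
                   rng: np.random.Generator, beta: float = 1.5) -> np.ndarray:
    """X_new = X_t + l * k * (X_b - X_t) with a Levy step l, clipped to [0, 1]."""
    step = levy_step(rng, beta)
    k = flight_coefficient(fes, max_fes)
    return np.clip(current + step * k * (best - current), 0.0, 1.0)


def run_sfoa(ctx: FitnessContext, config: OptimizerConfig) -> OptimizationTrace:
    rng = np.random.default_rng(config.seed)
    n, max_fes = config.population_size, config.max_fes
    pos = initialize_population(config, rng)
    prev = pos.copy()  # previous-iteration position; growth is a no-op at t=0
    fit = np.array([evaluate_position(pos[i], ctx, config.threshold) for i in range(n)])
    fes = 0  # MaxFES covers the iterative budget; init evals counted on top
    best_idx = int(np.argmin(fit))
    best_pos = pos[best_idx].copy()
    best_fit = float(fit[best_idx])
    history: list[float] = []
    p_grow, p_breed, _ = config.stage_probabilities
    total_evals = n

    for _ in range(config.max_iterations):
        if fes >= max_fes:
            break
        iter_start = pos.copy()
        for i in range(n):
            if fes >= max_fes:
                break
            u = rng.random()
            if u < p_grow:
                cand = growth_update(pos[i], prev[i], rng, config.rand_mode)
            elif u < p_grow + p_breed:
                cand = breeding_update(pos[i], best_pos, maturity(fes, max_fes),
                                       config.breeding_c)
            else:
                cand = enemies_update(pos[i], best_pos, fes, max_fes, rng, config.levy_beta)
            f_new = evaluate_position(cand, ctx, config.threshold)
            fes += 1
            total_evals += 1
            if f_new < fit[i]:  # greedy acceptance
                pos[i] = cand
                fit[i] = f_new
                if f_new < best_fit:
                    best_fit = f_new
                    best_pos = cand.copy()
        prev = iter_start
        history.append(best_fit)

    return OptimizationTrace(
        algorithm="sfoa",
        best_fitness_per_iteration=history,
        evaluations_used=total_evals,
        max_fes=max_fes,
        best_position=best_pos,
        best_mask=binarize_mask(best_pos, config.threshold),
        best_fitness=best_fit,
    )
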