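"""Baseline wrapper selectors: PSO, HHO and a compact PO variant.

All three share the common initialization, [0,1]^D clipping, 0.8-threshold
binarization and kNN-based fitness of :mod:`.core`; only the position-update
rules differ.  Parameters follow the published defaults: PSO inertia decays
linearly 0.9 -> 0.4 with c1 = c2 = 2.0; HHO's escape energy decays linearly
over the run; PO alternates exploration and exploitation phases scored by
their recent improvement (a compact re-implementation of the puma optimizer's
phase logic, documented in the methods note).
"""

from __future__ import annotations

import numpy as np

from .core import (
    FitnessContext,
    OptimizationTrace,
    OptimizerConfig,
    binarize_mask,
    evaluate_position,
    initialize_population,
)
from .sfoa import levy_step


def _trace(name, history, evals, config, best_pos, best_fit) -> OptimizationTrace:
    return OptimizationTrace(
        algorithm=name,
        best_fitness_per_iteration=history,
        evaluations_used=evals,
        max_fes=config.max_fes,
        best_position=best_pos,
        best_mask=binarize_mask(best_pos, config.threshold),
        best_fitness=best_fit,
    )


def run_pso(ctx: FitnessContext, config: OptimizerConfig) -> OptimizationTrace:
    """Canonical global-best PSO with linearly decreasing inertia."""
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, config.dimension
    pos = initialize_population(config, rng)
    vel = np.zeros((n, d))
    fit = np.array([evaluate_position(pos[i], ctx, config.threshold) for i in range(n)])
    evals = n
    pbest = pos.copy()
    pbest_fit = fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    history = []
    t_max = config.max_iterations

    for t in range(t_max):
        if evals - n >= config.max_fes:
            break
        w = config.inertia_start - (config.inertia_start - config.inertia_end) * (
            t / max(t_max - 1, 1)
        )
        for i in range(n):
            if evals - n >= config.max_fes:
                break
            r1, r2 = rng.random(d), rng.random(d)
            vel[i] = (
                w * vel[i]
                + config.cognitive * r1 * (pbest[i] - pos[i])
                + config.social * r2 * (gbest - pos[i])
            )
            pos[i] = np.clip(pos[i] + vel[i], 0.0, 1.0)
            f = evaluate_position(pos[i], ctx, config.threshold)
            evals += 1
            if f < pbest_fit[i]:
                pbest[i], pbest_fit[i] = pos[i].copy(), f
                if f < gbest_fit:
                    gbest, gbest_fit = pos[i].copy(), float(f)
        history.append(gbest_fit)

    return _trace("pso", history, evals, config, gbest, gbest_fit)


def run_hho(ctx: FitnessContext, config: OptimizerConfig) -> OptimizationTrace:
    """Harris hawks optimization with linearly decaying escape energy.

    Exploration uses random-perch moves; exploitation applies the four
    besiege strategies (soft/hard, with and without progressive Levy dives).
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, config.dimension
    pos = initialize_population(config, rng)
    fit = np.array([evaluate_position(pos[i], ctx, config.threshold) for i in range(n)])
    evals = n
    b = int(np.argmin(fit))
    best, best_fit = pos[b].copy(), float(fit[b])
    history = []

    def levy_vec() -> np.ndarray:
        return np.array([levy_step(rng, config.levy_beta) for _ in range(d)])

    for t in range(config.max_iterations):
        if evals - n >= config.max_fes:
            break
        e1 = 2.0 * (1.0 - t / config.max_iterations)  # linearly decreasing
        mean_pos = pos.mean(axis=0)
        for i in range(n):
            if evals - n >= config.max_fes:
                break
            e0 = 2.0 * rng.random() - 1.0
            energy = e1 * e0
            jump = 2.0 * (1.0 - rng.random())
            if abs(energy) >= 1.0:  # exploration
                if rng.random() >= 0.5:
                    k = rng.integers(n)
                    cand = pos[k] - rng.random() * np.abs(pos[k] - 2 * rng.random() * pos[i])
                else:
                    cand = (best - mean_pos) - rng.random() * rng.random(d)
            else:  # exploitation
                r = rng.random()
                if r >= 0.5 and abs(energy) >= 0.5:  # soft besiege
                    cand = (best - pos[i]) - energy * np.abs(jump * best - pos[i])
                elif r >= 0.5:  # hard besiege
                    cand = best - energy * np.abs(best - pos[i])
                else:  # progressive rapid dives
                    ref = pos[i] if abs(energy) >= 0.5 else mean_pos
                    y = np.clip(best - energy * np.abs(jump * best - ref), 0.0, 1.0)
                    f_y = evaluate_position(y, ctx, config.threshold)
                    evals += 1
                    if f_y < fit[i]:
                        cand = y
                    else:
                        cand = y + rng.random(d) * levy_vec()
            cand = np.clip(cand, 0.0, 1.0)
            f = evaluate_position(cand, ctx, config.threshold)
            evals += 1
            if f < fit[i]:
                pos[i], fit[i] = cand, f
                if f < best_fit:
                    best, best_fit = cand.copy(), float(f)
        history.append(best_fit)

    return _trace("hho", history, evals, config, best, best_fit)


def run_po(ctx: FitnessContext, config: OptimizerConfig) -> OptimizationTrace:
    """Compact puma-optimizer variant (version: entrosel-compact-1).

    Keeps the published algorithm's two-phase structure — exploration
    (random leaps and differential moves among pack members) and
    exploitation (ambush toward the best individual and short sprints) —
    with the phase chosen adaptively by the improvement each phase produced
    recently.  Greedy acceptance preserves the shared trace contracts.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, config.dimension
    pos = initialize_population(config, rng)
    fit = np.array([evaluate_position(pos[i], ctx, config.threshold) for i in range(n)])
    evals = n
    b = int(np.argmin(fit))
    best, best_fit = pos[b].copy(), float(fit[b])
    history = []
    score = {"explore": 1.0, "exploit": 1.0}  # adaptive phase scores

    def explore_move(i: int) -> np.ndarray:
        if rng.random() < 0.5:
            return rng.random(d)  # full random leap
        a, b_, c = rng.choice(n, size=3, replace=False)
        g = 2.0 * rng.random() - 1.0
        return pos[a] + g * (pos[b_] - pos[c])

    def exploit_move(i: int) -> np.ndarray:
        if rng.random() < 0.5:  # ambush: run at the best with a Levy-scaled jump
            step = levy_step(rng, config.levy_beta)
            return best + 0.5 * step * (best - pos[i])
        # sprint: biased midpoint with multiplicative noise
        w = rng.random(d)
        return np.clip(w * best + (1 - w) * pos[i] + 0.1 * rng.standard_normal(d), 0.0, 1.0)

    for t in range(config.max_iterations):
        if evals - n >= config.max_fes:
            break
        if t < 3:  # unexperienced phase: alternate both
            phase = "explore" if t % 2 == 0 else "exploit"
        else:
            total = score["explore"] + score["exploit"]
            phase = "explore" if rng.random() < score["explore"] / total else "exploit"
        improved = 0.0
        for i in range(n):
            if evals - n >= config.max_fes:
                break
            cand = explore_move(i) if phase == "explore" else exploit_move(i)
            cand = np.clip(cand, 0.0, 1.0)
            f = evaluate_position(cand, ctx, config.threshold)
            evals += 1
            if f < fit[i]:
                improved += fit[i] - f
                pos[i], fit[i] = cand, f
                if f < best_fit:
                    best, best_fit = cand.copy(), float(f)
        # exponential moving average of per-phase improvement
        score[phase] = 0.7 * score[phase] + 0.3 * (improved + 1e-6)
        history.append(best_fit)

    return _trace("po", history, evals, config, best, best_fit)
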