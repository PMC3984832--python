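"""Artificial fish swarm search over the (T0, gamma) parameter plane.

The SNR threshold T0 and the smoothing half-width gamma are species
dependent; the swarm finds the pair maximising recognition accuracy A_c
on an annotated training set.  Each "fish" holds a position in the
bounded (T0, gamma) box and repeatedly picks one of three behaviours:

* *swarm* — move toward the centroid of companions within the visual
  radius, if the centroid improves on the fish's own fitness and the
  neighbourhood is not crowded;
* *follow* — move toward the best companion within visual range, under
  the same crowding rule;
* *prey* — sample up to ``try_number`` random positions within visual
  range and step toward the first improvement, falling back to a random
  step.

A bulletin board keeps the best position ever evaluated, so the reported
fitness history is monotone non-decreasing.  gamma is searched as a real
coordinate and rounded to the nearest integer whenever the pipeline is
evaluated.  The crowding factor delta is interpreted as a *companion
count*: a neighbourhood with delta or more companions counts as crowded
(a fractional mode, crowded when companions >= delta * school size, is
available for the conventional parameterisation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable

import numpy as np

from .metrics import accuracy
from .pipeline import evaluate_pairs, two_stage_detect
from .refine import RefineParams
from .snn import PrototypeSet
from .spectral import SpectralParams

FitnessFn = Callable[[np.ndarray], float]


@dataclass
class SwarmConfig:
    fish_number: int = 100
    visual: float = 2.85
    delta: float = 9.0
    crowding_mode: str = "count"  # or "fraction"
    step: float = 1.0
    iterations: int = 60
    try_number: int = 5
    seed: int = 0
    t0_bounds: tuple[float, float] = (0.5, 5.0)
    gamma_bounds: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if self.fish_number < 1 or self.try_number < 1 or self.iterations < 0:
            raise ValueError("counts must be >= 1 (iterations >= 0)")
        if self.visual <= 0 or self.step <= 0 or self.delta <= 0:
            raise ValueError("visual, step and delta must be positive")
        if self.crowding_mode not in ("count", "fraction"):
            raise ValueError(f"unknown crowding mode {self.crowding_mode!r}")
        for lo, hi in (self.t0_bounds, self.gamma_bounds):
            if lo >= hi:
                raise ValueError("bounds must satisfy lo < hi")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.t0_bounds[0], self.gamma_bounds[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.t0_bounds[1], self.gamma_bounds[1]])


@dataclass
class Fish:
    position: np.ndarray
    fitness: float


def clamp(position: np.ndarray, config: SwarmConfig) -> np.ndarray:
    return np.clip(position, config.lower, config.upper)


def _move_toward(
    pos: np.ndarray,
    target: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    direction = target - pos
    norm = float(np.linalg.norm(direction))
    if norm == 0.0:
        return pos.copy()
    return clamp(pos + config.step * rng.random() * direction / norm, config)


def prey(
    fish: Fish,
    fitness_fn: FitnessFn,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> Fish:
    """Random local search: step toward the first improving candidate."""
    for _ in range(config.try_number):
        candidate = clamp(
            fish.position + config.visual * rng.uniform(-1.0, 1.0, size=2), config
        )
        if fitness_fn(candidate) > fish.fitness:
            new_pos = _move_toward(fish.position, candidate, config, rng)
            return Fish(new_pos, fitness_fn(new_pos))
    new_pos = clamp(
        fish.position + config.step * rng.uniform(-1.0, 1.0, size=2), config
    )
    return Fish(new_pos, fitness_fn(new_pos))


def _crowded(n_companions: int, school_size: int, config: SwarmConfig) -> bool:
    if config.crowding_mode == "count":
        return n_companions >= config.delta
    return n_companions >= config.delta * school_size


def swarm_and_follow(
    index: int,
    school: list[Fish],
    fitness_fn: FitnessFn,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> Fish:
    """Try swarm, then follow, then fall back to prey."""
    fish = school[index]
    companions = [
        f
        for i, f in enumerate(school)
        if i != index
        and np.linalg.norm(f.position - fish.position) <= config.visual
    ]
    if companions and not _crowded(len(companions), len(school), config):
        centroid = np.mean([f.position for f in companions], axis=0)
        if fitness_fn(centroid) > fish.fitness:
            new_pos = _move_toward(fish.position, centroid, config, rng)
            return Fish(new_pos, fitness_fn(new_pos))
        best = max(companions, key=lambda f: f.fitness)
        if best.fitness > fish.fitness:
            new_pos = _move_toward(fish.position, best.position, config, rng)
            return Fish(new_pos, fitness_fn(new_pos))
    return prey(fish, fitness_fn, config, rng)


def optimize(
    fitness_fn: FitnessFn,
    config: SwarmConfig,
) -> tuple[np.ndarray, float, list[tuple[int, float]]]:
    """Run the swarm; returns (best position, best fitness, history).

    The history carries one ``(iteration, best_fitness)`` entry per
    iteration and is monotone non-decreasing by construction.  The whole
    trajectory is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    school = []
    for _ in range(config.fish_number):
        pos = rng.uniform(config.lower, config.upper)
        school.append(Fish(pos, fitness_fn(pos)))

    best = max(school, key=lambda f: f.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    history: list[tuple[int, float]] = []

    for it in range(1, config.iterations + 1):
        for i in range(len(school)):
            school[i] = swarm_and_follow(i, school, fitness_fn, config, rng)
            if school[i].fitness > best_fit:
                best_fit = school[i].fitness
                best_pos = school[i].position.copy()
        history.append((it, best_fit))
    return best_pos, best_fit, history


def make_pipeline_fitness(
    training_pairs,
    protos: PrototypeSet,
    spectral_params: SpectralParams | None = None,
    refine_params: RefineParams | None = None,
    config: SwarmConfig | None = None,
    mode: str = "feature",
    segment_length: int | None = None,
) -> FitnessFn:
    """Fitness = pooled A_c of the two-stage pipeline at (T0, gamma).

    Positions are clamped into the configured bounds and gamma rounded to
    the nearest integer before evaluation; results are memoised on the
    rounded coordinates since the pipeline is deterministic.
    """
    if not training_pairs:
        raise ValueError("training set is empty")
    cfg = config or SwarmConfig()
    sp = spectral_params or SpectralParams()
    rp = refine_params or RefineParams()

    @lru_cache(maxsize=4096)
    def _evaluate(t0: float, gamma: int) -> float:
        sp_i = replace(sp, t0=t0, gamma=gamma)
        rp_i = replace(rp, t0=t0, gamma=gamma)
        preds = [
            two_stage_detect(seq, protos, sp_i, rp_i, segment_length=segment_length)
            for seq, _ in training_pairs
        ]
        counts = evaluate_pairs(preds, training_pairs, mode=mode)
        return accuracy(counts)

    def fitness(position: np.ndarray) -> float:
        pos = clamp(np.asarray(position, dtype=float), cfg)
        t0 = round(float(pos[0]), 6)
        gamma = int(round(float(pos[1])))
        return _evaluate(t0, gamma)

    return fitness


def write_history_tsv(history, best_pos, path) -> None:
    """Optimisation report: per-iteration best fitness, final position last."""
    with open(path, "w") as fh:
        fh.write("iteration\tbest_fitness\tbest_t0\tbest_gamma\n")
        for i, (it, fit) in enumerate(history):
            is_last = i == len(history) - 1
            t0 = f"{best_pos[0]:.4f}" if is_last else ""
            g = f"{best_pos[1]:.4f}" if is_last else ""
            fh.write(f"{it}\t{fit:.6f}\t{t0}\t{g}\n")
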