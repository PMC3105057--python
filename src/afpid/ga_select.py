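"""Genetic-algorithm selection of feature attributes for one coding scheme.

Fitness of a mask is the internally cross-validated MCC of an RBF-SVM
trained on the masked feature matrix; ties are broken by fewer false
positives, then by fewer selected attributes (the pipeline's stated goal
is to return as few false positives as possible while discarding
attributes that do not help classification).

The all-ones mask is injected into generation 0 and elitism preserves the
best individual, so the final mask can never score below no-selection on
the internal criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import ConfusionCounts, mcc
from .scheme_classifier import ClassifierConfig, TrainingError, cv_confusion, small_grid


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1 / n_attributes
    elitism_count: int = 2
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 1 <= self.elitism_count < self.population_size:
            raise ValueError("need 1 <= elitism_count < population_size")
        for name in ("crossover_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass(frozen=True)
class FitnessRecord:
    mask: tuple[bool, ...]
    mcc: float
    tp: int
    fp: int
    n_selected: int

    @property
    def key(self) -> tuple[float, int, int]:
        """Sort key: higher MCC, then fewer FPs, then fewer attributes."""
        return (self.mcc, -self.fp, -self.n_selected)

    def mask_array(self) -> np.ndarray:
        return np.array(self.mask, dtype=bool)


def evaluate_fitness(
    mask: np.ndarray,
    matrix: np.ndarray,
    y_signs: np.ndarray,
    internal_folds: int = 2,
    grid: Sequence[ClassifierConfig] | None = None,
    seed: int = 0,
) -> FitnessRecord:
    """Internal-CV fitness of one mask (best grid point if several given)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise TrainingError("cannot evaluate an empty feature mask")
    grid = list(grid) if grid is not None else small_grid()
    Xm = np.asarray(matrix, dtype=float)[:, mask]
    best: ConfusionCounts | None = None
    best_mcc = -np.inf
    for config in grid:
        counts = cv_confusion(Xm, y_signs, config, internal_folds, seed)
        m = mcc(counts)
        if m > best_mcc or best is None:
            best, best_mcc = counts, m
    return FitnessRecord(
        mask=tuple(bool(b) for b in mask),
        mcc=best_mcc,
        tp=best.tp,
        fp=best.fp,
        n_selected=int(mask.sum()),
    )


def _tournament(rng: np.random.Generator, population: list[FitnessRecord], size: int) -> FitnessRecord:
    picks = rng.integers(0, len(population), size=size)
    return max((population[i] for i in picks), key=lambda r: r.key)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(0, mask.size)] = True
    return mask


@dataclass
class GAResult:
    best: FitnessRecord
    history: list[dict] = field(default_factory=list)  # per-generation best


def run_ga(
    matrix: np.ndarray,
    y_signs: np.ndarray,
    ga_config: GAConfig | None = None,
    grid: Sequence[ClassifierConfig] | None = None,
    internal_folds: int = 2,
) -> GAResult:
    """Evolve feature masks; returns the best-ever mask plus history.

    Generation 0 is random masks at 50% density with the all-ones mask
    injected; then tournament selection, uniform crossover, per-bit
    mutation, and elitism.  Fully deterministic for a fixed seed.
    """
    cfg = ga_config or GAConfig()
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(y_signs)
    if len(set(y.tolist())) < 2:
        raise TrainingError("both classes must be present")
    n_attr = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    p_mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_attr

    cache: dict[bytes, FitnessRecord] = {}

    def fitness(mask: np.ndarray) -> FitnessRecord:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(mask, X, y, internal_folds, grid, cfg.seed)
        return cache[key]

    masks = [
        _repair(rng.random(n_attr) < 0.5, rng) for _ in range(cfg.population_size - 1)
    ]
    masks.append(np.ones(n_attr, dtype=bool))
    population = [fitness(m) for m in masks]
    best = max(population, key=lambda r: r.key)
    history = [
        {"generation": 0, "mcc": best.mcc, "fp": best.fp, "n_selected": best.n_selected}
    ]

    for gen in range(1, cfg.generations + 1):
        elite = sorted(population, key=lambda r: r.key, reverse=True)[: cfg.elitism_count]
        offspring: list[np.ndarray] = []
        while len(offspring) < cfg.population_size - cfg.elitism_count:
            pa = _tournament(rng, population, cfg.tournament_size).mask_array()
            pb = _tournament(rng, population, cfg.tournament_size).mask_array()
            if rng.random() < cfg.crossover_rate:
                take_a = rng.random(n_attr) < 0.5
                child_a = np.where(take_a, pa, pb)
                child_b = np.where(take_a, pb, pa)
            else:
                child_a, child_b = pa.copy(), pb.copy()
            for child in (child_a, child_b):
                flip = rng.random(n_attr) < p_mut
                child ^= flip
                offspring.append(_repair(child, rng))
        offspring = offspring[: cfg.population_size - cfg.elitism_count]
        population = elite + [fitness(m) for m in offspring]
        gen_best = max(population, key=lambda r: r.key)
        if gen_best.key > best.key:
            best = gen_best
        history.append(
            {"generation": gen, "mcc": best.mcc, "fp": best.fp, "n_selected": best.n_selected}
        )
    return GAResult(best=best, history=history)


def write_history(history: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("#generation\tbest_mcc\tbest_fp\tn_selected\n")
        for row in history:
            fh.write(
                f"{row['generation']}\t{row['mcc']:.6f}\t{row['fp']}\t{row['n_selected']}\n"
            )
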