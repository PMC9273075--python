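"""Genetic algorithm over per-class cost vectors, minimising arrival-time RMSE.

A population of cost vectors is initialised from N(1, 1) (clamped to the cost
floor), scored with the least-cost arrival model, and evolved by truncation
selection, elitism, uniform crossover and single-gene Gaussian mutation:

* population 500, kept constant;
* the 250 fittest individuals become the parent pool;
* the 50 fittest are copied unchanged (elitism);
* children take each gene from either parent with probability 1/2;
* with probability 0.2 a child has one uniformly chosen gene perturbed by a
  standard-normal draw;
* 20 generations.

Elitism makes the best-RMSE trace non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SimulationConfig, score_sampled, speeds_from_costs
from .raster import COST_FLOOR, ClassRaster, accumulate_cost, sample_surface


@dataclass
class GAConfig:
    pop_size: int = 500
    n_parents: int = 250
    n_elite: int = 50
    p_mutation: float = 0.2
    n_generations: int = 20
    init_mu: float = 1.0
    init_sigma: float = 1.0
    clamp_floor: float = COST_FLOOR
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.n_elite <= self.n_parents <= self.pop_size):
            raise ValueError("need n_elite <= n_parents <= pop_size")
        if not 0.0 <= self.p_mutation <= 1.0:
            raise ValueError("p_mutation must be in [0, 1]")
        if not self.init_sigma > 0:
            raise ValueError("init_sigma must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")


@dataclass
class Individual:
    costs: np.ndarray
    fitness: float | None = None  # RMSE in years; None until evaluated


@dataclass
class GATrace:
    generation: list[int] = field(default_factory=list)
    best_rmse: list[float] = field(default_factory=list)
    mean_rmse: list[float] = field(default_factory=list)
    best_costs: list[np.ndarray] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": self.generation, "best_rmse": self.best_rmse,
             "mean_rmse": self.mean_rmse}
        )


@dataclass
class FitResult:
    best_costs: np.ndarray
    best_rmse: float
    speeds: np.ndarray
    trace: GATrace
    n_evaluations: int


def init_population(cfg: GAConfig, n_classes: int, rng: np.random.Generator) -> list[Individual]:
    """pop_size cost vectors, genes ~ N(init_mu, init_sigma²), clamped."""
    if n_classes < 1:
        raise ValueError("need at least one terrain class")
    genes = rng.normal(cfg.init_mu, cfg.init_sigma, size=(cfg.pop_size, n_classes))
    genes = np.maximum(genes, cfg.clamp_floor)
    return [Individual(costs=genes[i].copy()) for i in range(cfg.pop_size)]


def sort_population(population: list[Individual]) -> list[Individual]:
    """Ascending by fitness; stable, so ties keep insertion order."""
    if any(ind.fitness is None for ind in population):
        raise ValueError("cannot sort: population contains unevaluated individuals")
    order = np.argsort([ind.fitness for ind in population], kind="stable")
    return [population[i] for i in order]


def breed(sorted_population: list[Individual], cfg: GAConfig,
          rng: np.random.Generator) -> list[Individual]:
    """Next generation from a fitness-sorted population.

    The top ``n_elite`` pass unchanged (fitness retained, so they are not
    re-evaluated); the remaining slots are children of parent pairs drawn
    uniformly without replacement per pairing from the top ``n_parents``.
    """
    if any(ind.fitness is None for ind in sorted_population):
        raise ValueError("breed requires an evaluated, sorted population")
    fits = [ind.fitness for ind in sorted_population]
    if any(fits[i] > fits[i + 1] for i in range(len(fits) - 1)):
        raise ValueError("population must be sorted ascending by fitness")

    k = sorted_population[0].costs.shape[0]
    nxt: list[Individual] = [
        Individual(costs=ind.costs.copy(), fitness=ind.fitness)
        for ind in sorted_population[: cfg.n_elite]
    ]
    n_children = cfg.pop_size - cfg.n_elite
    for _ in range(n_children):
        i, j = rng.choice(cfg.n_parents, size=2, replace=False)
        pa = sorted_population[i].costs
        pb = sorted_population[j].costs
        mask = rng.random(k) < 0.5
        child = np.where(mask, pa, pb)
        if rng.random() < cfg.p_mutation:
            gene = rng.integers(k)
            child = child.copy()
            child[gene] += rng.standard_normal()
        nxt.append(Individual(costs=np.maximum(child, cfg.clamp_floor)))
    return nxt


def make_evaluator(raster: ClassRaster, sites: pd.DataFrame, config: SimulationConfig):
    """Closure scoring a cost vector; site→cell lookup is done once.

    Equivalent to :func:`cropspread.model.score` but avoids re-resolving site
    cells for each of the thousands of GA evaluations.
    """
    tr = raster.transform
    cells = [tr.xy_to_cell(float(x), float(y))
             for x, y in zip(sites["x"], sites["y"])]
    inside = np.array([tr.contains(r, c) for r, c in cells])
    rows = np.array([r for (r, c), ok in zip(cells, inside) if ok])
    cols = np.array([c for (r, c), ok in zip(cells, inside) if ok])
    observed = sites["observed_cal_bp"].to_numpy()[inside]
    if rows.size == 0:
        raise ValueError("no site falls inside the raster extent")

    def evaluate(costs: np.ndarray) -> float:
        surface = accumulate_cost(raster, costs, config.origin_cell)
        d = surface.dist[rows, cols]
        ok = np.isfinite(d)
        if not np.any(ok):
            return float("inf")
        predicted = config.t0 - d[ok] / config.v0
        return float(np.sqrt(np.mean((predicted - observed[ok]) ** 2)))

    return evaluate


def run_ga(
    cfg: GAConfig,
    raster: ClassRaster,
    sites: pd.DataFrame,
    sim_config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Evolve cost vectors against the observed site dates.

    ``sites`` needs columns x, y (km) and observed_cal_bp.  Returns the
    best-ever individual, its per-class speeds and the per-generation trace.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    evaluate = make_evaluator(raster, sites, sim_config)

    population = init_population(cfg, raster.n_classes, rng)
    trace = GATrace()
    n_evals = 0
    best: Individual | None = None

    for gen in range(cfg.n_generations + 1):
        for ind in population:
            if ind.fitness is None:
                ind.fitness = evaluate(ind.costs)
                n_evals += 1
        population = sort_population(population)
        if best is None or population[0].fitness < best.fitness:
            best = Individual(population[0].costs.copy(), population[0].fitness)
        trace.generation.append(gen)
        trace.best_rmse.append(population[0].fitness)
        trace.mean_rmse.append(float(np.mean([i.fitness for i in population])))
        trace.best_costs.append(population[0].costs.copy())
        if gen < cfg.n_generations:
            population = breed(population, cfg, rng)

    return FitResult(
        best_costs=best.costs,
        best_rmse=best.fitness,
        speeds=speeds_from_costs(best.costs, sim_config.v0),
        trace=trace,
        n_evaluations=n_evals,
    )


def score_full(costs, raster, sites, sim_config) -> "pd.DataFrame":
    """Full per-site diagnostic table at a given cost vector (site, D, residual)."""
    surface = accumulate_cost(raster, costs, sim_config.origin_cell)
    sampled = sample_surface(surface, sites)
    return score_sampled(sampled, sim_config).residuals
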