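"""Elitist genetic algorithm over circuit parameter sets.

Each generation holds a small population (10 by default).  The
best-performing model seeds the next generation: one elite copy is
kept intact and the remaining slots are filled with mutants.  A
parameter mutates by a multiplicative factor drawn from N(1, 0.1)
plus an additive term from U(-0.015, 0.015), clipped to its bounds.
"Shared" parameters mutate once (in the first input group) and the
new value is copied to all groups; "independent" parameters mutate
per group.

Fitness is the directional metric DSI * tanh(max R) averaged over the
stimulation speeds, computed by a pluggable circuit backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ParamSpec",
    "Genome",
    "EvolutionConfig",
    "EvalResult",
    "RunResult",
    "seed_population",
    "mutate",
    "evolve",
    "grid_search_minimal",
]


@dataclass(frozen=True)
class ParamSpec:
    """One named, bounded circuit parameter.

    ``size`` is the number of values the parameter holds (1 for global
    parameters, the number of input groups for per-group ones).
    ``shared`` parameters hold one value per group but mutate jointly;
    ``free`` controls whether the GA touches the parameter at all.
    Initial values are drawn uniformly from [init_low, init_high],
    which default to the clip bounds and must be finite.
    """

    name: str
    low: float
    high: float
    size: int = 1
    shared: bool = False
    free: bool = True
    init_low: Optional[float] = None
    init_high: Optional[float] = None

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"{self.name}: low > high")
        lo = self.low if self.init_low is None else self.init_low
        hi = self.high if self.init_high is None else self.init_high
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"{self.name}: initialization range must be finite")
        if self.size < 1:
            raise ValueError(f"{self.name}: size must be >= 1")

    @property
    def init_bounds(self) -> tuple[float, float]:
        return (self.low if self.init_low is None else self.init_low,
                self.high if self.init_high is None else self.init_high)


@dataclass
class Genome:
    """Named parameter vectors with bounds and sharing masks."""

    specs: tuple[ParamSpec, ...]
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        self.specs = tuple(self.specs)
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        for s in self.specs:
            v = self.values.get(s.name)
            if v is None:
                mid = np.clip(np.mean(s.init_bounds), s.low, s.high)
                v = np.full(s.size, mid)
            v = np.atleast_1d(np.asarray(v, dtype=float))
            if v.size == 1 and s.size > 1:
                v = np.full(s.size, v[0])
            if v.size != s.size:
                raise ValueError(f"{s.name}: expected {s.size} values, got {v.size}")
            self.values[s.name] = v

    def spec(self, name: str) -> ParamSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def copy(self) -> "Genome":
        return Genome(self.specs, {k: v.copy() for k, v in self.values.items()})

    def check_bounds(self) -> bool:
        return all(np.all(v >= s.low - 1e-12) and np.all(v <= s.high + 1e-12)
                   for s, v in ((s, self.values[s.name]) for s in self.specs))

    @property
    def free_specs(self) -> list[ParamSpec]:
        return [s for s in self.specs if s.free]


@dataclass
class EvolutionConfig:
    """GA hyperparameters; mutation scales follow the training recipe."""

    population_size: int = 10
    generations: int = 300
    mutation_sd: float = 0.10
    additive_range: float = 0.015
    n_elite: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_elite < 1:
            raise ValueError("n_elite must be >= 1 (one model is left intact)")


@dataclass
class EvalResult:
    """Fitness plus the tuning details behind it."""

    fitness: float
    dsi_per_speed: dict = field(default_factory=dict)
    responses: dict = field(default_factory=dict)  # speed -> R_theta array
    max_response: float = 0.0

    @property
    def mean_dsi(self) -> float:
        vals = list(self.dsi_per_speed.values())
        return float(np.mean(vals)) if vals else 0.0


@dataclass
class RunResult:
    """Outcome of one GA run with full seed provenance."""

    best_fitness: np.ndarray       # per generation
    best_genome: Genome
    best_eval: EvalResult
    config: EvolutionConfig
    seed: int
    n_evaluations: int


def seed_population(config: EvolutionConfig, template: Genome,
                    rng: np.random.Generator) -> list[Genome]:
    """Random initial population: free parameters uniform within their
    initialization bounds, fixed parameters copied from the template."""
    if not template.free_specs and config.population_size > 1:
        # all-fixed templates are legal (symmetric controls) but degenerate
        return [template.copy() for _ in range(config.population_size)]
    pop = []
    for _ in range(config.population_size):
        g = template.copy()
        for s in g.free_specs:
            lo, hi = s.init_bounds
            if s.shared:
                g.values[s.name][:] = rng.uniform(lo, hi)
            else:
                g.values[s.name][:] = rng.uniform(lo, hi, size=s.size)
        pop.append(g)
    return pop


def mutate(parent: Genome, config: EvolutionConfig,
           rng: np.random.Generator) -> Genome:
    """Multiplicative N(1, sd) x additive U(-a, a) mutation, clipped."""
    child = parent.copy()
    for s in child.free_specs:
        v = child.values[s.name]
        if s.shared:
            factor = rng.normal(1.0, config.mutation_sd)
            add = rng.uniform(-config.additive_range, config.additive_range)
            v[:] = v[0] * factor + add
        else:
            factor = rng.normal(1.0, config.mutation_sd, size=s.size)
            add = rng.uniform(-config.additive_range, config.additive_range, size=s.size)
            v[:] = v * factor + add
        np.clip(v, s.low, s.high, out=v)
    return child


def evolve(config: EvolutionConfig, template: Genome, backend,
           callback=None) -> RunResult:
    """Run the elitist GA: seed -> evaluate -> elite + mutants, repeat.

    ``backend`` must expose ``evaluate(genome) -> EvalResult``.  The
    elite's fitness is carried over, so with a deterministic backend
    the best fitness is exactly non-decreasing.  Evaluation failures
    assign the worst fitness (-inf) to the offending genome.
    """
    rng = np.random.default_rng(config.seed)
    population = seed_population(config, template, rng)
    best_genome: Optional[Genome] = None
    best_eval: Optional[EvalResult] = None
    history = np.empty(config.generations)
    n_evals = 0
    for gen in range(config.generations):
        for g in population:
            try:
                res = backend.evaluate(g)
            except (FloatingPointError, ValueError):
                res = EvalResult(fitness=-np.inf)
            n_evals += 1
            if best_eval is None or res.fitness > best_eval.fitness:
                best_eval, best_genome = res, g
        history[gen] = best_eval.fitness
        log.info("generation %d: best metric %.4f, mean DSI %.3f",
                 gen, best_eval.fitness, best_eval.mean_dsi)
        if log.isEnabledFor(logging.DEBUG):
            log.debug("best genome: %s",
                      {k: v.tolist() for k, v in best_genome.values.items()})
        if callback is not None:
            callback(gen, best_genome, best_eval)
        if gen < config.generations - 1:
            population = [best_genome] * config.n_elite + [
                mutate(best_genome, config, rng)
                for _ in range(config.population_size - config.n_elite)
            ]
            # the elite is not re-evaluated: its result is cached in best_eval
            population = population[config.n_elite:]
    return RunResult(history, best_genome.copy(), best_eval, config,
                     config.seed, n_evals)


def grid_search_minimal(template: Genome, backend, grid: dict,
                        max_points: int = 200_000):
    """Exhaustive lattice evaluation over the free parameters.

    ``grid`` maps parameter names to 1-D value arrays; shared and
    global parameters occupy one grid dimension each (per-group
    parameters get one dimension per group).  Returns the argmax
    genome, its EvalResult and the full fitness landscape array.
    """
    free = [s.name for s in template.free_specs]
    if set(grid) != set(free):
        raise ValueError(f"grid must cover exactly the free parameters {free}")
    dims = []
    for s in template.free_specs:
        axes = 1 if (s.shared or s.size == 1) else s.size
        for a in range(axes):
            dims.append((s.name, a, np.asarray(grid[s.name], dtype=float)))
    shape = tuple(len(d[2]) for d in dims)
    n_points = int(np.prod(shape))
    if len(dims) > 6 or n_points > max_points:
        raise ValueError(f"grid too large: {len(dims)} dims, {n_points} points")
    landscape = np.empty(shape)
    best = None
    for idx in np.ndindex(shape):
        g = template.copy()
        for (name, axis, vals), i in zip(dims, idx):
            s = g.spec(name)
            if s.shared or s.size == 1:
                g.values[name][:] = vals[i]
            else:
                g.values[name][axis] = vals[i]
        res = backend.evaluate(g)
        landscape[idx] = res.fitness
        if best is None or res.fitness > best[1].fitness:
            best = (g, res)
    return best[0], best[1], landscape
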