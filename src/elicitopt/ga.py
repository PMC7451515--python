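"""Real-coded genetic algorithm for maximizing a fitted response surface.

The optimizer follows the classic generational scheme: an initial
population drawn uniformly inside box bounds; roulette-wheel (fitness-
proportional) selection on min-shifted fitness; two-point crossover of the
real-valued chromosomes; per-coordinate uniform-redraw mutation; and
single-individual elitism, which makes the best-so-far trajectory
monotone.  Defaults — population 200, 1000 generations, crossover rate
0.7, mutation rate 0.03 — match the elicitation-optimization protocol the
package implements.

For elicitation models the search variables are (elicitor concentration,
MBCD concentration, adding day, elapsed days after elicitation); using
elapsed time instead of harvest day makes the "harvest after elicitation"
constraint structural rather than a penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    generations: int = 1000
    crossover_rate: float = 0.7
    mutation_rate: float = 0.03
    selection: str = "roulette"
    crossover: str = "two_point"
    mutation: str = "uniform"
    elite_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be < population_size")
        if self.selection != "roulette" or self.crossover != "two_point" \
                or self.mutation != "uniform":
            raise ValueError("unsupported operator choice")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass(frozen=True)
class VariableBounds:
    """Named box bounds, one (name, lower, upper) per search variable."""

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names, lower and upper must have equal length")
        for name, lo, hi in zip(self.names, self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    @property
    def d(self) -> int:
        return len(self.names)

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.lower, dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.upper, dtype=float)


#: default elicitation search region: dose and MBCD over the tested ranges,
#: adding day between mid and late log phase, harvest 2-10 days after adding
DEFAULT_BOUNDS = VariableBounds(
    names=("elicitor_conc", "mbcd_conc", "adding_day", "elapsed_days"),
    lower=(0.0, 0.0, 13.0, 2.0),
    upper=(10.0, 50.0, 17.0, 10.0),
)


@dataclass
class OptimizationResult:
    best_inputs: np.ndarray
    best_predicted: float
    history: np.ndarray
    evaluations: int
    variable_names: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)


def init_population(bounds: VariableBounds, n: int, seed_or_rng) -> np.ndarray:
    """Uniform population inside the box; reproducible from the seed."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    return rng.uniform(bounds.lo, bounds.hi, size=(n, bounds.d))


def _selection_probs(fitness: np.ndarray) -> np.ndarray:
    fitness = np.asarray(fitness, dtype=float)
    if not np.isfinite(fitness).all():
        raise ValueError("fitness must be finite for roulette selection")
    span = fitness.max() - fitness.min()
    if span == 0.0:
        return np.full(fitness.size, 1.0 / fitness.size)
    shifted = fitness - fitness.min() + 1e-9 * span
    return shifted / shifted.sum()


def roulette_select(population: np.ndarray, fitness, rng) -> tuple[int, int]:
    """Two independent fitness-proportional draws (min-shifted fitness)."""
    probs = _selection_probs(fitness)
    i, j = rng.choice(population.shape[0], size=2, p=probs)
    return int(i), int(j)


def two_point_crossover(p1, p2, rate: float, rng):
    """Swap the segment between two cut points with probability ``rate``.

    Cut points i < j are drawn uniformly from the d-1 interior positions;
    genes at positions i+1..j (1-based segment between the cuts) are
    exchanged.  The multiset of genes across the pair is conserved.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p1.size
    if d < 2:
        raise ValueError("need chromosomes of length >= 2 for two-point crossover")
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() < rate:
        if d > 2:
            i, j = np.sort(rng.choice(np.arange(1, d), size=2, replace=False))
        else:  # single interior cut: the only non-trivial segment is gene 2
            i, j = 1, 2
        # cuts sit after positions i and j (1-based): genes i..j-1 swap
        c1[i:j], c2[i:j] = p2[i:j].copy(), p1[i:j].copy()
    return c1, c2


def uniform_mutation(ind, rate: float, bounds: VariableBounds, rng):
    """Redraw each coordinate uniformly inside its bounds with prob ``rate``."""
    ind = np.asarray(ind, dtype=float).copy()
    mask = rng.random(ind.size) < rate
    if mask.any():
        ind[mask] = rng.uniform(bounds.lo[mask], bounds.hi[mask])
    return ind


def _evaluate(objective, pop: np.ndarray) -> np.ndarray:
    """Evaluate a population, accepting vectorized or per-point objectives."""
    try:
        vals = np.asarray(objective(pop), dtype=float)
        if vals.shape == (pop.shape[0],):
            return vals
    except Exception:
        pass
    return np.array([float(objective(row)) for row in pop])


def ga_maximize(objective, bounds: VariableBounds,
                config: GAConfig = GAConfig()) -> OptimizationResult:
    """Generational GA maximization of ``objective`` over the box.

    ``objective`` may accept a single length-d vector or, for speed, a
    whole (n, d) matrix returning n values.  Returns the best-ever point;
    ``history`` holds the best-so-far fitness per generation and is
    non-decreasing whenever ``elite_count >= 1``.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(bounds, config.population_size, rng)
    fitness = _evaluate(objective, pop)
    if not np.isfinite(fitness).all():
        k = int(np.argmax(~np.isfinite(fitness)))
        raise ValueError(f"objective returned non-finite value at {pop[k]}")
    evaluations = config.population_size
    best_x = pop[np.argmax(fitness)].copy()
    best_f = float(fitness.max())
    history = []

    n_children = config.population_size - config.elite_count
    d = bounds.d
    # all admissible (i, j) interior cut pairs, enumerated once
    if d > 2:
        cut_pairs = np.array([(i, j) for i in range(1, d)
                              for j in range(i + 1, d)], dtype=int)
    else:
        cut_pairs = np.array([(1, 2)], dtype=int)
    cols = np.arange(d)
    for _ in range(config.generations):
        probs = _selection_probs(fitness)
        n_pairs = (n_children + 1) // 2
        parents = rng.choice(config.population_size, size=(n_pairs, 2), p=probs)
        p1, p2 = pop[parents[:, 0]], pop[parents[:, 1]]
        # vectorized two-point crossover (same distribution as the scalar op)
        cross = rng.random(n_pairs) < config.crossover_rate
        cuts = cut_pairs[rng.integers(cut_pairs.shape[0], size=n_pairs)]
        seg = (cols >= cuts[:, :1]) & (cols < cuts[:, 1:]) & cross[:, None]
        c1 = np.where(seg, p2, p1)
        c2 = np.where(seg, p1, p2)
        children = np.empty((n_pairs * 2, d))
        children[0::2] = c1
        children[1::2] = c2
        children = children[:n_children]
        # vectorized uniform mutation over the whole brood
        mask = rng.random(children.shape) < config.mutation_rate
        if mask.any():
            draws = rng.uniform(bounds.lo, bounds.hi, size=children.shape)
            children[mask] = draws[mask]
        if config.elite_count:
            elite_idx = np.argsort(fitness)[-config.elite_count:]
            pop = np.vstack([pop[elite_idx], children])
        else:
            pop = children
        fitness = _evaluate(objective, pop)
        if not np.isfinite(fitness).all():
            k = int(np.argmax(~np.isfinite(fitness)))
            raise ValueError(f"objective returned non-finite value at {pop[k]}")
        evaluations += pop.shape[0]
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_f:
            best_f = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
        history.append(best_f)

    return OptimizationResult(best_inputs=best_x, best_predicted=best_f,
                              history=np.asarray(history),
                              evaluations=evaluations,
                              variable_names=bounds.names)


def optimize_model(model_predict, bounds: VariableBounds = DEFAULT_BOUNDS,
                   config: GAConfig = GAConfig(),
                   max_harvest_day: float | None = None) -> OptimizationResult:
    """Maximize a fitted elicitation model over (conc, mbcd, adding, elapsed).

    ``model_predict`` must map an (n, 4) array of (elicitor_conc,
    mbcd_conc, adding_day, harvest_day) rows to n predicted responses.
    The GA searches elapsed days after elicitation as its fourth variable
    and maps it to a harvest day before prediction, so harvest > adding
    holds for every candidate.

    ``max_harvest_day`` bounds candidate harvests at the last day the data
    actually cover (e.g. the final scheduled harvest): a surrogate fitted
    to a harvest schedule has no support beyond it, and unconstrained
    search readily chases extrapolation artifacts there.  Candidates past
    the cap are evaluated at the cap, so the reported optimum never leaves
    the data region.  The result reports both time scales; ``best_inputs``
    holds the effective (capped) elapsed time.
    """
    if bounds.d != 4:
        raise ValueError("elicitation bounds must have 4 variables")

    def clamp_harvest(pts: np.ndarray) -> np.ndarray:
        mapped = np.atleast_2d(pts).copy()
        harvest = mapped[:, 2] + mapped[:, 3]
        if max_harvest_day is not None:
            harvest = np.minimum(harvest, max_harvest_day)
        mapped[:, 3] = harvest
        return mapped

    def objective(pts: np.ndarray) -> np.ndarray:
        return np.asarray(model_predict(clamp_harvest(pts)), dtype=float)

    res = ga_maximize(objective, bounds, config)
    best = clamp_harvest(res.best_inputs)[0]
    conc, mbcd, adding, harvest = best
    res.best_inputs = np.array([conc, mbcd, adding, harvest - adding])
    res.extras = {
        "harvest_day": float(harvest),
        "elapsed_days": float(harvest - adding),
    }
    return res
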