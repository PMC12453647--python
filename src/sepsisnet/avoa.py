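"""African vulture optimization algorithm (AVOA) and the hyperparameter driver.

A population of candidate solutions ("vultures") is evolved by alternating
random exploration steps, exploitation moves toward the best solution found
so far, midpoint breeding, and an optional accept-if-better Gaussian local
search.  Minimization convention throughout; positions are always clipped to
the search-space bounds.

Per-dimension ``log10`` scaling lets rate-like quantities (e.g. the learning
rate) be searched uniformly on a log axis: internally all positions live in
the transformed box, and are decoded before the fitness function sees them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchSpace",
    "AVOAConfig",
    "Candidate",
    "OptimizationTrace",
    "initialize_population",
    "explore_or_exploit",
    "breed",
    "local_search",
    "avoa_optimize",
    "tune_hyperparameters",
    "default_hyperparameter_space",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box constraints with optional per-dimension log scaling."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    scale: tuple[str, ...] | None = None  # "linear" | "log10" per dimension
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.lower) != len(self.upper):
            raise ValueError("lower and upper must have equal length")
        for lo, hi in zip(self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"need lower < upper in every dimension ({lo} !< {hi})")
        if self.scale is not None:
            if len(self.scale) != len(self.lower):
                raise ValueError("scale must name every dimension")
            for s, lo in zip(self.scale, self.lower):
                if s not in ("linear", "log10"):
                    raise ValueError(f"unknown scale {s!r}")
                if s == "log10" and lo <= 0:
                    raise ValueError("log10 scaling needs positive bounds")

    @property
    def ndim(self) -> int:
        return len(self.lower)

    def _scales(self) -> tuple[str, ...]:
        return self.scale or ("linear",) * self.ndim

    def internal_bounds(self):
        """Bounds in the (possibly log-transformed) internal coordinates."""
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        log = np.array([s == "log10" for s in self._scales()])
        lo = np.where(log, np.log10(np.where(log, lo, 1.0)), lo)
        hi = np.where(log, np.log10(np.where(log, hi, 1.0)), hi)
        return lo, hi

    def decode(self, internal: np.ndarray) -> np.ndarray:
        log = np.array([s == "log10" for s in self._scales()])
        return np.where(log, 10.0**internal, internal)

    def clip(self, internal: np.ndarray) -> np.ndarray:
        lo, hi = self.internal_bounds()
        return np.clip(internal, lo, hi)


@dataclass(frozen=True)
class AVOAConfig:
    population_size: int = 30
    max_iter: int = 50
    step_size: float = 0.1            # exploration step, fraction of range/dim
    exploration_radius: float = 0.3   # probability of the exploration branch
    exploitation_factor: float = 0.7  # pull toward the best solution
    reproduction_rate: float = 0.2
    breeding_factor: float = 1.0
    local_search: bool = True
    local_search_scale: float = 0.01  # Gaussian sd, fraction of range/dim
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exploration_radius", "exploitation_factor", "reproduction_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Candidate:
    """Internal-coordinate position and its fitness (inf = unevaluated)."""

    position: np.ndarray
    fitness: float = np.inf


@dataclass
class OptimizationTrace:
    best_fitness: list[float] = field(default_factory=list)
    best_position: list[np.ndarray] = field(default_factory=list)
    evaluations: list[int] = field(default_factory=list)

    def to_rows(self):
        return [
            {"iteration": i, "best_fitness": f, "evaluations": n,
             **{f"x{d}": p[d] for d in range(len(p))}}
            for i, (f, p, n) in enumerate(
                zip(self.best_fitness, self.best_position, self.evaluations)
            )
        ]


def initialize_population(
    space: SearchSpace, config: AVOAConfig, rng: np.random.Generator | None = None
) -> list[Candidate]:
    """Uniform positions within bounds (uniform in log10 for log dimensions)."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = space.internal_bounds()
    positions = rng.uniform(lo, hi, size=(config.population_size, space.ndim))
    return [Candidate(position=p) for p in positions]


def explore_or_exploit(
    candidate: Candidate,
    best_position: np.ndarray,
    space: SearchSpace,
    config: AVOAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One movement step: random walk with probability ``exploration_radius``,
    otherwise a pull of strength ``exploitation_factor`` toward the best."""
    lo, hi = space.internal_bounds()
    span = hi - lo
    pos = candidate.position
    if rng.random() < config.exploration_radius:
        step = rng.uniform(-config.step_size * span, config.step_size * span)
        pos = pos + step
    else:
        pos = pos + config.exploitation_factor * (best_position - pos)
    return space.clip(pos)


def breed(
    parent1: np.ndarray,
    parent2: np.ndarray,
    breeding_factor: float,
    space: SearchSpace,
) -> np.ndarray:
    """Child = breeding_factor x midpoint of the parents, clipped to bounds."""
    return space.clip(breeding_factor * (parent1 + parent2) / 2.0)


def local_search(
    position: np.ndarray,
    fitness: float,
    fitness_fn,
    space: SearchSpace,
    scale: float,
    rng: np.random.Generator,
):
    """One Gaussian perturbation, accepted only if it improves the fitness.

    Returns ``(position, fitness, evaluated)``.
    """
    if scale <= 0:
        return position, fitness, 0
    lo, hi = space.internal_bounds()
    trial = space.clip(position + rng.normal(0.0, scale * (hi - lo)))
    trial_fitness = _safe_fitness(fitness_fn, space.decode(trial))
    if trial_fitness < fitness:
        return trial, trial_fitness, 1
    return position, fitness, 1


def _safe_fitness(fitness_fn, decoded: np.ndarray) -> float:
    value = float(fitness_fn(decoded))
    if not np.isfinite(value):
        warnings.warn(
            f"non-finite fitness at {decoded}; candidate penalized", stacklevel=3
        )
        return np.inf
    return value


def avoa_optimize(fitness_fn, space: SearchSpace, config: AVOAConfig | None = None):
    """Run the full optimization loop.

    Returns ``(best_position, best_fitness, trace)`` with the position in
    original (decoded) units.  The best-so-far fitness recorded in the trace
    is non-increasing, and the run is fully reproducible from the seed.
    """
    config = config or AVOAConfig()
    rng = np.random.default_rng(config.seed)
    population = initialize_population(space, config, rng)
    best_position = population[0].position.copy()
    best_fitness = np.inf
    trace = OptimizationTrace()
    evaluations = 0

    for _ in range(config.max_iter):
        # evaluate every vulture, track the best solution found so far
        for cand in population:
            cand.fitness = _safe_fitness(fitness_fn, space.decode(cand.position))
            evaluations += 1
            if cand.fitness < best_fitness:
                best_fitness = cand.fitness
                best_position = cand.position.copy()
        # foraging / scavenging movement
        for cand in population:
            cand.position = explore_or_exploit(cand, best_position, space, config, rng)
        # reproduction and breeding
        for cand in population:
            if rng.random() < config.reproduction_rate:
                partner = population[int(rng.integers(config.population_size))]
                cand.position = breed(
                    cand.position, partner.position, config.breeding_factor, space
                )
        # optional local refinement (accept-if-better)
        if config.local_search:
            for cand in population:
                cand.fitness = _safe_fitness(fitness_fn, space.decode(cand.position))
                evaluations += 1
                if cand.fitness < best_fitness:
                    best_fitness = cand.fitness
                    best_position = cand.position.copy()
                cand.position, cand.fitness, used = local_search(
                    cand.position,
                    cand.fitness,
                    fitness_fn,
                    space,
                    config.local_search_scale,
                    rng,
                )
                evaluations += used
                if cand.fitness < best_fitness:
                    best_fitness = cand.fitness
                    best_position = cand.position.copy()
        trace.best_fitness.append(best_fitness)
        trace.best_position.append(space.decode(best_position))
        trace.evaluations.append(evaluations)

    return space.decode(best_position), best_fitness, trace


def default_hyperparameter_space() -> SearchSpace:
    """Learning rate on a log axis in [1e-4, 1e-1]; dropout in [0.1, 0.7]."""
    return SearchSpace(
        lower=(1e-4, 0.1),
        upper=(1e-1, 0.7),
        scale=("log10", "linear"),
        names=("learning_rate", "dropout"),
    )


def tune_hyperparameters(
    train_cohort,
    val_cohort,
    space: SearchSpace | None = None,
    config: AVOAConfig | None = None,
    model_config=None,
    train_config=None,
    tuning_epochs: int = 3,
):
    """Search (learning rate, dropout) by minimizing budget-limited
    validation loss.

    Each candidate trains the model for ``tuning_epochs`` epochs at its
    hyperparameters and is scored by final validation loss.  Returns
    ``(best_hyperparameters: dict, best_fitness, trace)``.
    """
    from dataclasses import replace

    from .training import TrainConfig, prepare_windows, train as train_model

    space = space or default_hyperparameter_space()
    config = config or AVOAConfig(population_size=4, max_iter=3, local_search=False)
    train_config = train_config or TrainConfig()
    names = space.names or tuple(f"x{i}" for i in range(space.ndim))

    train_data = prepare_windows(train_cohort, model_config)
    val_data = prepare_windows(val_cohort, model_config)

    def fitness(decoded: np.ndarray) -> float:
        params = dict(zip(names, decoded))
        tc = replace(
            train_config,
            learning_rate=float(params.get("learning_rate", train_config.learning_rate)),
            dropout=float(params.get("dropout", train_config.dropout)),
            max_epochs=tuning_epochs,
            patience=max(tuning_epochs, 1),
        )
        from dataclasses import replace as _rep

        mc = _rep(model_config, dropout=tc.dropout)
        from .model import build_model

        model = build_model(mc)
        _, history = train_model(model, train_data, val_data, tc)
        return float(history["val_loss"][-1])

    best_position, best_fitness, trace = avoa_optimize(fitness, space, config)
    best = dict(zip(names, best_position))
    return best, best_fitness, trace
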