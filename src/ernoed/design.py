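"""Evolutionary optimal experimental design of six-inlet flow sequences.

A design candidate is a genome of level indices (one per segment and
inlet) decoding to a piecewise-constant :class:`FlowProfile`.  Fitness is
the expected D-criterion: forward sensitivities are simulated per ensemble
member under the candidate profile, weighted by the measurement-noise
model evaluated on the member's own nominal trajectory, assembled into a
Fisher information matrix and scored by ``log det``; the candidate's
fitness is the mean score over the ensemble, which makes the design robust
to the current parameter uncertainty.

The optimiser is a generational genetic algorithm: tournament selection,
one-point crossover on the flattened genome, per-gene mutation to a random
other level, and elitism (so best-so-far fitness is monotone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkModel
from .reactor import FlowProfile, ReactorConfig, SimulationError, fraction_times
from .sensitivity import d_score, fisher_information, forward_sensitivities
from .synthetic import NoiseModel

__all__ = [
    "DesignSpace",
    "OEDConfig",
    "DesignCandidate",
    "DesignResult",
    "random_candidate",
    "score_candidate",
    "evolve_design",
]


@dataclass(frozen=True)
class DesignSpace:
    """Discrete search space: per segment and inlet, one allowed flow level."""

    n_segments: int = 12
    segment_min: float = 60.0
    levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    n_inlets: int = 6

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.n_inlets < 1:
            raise ValueError("need >= 1 segment and inlet")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("duplicate flow levels")

    @property
    def horizon(self) -> float:
        return self.n_segments * self.segment_min

    @classmethod
    def for_reactor(cls, reactor: ReactorConfig, n_segments: int = 12,
                    segment_min: float = 60.0) -> "DesignSpace":
        return cls(n_segments=n_segments, segment_min=segment_min,
                   levels=tuple(reactor.flow_levels))


@dataclass(frozen=True)
class OEDConfig:
    """Genetic-algorithm hyperparameters (all logged with every run)."""

    population: int = 32
    generations: int = 40
    p_crossover: float = 0.7
    p_mutation: float | None = None  # default: 1 / genome length
    elitism: int = 2
    tournament: int = 3
    #: cap on ensemble members used for robust scoring
    ensemble_max: int = 3

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.elitism < 1 or self.elitism >= self.population:
            raise ValueError("elitism must be in [1, population)")


@dataclass
class DesignCandidate:
    """Genome of level indices with its decoded profile and fitness."""

    genome: np.ndarray  # (n_segments, n_inlets) int
    space: DesignSpace
    fitness: float | None = None

    def decode(self) -> FlowProfile:
        levels = np.asarray(self.space.levels)
        rates = levels[self.genome]
        durations = [(self.space.segment_min, row) for row in rates]
        return FlowProfile.from_segments(durations)

    def key(self) -> bytes:
        return self.genome.astype(np.int64).tobytes()


@dataclass
class DesignResult:
    best: DesignCandidate
    best_fitness: float
    history: list[dict] = field(default_factory=list)
    evaluations: int = 0


def random_candidate(space: DesignSpace, rng: np.random.Generator
                     ) -> DesignCandidate:
    """Uniform draw over level indices; segments with zero total flow are
    redrawn so the reactor never stalls."""
    levels = np.asarray(space.levels)
    genome = rng.integers(0, len(levels), size=(space.n_segments, space.n_inlets))
    zero = levels[genome].sum(axis=1) <= 0
    while zero.any():
        genome[zero] = rng.integers(0, len(levels),
                                    size=(int(zero.sum()), space.n_inlets))
        zero = levels[genome].sum(axis=1) <= 0
    return DesignCandidate(genome=genome, space=space)


def score_candidate(candidate: DesignCandidate, model: NetworkModel,
                    ensemble, reactor: ReactorConfig,
                    noise: NoiseModel | None = None, *,
                    times=None, loading=None,
                    rtol: float = 1e-6, atol: float = 1e-8) -> float:
    """Expected D-score of a candidate over a parameter ensemble.

    ``ensemble`` may be a ParameterEnsemble or any iterable of parameter
    vectors.  Members whose sensitivity integration fails are skipped with
    a warning; if all fail an error is raised.
    """
    members = getattr(ensemble, "members", ensemble)
    members = list(members)
    if not members:
        raise ValueError("ensemble must be non-empty")
    noise = noise or NoiseModel()
    profile = candidate.decode()
    if times is None:
        times = fraction_times(reactor, profile.horizon)
    scores = []
    for member in members:
        theta = model.coerce_theta(member)
        try:
            sens = forward_sensitivities(model, theta, profile, reactor,
                                         times, loading=loading,
                                         method="staggered",
                                         rtol=rtol, atol=atol)
        except SimulationError as exc:
            warnings.warn(f"design scoring skipped one member: {exc}")
            continue
        obs_idx = [model.species.index(s) for s in sens.observables]
        sigma = noise.sigma(sens.states[:, obs_idx])
        try:
            F = fisher_information(sens, sigma, theta)
        except ValueError as exc:  # overflowing sensitivities etc.
            warnings.warn(f"design scoring skipped one member: {exc}")
            continue
        scores.append(d_score(F))
    if not scores:
        raise SimulationError("design scoring failed for every ensemble member")
    return float(np.mean(scores))


def evolve_design(space: DesignSpace, model: NetworkModel, ensemble,
                  reactor: ReactorConfig, cfg: OEDConfig,
                  rng: np.random.Generator | int | None = None, *,
                  noise: NoiseModel | None = None, loading=None,
                  score_fn=None) -> DesignResult:
    """Run the generational GA and return the best design found.

    Fitness evaluations are memoised per genome; ``history`` records the
    best and mean fitness of every generation.  ``score_fn`` (candidate ->
    fitness) replaces the default expected-D-score objective, e.g. for
    cheap surrogate objectives.
    """
    rng = np.random.default_rng(rng)
    members = list(getattr(ensemble, "members", ensemble))[:cfg.ensemble_max] \
        if score_fn is None else []
    n_levels = len(space.levels)
    genome_len = space.n_segments * space.n_inlets
    p_mut = cfg.p_mutation if cfg.p_mutation is not None else 1.0 / genome_len

    cache: dict[bytes, float] = {}
    evaluations = 0

    def fitness(cand: DesignCandidate) -> float:
        nonlocal evaluations
        key = cand.key()
        if key not in cache:
            if score_fn is not None:
                cache[key] = float(score_fn(cand))
            else:
                try:
                    cache[key] = score_candidate(cand, model, members,
                                                 reactor, noise,
                                                 loading=loading)
                except SimulationError:
                    # unsimulatable for every member: a dead candidate
                    cache[key] = -np.inf
            evaluations += 1
        cand.fitness = cache[key]
        return cand.fitness

    def repair(genome: np.ndarray) -> np.ndarray:
        levels = np.asarray(space.levels)
        zero = levels[genome].sum(axis=1) <= 0
        while zero.any():
            genome[zero] = rng.integers(0, n_levels,
                                        size=(int(zero.sum()), space.n_inlets))
            zero = levels[genome].sum(axis=1) <= 0
        return genome

    population = [random_candidate(space, rng) for _ in range(cfg.population)]
    for cand in population:
        fitness(cand)
    history: list[dict] = []

    for gen in range(cfg.generations):
        population.sort(key=lambda c: -c.fitness)
        history.append({
            "generation": gen,
            "best": float(population[0].fitness),
            "mean": float(np.mean([c.fitness for c in population])),
        })
        elites = [DesignCandidate(c.genome.copy(), space, c.fitness)
                  for c in population[:cfg.elitism]]
        offspring: list[DesignCandidate] = []
        while len(offspring) < cfg.population - cfg.elitism:
            def tournament() -> DesignCandidate:
                picks = rng.integers(0, cfg.population, size=cfg.tournament)
                return max((population[i] for i in picks),
                           key=lambda c: c.fitness)
            a, b = tournament().genome.ravel().copy(), \
                tournament().genome.ravel().copy()
            if rng.random() < cfg.p_crossover:
                cut = int(rng.integers(1, genome_len))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                mutate = rng.random(genome_len) < p_mut
                if mutate.any():
                    shift = rng.integers(1, n_levels, size=int(mutate.sum()))
                    child[mutate] = (child[mutate] + shift) % n_levels
                genome = repair(child.reshape(space.n_segments, space.n_inlets))
                offspring.append(DesignCandidate(genome, space))
                if len(offspring) >= cfg.population - cfg.elitism:
                    break
        population = elites + offspring
        for cand in population:
            fitness(cand)

    population.sort(key=lambda c: -c.fitness)
    best = population[0]
    history.append({
        "generation": cfg.generations,
        "best": float(best.fitness),
        "mean": float(np.mean([c.fitness for c in population])),
    })
    return DesignResult(best=best, best_fitness=float(best.fitness),
                        history=history, evaluations=evaluations)
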