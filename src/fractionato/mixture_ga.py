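"""Genetic-algorithm estimation of the deletion-length mixture.

The mixture that best explains an observed deletion-run histogram is found
by evolving genomes of 20 slots, each slot holding a deletion length in
1..5; a genome's mixture weight for length L is (slots equal to L)/20, so
weights move in 5% steps.  Fitness is the total absolute difference between
the observed run counts and the median run counts of a Monte Carlo
simulation run with the candidate mixture at the same gene count and
deletion count; lower is better.

Because the fitness is a Monte Carlo estimate it is noisy; the elite genome
is re-evaluated every generation with a fresh sub-seed so a lucky draw
cannot lock in.  The selection/crossover/mutation operators and their
defaults are this package's own choices and are fully config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .fractionation_sim import DeletionMixture, simulate_deletion_runs
from .run_analysis import RunDistribution

__all__ = ["GAConfig", "FitResult", "fitness", "fit_mixture"]


@dataclass(frozen=True)
class GAConfig:
    """Tuning knobs for the mixture fit.

    ``n_slots=20`` gives 5% weight granularity over lengths
    ``min_length..max_length`` (1..5).  ``generations`` defaults to a
    scaled-down 500 (the original fit ran far longer); raise it for
    higher-precision fits.
    """

    n_slots: int = 20
    min_length: int = 1
    max_length: int = 5
    generations: int = 500
    population_size: int = 50
    mutation_rate: float = 0.05
    crossover_rate: float = 0.7
    tournament_k: int = 3
    elitism: int = 1
    fitness_replicates: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slots < 1 or self.generations < 1 or self.population_size < 1:
            raise ValueError("n_slots, generations and population_size must be >= 1")
        if not (1 <= self.min_length <= self.max_length <= 5):
            raise ValueError("length range must lie within 1..5")
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ValueError("rates must be probabilities")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_mixture`."""

    best_mixture: DeletionMixture
    fitness: float
    history: np.ndarray  # best-so-far fitness, non-increasing
    history_raw: np.ndarray  # per-generation elite score (noisy)
    best_genome: np.ndarray
    config: GAConfig


def _genome_to_mixture(genome: np.ndarray, n_slots: int) -> DeletionMixture:
    vals, counts = np.unique(genome, return_counts=True)
    return DeletionMixture({int(v): float(c) / n_slots for v, c in zip(vals, counts)})


def fitness(
    candidate: DeletionMixture,
    observed: RunDistribution,
    n_genes: int,
    n_deleted: int,
    replicates: int = 25,
    seed: int = 0,
) -> float:
    """Sum over run lengths of |median simulated count - observed count|.

    Lengths present on either side contribute; a perfect score of 0 means
    the candidate's median replicate reproduces the observed histogram
    exactly.
    """
    if not observed.counts:
        raise ValueError("observed run distribution is empty")
    env = simulate_deletion_runs(
        n_genes, n_deleted, candidate, replicates=replicates, seed=seed
    )
    lengths = set(observed.counts) | set(env.medians)
    return float(
        sum(
            abs(env.medians.get(k, 0.0) - observed.counts.get(k, 0))
            for k in lengths
        )
    )


def fit_mixture(
    observed: RunDistribution,
    n_genes: int,
    n_deleted: int,
    config: Optional[GAConfig] = None,
) -> FitResult:
    """Evolve the deletion-length mixture that best reproduces *observed*.

    ``observed`` must be consistent with the problem size: the runs must
    cover exactly ``n_deleted`` genes.  Deterministic given ``config.seed``.
    """
    cfg = config or GAConfig()
    if observed.total_genes != n_deleted:
        raise ValueError(
            f"observed runs cover {observed.total_genes} genes but n_deleted={n_deleted}"
        )
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.min_length, cfg.max_length
    pop = rng.integers(lo, hi + 1, size=(cfg.population_size, cfg.n_slots))

    def evaluate(genomes: np.ndarray, eval_seed: int) -> np.ndarray:
        scores = np.empty(len(genomes))
        for i, g in enumerate(genomes):
            scores[i] = fitness(
                _genome_to_mixture(g, cfg.n_slots),
                observed,
                n_genes,
                n_deleted,
                replicates=cfg.fitness_replicates,
                seed=eval_seed,
            )
        return scores

    history_raw = np.empty(cfg.generations)
    best_genome = pop[0].copy()
    best_score = np.inf
    for gen in range(cfg.generations):
        eval_seed = (cfg.seed * 1000003 + gen) & 0x7FFFFFFF
        scores = evaluate(pop, eval_seed)
        order = np.argsort(scores, kind="stable")
        elite_idx = order[0]
        history_raw[gen] = scores[elite_idx]
        if scores[elite_idx] <= best_score:
            best_score = float(scores[elite_idx])
            best_genome = pop[elite_idx].copy()
        if gen == cfg.generations - 1:
            break
        children = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(children) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_k)
                parents.append(pop[contenders[np.argmin(scores[contenders])]])
            child = parents[0].copy()
            if cfg.n_slots > 1 and rng.random() < cfg.crossover_rate:
                cut = int(rng.integers(1, cfg.n_slots))
                child[cut:] = parents[1][cut:]
            mutate = rng.random(cfg.n_slots) < cfg.mutation_rate
            if mutate.any():
                child[mutate] = rng.integers(lo, hi + 1, size=int(mutate.sum()))
            children.append(child)
        pop = np.array(children)

    history = np.minimum.accumulate(history_raw)
    return FitResult(
        best_mixture=_genome_to_mixture(best_genome, cfg.n_slots),
        fitness=float(best_score),
        history=history,
        history_raw=history_raw,
        best_genome=best_genome,
        config=cfg,
    )
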