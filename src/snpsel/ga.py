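"""Stage 2: binary genetic-algorithm wrapper over a candidate SNP group.

Each chromosome is a bit vector over the candidate SNPs; its fitness is the
k-fold cross-validated mean squared error of an epsilon-SVR (PUK kernel by
default) restricted to the selected columns — lower is better.  The fold
partition is fixed once per run (seeded from the configuration), so fitness
is a deterministic function of the chromosome and can be memoized.

Operators: tournament (default) or roulette selection, one-point crossover
applied to each selected parent pair with probability ``p_crossover``,
independent per-bit mutation with probability ``p_mutation_per_bit``, and
elitism copying the best individuals unchanged, which makes the
per-generation best fitness non-increasing.  The all-zero chromosome is
penalized with +inf rather than repaired.

SVR hyperparameters are frozen during the run (typically the values tuned
for the full candidate group): re-tuning per chromosome would multiply the
cost by the grid size and is not part of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .svr import SVRHyper, _fold_indices, _standardize_train_apply, fit_svr

PENALTY = np.inf


@dataclass
class GAConfig:
    population_size: int = 20
    generations: int = 20
    p_crossover: float = 0.6
    p_mutation_per_bit: float = 0.033
    elitism_count: int = 1
    selection: str = "tournament"
    tournament_size: int = 2
    fitness_folds: int = 10
    seed: int = 0
    svr_hyper: SVRHyper | None = None
    standardize: bool = True
    mutation_mode: str = "per_bit"  # or 'per_chromosome'
    fitness_seed: int | None = None  # fold-partition seed; defaults to `seed`

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.generations < 1:
            raise ValueError("generations must be positive")
        for p, name in ((self.p_crossover, "p_crossover"), (self.p_mutation_per_bit, "p_mutation_per_bit")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be < population_size")
        if self.selection not in ("tournament", "roulette"):
            raise ValueError("selection must be 'tournament' or 'roulette'")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if self.fitness_folds < 2:
            raise ValueError("fitness_folds must be >= 2")
        if self.mutation_mode not in ("per_bit", "per_chromosome"):
            raise ValueError("mutation_mode must be 'per_bit' or 'per_chromosome'")

    def to_dict(self) -> dict:
        h = self.svr_hyper
        return {
            "population_size": self.population_size,
            "generations": self.generations,
            "p_crossover": self.p_crossover,
            "p_mutation_per_bit": self.p_mutation_per_bit,
            "elitism_count": self.elitism_count,
            "selection": self.selection,
            "tournament_size": self.tournament_size,
            "fitness_folds": self.fitness_folds,
            "seed": self.seed,
            "mutation_mode": self.mutation_mode,
            "svr_hyper": None
            if h is None
            else {"C": h.C, "epsilon": h.epsilon, "kernel": h.kernel.label()},
        }


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_fitness: float
    trajectory_best: list[float]
    trajectory_mean: list[float]
    selected_snp_ids: list[str]
    evaluation_count: int
    config: GAConfig

    def to_dict(self) -> dict:
        return {
            "best_chromosome": [int(b) for b in self.best_chromosome],
            "best_fitness": float(self.best_fitness),
            "trajectory_best": [float(v) for v in self.trajectory_best],
            "trajectory_mean": [float(v) for v in self.trajectory_mean],
            "selected_snp_ids": list(self.selected_snp_ids),
            "evaluation_count": self.evaluation_count,
            "config": self.config.to_dict(),
        }


class _FitnessEvaluator:
    """Memoized CV-MSE fitness with a fixed, seeded fold partition."""

    def __init__(self, X: np.ndarray, y: np.ndarray, config: GAConfig):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.config = config
        if config.svr_hyper is None:
            raise ValueError("GAConfig.svr_hyper must be set")
        partition_seed = config.seed if config.fitness_seed is None else config.fitness_seed
        rng = np.random.default_rng(np.random.SeedSequence([partition_seed, 0x5F17]))
        self.folds = _fold_indices(len(self.y), config.fitness_folds, rng)
        self.cache: dict[bytes, float] = {}
        self.evaluations = 0

    def __call__(self, chromosome: np.ndarray) -> float:
        key = np.packbits(chromosome).tobytes()
        if key in self.cache:
            return self.cache[key]
        if not chromosome.any():
            value = PENALTY
        else:
            value = self._cv_mse(np.flatnonzero(chromosome))
            self.evaluations += 1
        self.cache[key] = value
        return value

    def _cv_mse(self, cols: np.ndarray) -> float:
        Xs = self.X[:, cols]
        n = len(self.y)
        pred = np.empty(n)
        for test_idx in self.folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            X_tr, X_te = Xs[train_mask], Xs[test_idx]
            if self.config.standardize:
                X_tr, X_te = _standardize_train_apply(X_tr, X_te)
            model = fit_svr(X_tr, self.y[train_mask], self.config.svr_hyper)
            pred[test_idx] = model.predict(X_te)
        return float(np.mean((pred - self.y) ** 2))


def fitness(chromosome: np.ndarray, X: np.ndarray, y: np.ndarray, config: GAConfig) -> float:
    """Cross-validated MSE of the SVR restricted to the 1-bits (one-off call)."""
    chromosome = np.asarray(chromosome, dtype=bool)
    if chromosome.shape[0] != np.asarray(X).shape[1]:
        raise ValueError("chromosome length must equal the number of candidate SNPs")
    return _FitnessEvaluator(X, y, config)(chromosome)


def _select_parent(rng, population, fitnesses, config: GAConfig) -> np.ndarray:
    n = len(population)
    if config.selection == "tournament":
        contenders = rng.integers(0, n, size=config.tournament_size)
        best = min(contenders, key=lambda i: fitnesses[i])
        return population[best]
    # roulette on inverse MSE (penalized individuals get zero weight)
    inv = np.array([0.0 if not np.isfinite(f) else 1.0 / (f + 1e-12) for f in fitnesses])
    if inv.sum() == 0:
        return population[rng.integers(0, n)]
    probs = inv / inv.sum()
    return population[rng.choice(n, p=probs)]


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    candidate_snp_ids,
    config: GAConfig,
) -> GAResult:
    """Run the GA wrapper and return the best SNP subset found.

    ``X`` holds the candidate columns (same order as ``candidate_snp_ids``).
    Deterministic for a fixed config/seed.
    """
    X = np.asarray(X, dtype=float)
    snp_ids = list(candidate_snp_ids)
    L = X.shape[1]
    if L != len(snp_ids):
        raise ValueError("candidate_snp_ids length must match X columns")
    if L < 1:
        raise ValueError("need at least one candidate SNP")

    evaluator = _FitnessEvaluator(X, y, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6A]))

    population = [rng.random(L) < 0.5 for _ in range(config.population_size)]
    fitnesses = [evaluator(c) for c in population]

    best_idx = int(np.argmin(fitnesses))
    best_chrom = population[best_idx].copy()
    best_fit = fitnesses[best_idx]
    traj_best: list[float] = [best_fit]
    finite = [f for f in fitnesses if np.isfinite(f)]
    traj_mean: list[float] = [float(np.mean(finite)) if finite else PENALTY]

    for _gen in range(config.generations):
        order = np.argsort(fitnesses, kind="stable")
        next_pop = [population[i].copy() for i in order[: config.elitism_count]]
        while len(next_pop) < config.population_size:
            p1 = _select_parent(rng, population, fitnesses, config)
            p2 = _select_parent(rng, population, fitnesses, config)
            c1, c2 = p1.copy(), p2.copy()
            if L > 1 and rng.random() < config.p_crossover:
                point = int(rng.integers(1, L))
                c1 = np.concatenate([p1[:point], p2[point:]])
                c2 = np.concatenate([p2[:point], p1[point:]])
            for child in (c1, c2):
                if config.mutation_mode == "per_bit":
                    flips = rng.random(L) < config.p_mutation_per_bit
                    child ^= flips
                else:
                    if rng.random() < config.p_mutation_per_bit:
                        child[rng.integers(0, L)] ^= True
                if len(next_pop) < config.population_size:
                    next_pop.append(child)
        population = next_pop
        fitnesses = [evaluator(c) for c in population]
        gen_best = int(np.argmin(fitnesses))
        if fitnesses[gen_best] < best_fit:
            best_fit = fitnesses[gen_best]
            best_chrom = population[gen_best].copy()
        traj_best.append(best_fit)
        finite = [f for f in fitnesses if np.isfinite(f)]
        traj_mean.append(float(np.mean(finite)) if finite else PENALTY)

    selected = [snp_ids[i] for i in np.flatnonzero(best_chrom)]
    return GAResult(
        best_chromosome=best_chrom.astype(np.int8),
        best_fitness=float(best_fit),
        trajectory_best=traj_best,
        trajectory_mean=traj_mean,
        selected_snp_ids=selected,
        evaluation_count=evaluator.evaluations,
        config=config,
    )
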