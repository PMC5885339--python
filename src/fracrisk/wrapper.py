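"""Genetic-algorithm wrapper around a soft-margin RBF-kernel classifier.

A chromosome carries a 20-bit feature mask and two real genes, ``alpha``
and ``gamma_exp``, both bounded in [-25, +25] and decoded as base-2
exponents: cost C = 2**alpha, kernel width gamma = 2**gamma_exp.  Fitness
is a cross-validated objective (OB1 or OB2) computed from the pooled
held-out predictions of a fixed stratified ten-fold plan, so fitnesses of
different chromosomes are directly comparable.  Each generation fully
replaces the population with n/2 crossover offspring and n/2 mutants of
tournament-selected parents; the best-so-far chromosome is archived outside
the population and defines the fitness trace and the final model.

Feature standardisation is learned on the training folds only and applied
to the held-out fold (no leakage); the final classifier is refitted on the
whole training set with the best decoded parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import CohortTable
from .metrics import MetricSet, confusion_metrics, objective_value

GENE_BOUND = 25.0  # |alpha|, |gamma_exp| <= 25


@dataclass
class Chromosome:
    mask: np.ndarray  # boolean, one gene per candidate feature
    alpha: float
    gamma_exp: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("chromosome mask must select at least one feature")
        if abs(self.alpha) > GENE_BOUND or abs(self.gamma_exp) > GENE_BOUND:
            raise ValueError(f"real genes must lie in [-{GENE_BOUND}, {GENE_BOUND}]")

    def key(self) -> tuple:
        return (self.mask.tobytes(), self.alpha, self.gamma_exp)


@dataclass
class GAParams:
    """Search limits and operator rates.

    Defaults mirror the published configuration: population 10, stop after
    500 generations without improvement or 100000 generations in total.
    """

    population_n: int = 10
    max_not_improved: int = 500
    max_iteration: int = 100_000
    mutation_bit_rate: float = 0.05
    mutation_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_n < 2 or self.population_n % 2:
            raise ValueError("population_n must be even and >= 2")
        if self.max_not_improved < 1 or self.max_iteration < 1:
            raise ValueError("iteration limits must be >= 1")


@dataclass
class TrainedModel:
    """A decoded, refitted classifier with its search provenance."""

    selected_features: list[str]
    alpha: float
    gamma_exp: float
    fitness: float
    classifier: SVC
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    validation_metrics: MetricSet
    fitness_trace: list[float]
    provenance: dict = field(default_factory=dict)

    @property
    def cost(self) -> float:
        return 2.0 ** self.alpha

    @property
    def kernel_gamma(self) -> float:
        return 2.0 ** self.gamma_exp


def decode_chromosome(chrom: Chromosome, feature_names: Sequence[str]
                      ) -> tuple[list[str], float, float]:
    """(selected feature names, cost C = 2**alpha, gamma = 2**gamma_exp)."""
    if len(chrom.mask) != len(feature_names):
        raise ValueError(
            f"mask length {len(chrom.mask)} != {len(feature_names)} features")
    subset = [name for name, bit in zip(feature_names, chrom.mask) if bit]
    return subset, 2.0 ** chrom.alpha, 2.0 ** chrom.gamma_exp


def make_fold_plan(labels: np.ndarray, n_folds: int = 10,
                   seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """A fixed stratified K-fold partition, reused for a whole GA run."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=seed % (2 ** 31))
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


SVC_MAX_ITER = 5_000  # bounds solver time at extreme cost values


def _fit_svc(x: np.ndarray, y: np.ndarray, cost: float, gamma: float) -> SVC:
    svc = SVC(C=cost, gamma=gamma, kernel="rbf", max_iter=SVC_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extreme C may hit the iteration cap
        svc.fit(x, y)
    return svc


def _scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0.0] = 1.0
    return (x - mean) / std, mean, std


def cv_fitness(chrom: Chromosome, train: CohortTable, objective: str,
               fold_plan: Sequence[tuple[np.ndarray, np.ndarray]]
               ) -> tuple[float, MetricSet]:
    """Cross-validated fitness: pool held-out predictions over all folds and
    score the pooled confusion/ranking with the objective."""
    subset, cost, gamma = decode_chromosome(chrom, train.feature_names)
    x = train.matrix(subset)
    y = train.labels
    pooled_y = np.empty(0, dtype=np.int64)
    pooled_pred = np.empty(0, dtype=np.int64)
    pooled_dec = np.empty(0, dtype=np.float64)
    for tr, va in fold_plan:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold is missing a class")
        xt, mean, std = _scale(x[tr])
        svc = _fit_svc(xt, y[tr], cost, gamma)
        dec = svc.decision_function((x[va] - mean) / std)
        pooled_y = np.concatenate([pooled_y, y[va]])
        pooled_pred = np.concatenate([pooled_pred, (dec > 0).astype(np.int64)])
        pooled_dec = np.concatenate([pooled_dec, dec])
    metrics = confusion_metrics(pooled_y, pooled_pred, scores=pooled_dec)
    return objective_value(metrics, objective), metrics


def random_chromosome(rng: np.random.Generator, n_features: int) -> Chromosome:
    mask = rng.random(n_features) < 0.5
    if not mask.any():
        mask[rng.integers(n_features)] = True
    alpha, gamma_exp = rng.uniform(-GENE_BOUND, GENE_BOUND, size=2)
    return Chromosome(mask=mask, alpha=float(alpha), gamma_exp=float(gamma_exp))


def _repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(len(mask))] = True
    return mask


def _tournament(fitnesses: Sequence[float], rng: np.random.Generator) -> int:
    a, b = rng.choice(len(fitnesses), size=2, replace=False)
    a, b = int(a), int(b)
    if fitnesses[a] > fitnesses[b]:
        return a
    if fitnesses[b] > fitnesses[a]:
        return b
    return min(a, b)


def _clip(v: float) -> float:
    return float(np.clip(v, -GENE_BOUND, GENE_BOUND))


def next_generation(population: Sequence[Chromosome],
                    fitnesses: Sequence[float], params: GAParams,
                    rng: np.random.Generator) -> list[Chromosome]:
    """Full replacement: n/2 crossover offspring + n/2 mutants, parents by
    binary tournament.  Crossover is uniform on mask bits and a random
    convex combination on each real gene; mutation flips bits at
    ``mutation_bit_rate`` and adds N(0, sigma) to real genes, clipped."""
    n = len(population)
    if n < 2 or n % 2:
        raise ValueError("population size must be even and >= 2")
    if len(fitnesses) != n:
        raise ValueError("one fitness per chromosome required")
    offspring: list[Chromosome] = []
    for _ in range(n // 2):
        pa = population[_tournament(fitnesses, rng)]
        pb = population[_tournament(fitnesses, rng)]
        take_a = rng.random(len(pa.mask)) < 0.5
        mask = _repair_mask(np.where(take_a, pa.mask, pb.mask), rng)
        ua, ug = rng.random(2)
        offspring.append(Chromosome(
            mask=mask,
            alpha=_clip(ua * pa.alpha + (1 - ua) * pb.alpha),
            gamma_exp=_clip(ug * pa.gamma_exp + (1 - ug) * pb.gamma_exp)))
    for _ in range(n // 2):
        p = population[_tournament(fitnesses, rng)]
        flips = rng.random(len(p.mask)) < params.mutation_bit_rate
        mask = _repair_mask(np.logical_xor(p.mask, flips), rng)
        da, dg = rng.normal(0.0, 1.0, size=2) * params.mutation_sigma
        offspring.append(Chromosome(
            mask=mask,
            alpha=_clip(p.alpha + da),
            gamma_exp=_clip(p.gamma_exp + dg)))
    return offspring


def ga_search(train: CohortTable, objective: str, params: GAParams,
              n_folds: int = 10,
              on_generation: Callable[[int, float, int], None] | None = None
              ) -> TrainedModel:
    """Run the wrapper search and return the refitted best model.

    Terminates when the generation count reaches ``max_iteration`` or the
    best fitness has not improved for ``max_not_improved`` generations.
    ``on_generation(generation, best_fitness, num_not_improved)`` is called
    after each generation (used by the CLI for progress logging).
    """
    n_major, n_minor = train.class_counts()
    if n_major == 0 or n_minor == 0:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(params.seed)
    fold_plan = make_fold_plan(train.labels, n_folds=n_folds, seed=params.seed)
    cache: dict[tuple, tuple[float, MetricSet]] = {}

    def evaluate(chrom: Chromosome) -> tuple[float, MetricSet]:
        key = chrom.key()
        if key not in cache:
            cache[key] = cv_fitness(chrom, train, objective, fold_plan)
        return cache[key]

    population = [random_chromosome(rng, len(train.feature_names))
                  for _ in range(params.population_n)]
    scored = [evaluate(c) for c in population]
    fitnesses = [s[0] for s in scored]
    best_i = int(np.argmax(fitnesses))
    best_chrom, (best_fit, best_metrics) = population[best_i], scored[best_i]
    trace = [best_fit]

    iteration = 0
    not_improved = 0
    while iteration < params.max_iteration and not_improved < params.max_not_improved:
        population = next_generation(population, fitnesses, params, rng)
        scored = [evaluate(c) for c in population]
        fitnesses = [s[0] for s in scored]
        gen_i = int(np.argmax(fitnesses))
        if fitnesses[gen_i] > best_fit:
            best_fit = fitnesses[gen_i]
            best_chrom = population[gen_i]
            best_metrics = scored[gen_i][1]
            not_improved = 0
        else:
            not_improved += 1
        iteration += 1
        trace.append(best_fit)
        if on_generation is not None:
            on_generation(iteration, best_fit, not_improved)

    subset, cost, gamma = decode_chromosome(best_chrom, train.feature_names)
    x = train.matrix(subset)
    xt, mean, std = _scale(x)
    classifier = _fit_svc(xt, train.labels, cost, gamma)
    return TrainedModel(
        selected_features=subset, alpha=best_chrom.alpha,
        gamma_exp=best_chrom.gamma_exp, fitness=best_fit,
        classifier=classifier, scaler_mean=mean, scaler_std=std,
        validation_metrics=best_metrics, fitness_trace=trace,
        provenance={"objective": objective.upper(), "seed": params.seed,
                    "generations": iteration, "n_folds": n_folds,
                    "params": params})


def predict_scores(model: TrainedModel, table: CohortTable
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Binary predictions and continuous decision values for a table.

    Predictions threshold the decision values at 0; the decision values are
    the signed margins, usable directly by :func:`fracrisk.metrics.auc_score`.
    """
    x = table.matrix(model.selected_features)
    dec = model.classifier.decision_function(
        (x - model.scaler_mean) / model.scaler_std)
    return (dec > 0).astype(np.int64), dec
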