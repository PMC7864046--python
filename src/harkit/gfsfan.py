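"""Two-stage genetic feature selection with a fixed activation number.

Stage one is a filter: features are ranked by Fisher Index and given
selection probabilities (SP) decreasing arithmetically from P1 = 0.8
(best rank) to P2 = 0.4 (worst rank).  Stage two is a wrapper genetic
algorithm over binary masks constrained to exactly ``ninit`` active
bits:

* individuals are initialized by weighted sampling without replacement
  (Efraimidis–Spirakis keys w_i = u_i^(1/SP_i), top-``ninit`` kept);
* fitness wraps LDA and Gaussian naive Bayes under stratified 10-fold
  cross-validation, averaged over the resampled data groups:
  f = exp(FM_all) + alpha * exp(FM_min), alpha = 0.1, so mean per-class
  F-measure dominates and the worst class breaks ties;
* crossover (COFAN) passes the parents' shared active indices to both
  children and two-point-crosses the disjoint remainders as index
  lists; mutation (MOFAN) deactivates each active bit with the mutation
  probability and re-activates the same number of random inactive bits
  — both preserve the activation count exactly;
* crossover/mutation probabilities adapt to fitness between a
  protective lower bound for the fittest and an exploratory upper
  bound for below-average individuals;
* tournament selection, crowding replacement (an offspring replaces
  the most similar of a small random cohort only if fitter) and
  single-elite preservation guard against premature convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import GaussianNB, LDA
from .evaluation import cross_validated_fm, f_measure, stratified_folds
from .features import FeatureTable
from .resampling import ResampledEnsemble
from .separability import fisher_index

__all__ = [
    "GAConfig",
    "Individual",
    "GFSFANResult",
    "selection_probabilities",
    "init_individual",
    "WrapperFitness",
    "fitness_from_fm",
    "adaptive_probability",
    "cofan",
    "mofan",
    "run_gfsfan",
]


def fitness_from_fm(fm_all: float, fm_min: float, alpha: float = 0.1) -> float:
    """GA fitness: exp(FM_all) + alpha * exp(FM_min)."""
    return float(np.exp(fm_all) + alpha * np.exp(fm_min))


@dataclass
class GAConfig:
    ninit: int
    population: int = 80
    max_iterations: int = 100
    p_select_max: float = 0.8  # SP of the top-ranked feature
    p_select_min: float = 0.4  # SP of the bottom-ranked feature
    crossover_range: tuple[float, float] = (0.4, 0.8)
    mutation_range: tuple[float, float] = (0.1, 0.4)
    alpha: float = 0.1
    tournament_size: int = 2
    crowding_cohort: int = 4
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ninit <= 0:
            raise ValueError("ninit must be positive")
        if self.p_select_min > self.p_select_max:
            raise ValueError("selection probabilities must satisfy P2 <= P1")


@dataclass
class Individual:
    mask: np.ndarray
    fitness: float | None = None
    fm_all: float | None = None
    fm_min: float | None = None

    def active(self) -> np.ndarray:
        return np.nonzero(self.mask)[0]

    @property
    def popcount(self) -> int:
        return int(self.mask.sum())


@dataclass
class GFSFANResult:
    selected: list[str]
    mask: np.ndarray
    fitness: float
    fm_all: float
    fm_min: float
    history_best: list[float]
    history_mean: list[float]
    config: GAConfig


def selection_probabilities(
    n_ranked: int, p_max: float = 0.8, p_min: float = 0.4
) -> np.ndarray:
    """SP by rank (0 = best): arithmetic sequence from p_max down to p_min."""
    if n_ranked < 1:
        raise ValueError("need at least one feature")
    if n_ranked == 1:
        return np.array([p_max])
    r = np.arange(n_ranked)
    return p_max - (p_max - p_min) * r / (n_ranked - 1)


def init_individual(
    sp: np.ndarray, ninit: int, rng: np.random.Generator
) -> Individual:
    """Weighted sampling without replacement via exponentiated keys."""
    m = len(sp)
    if ninit > m:
        raise ValueError("ninit exceeds the number of features")
    u = rng.random(m)
    w = u ** (1.0 / np.asarray(sp))
    chosen = np.argsort(-w, kind="stable")[:ninit]
    mask = np.zeros(m, dtype=bool)
    mask[chosen] = True
    return Individual(mask=mask)


class WrapperFitness:
    """Cached wrapper-classifier fitness over resampled data groups.

    Fold assignments are drawn once per group and shared by every mask,
    so individuals are compared on identical splits.
    """

    def __init__(
        self,
        groups: list[FeatureTable],
        n_folds: int = 10,
        alpha: float = 0.1,
        seed: int = 0,
        wrappers: tuple[str, ...] = ("lda", "nb"),
    ):
        self.alpha = alpha
        self._wrappers = wrappers
        self._data = []
        for g, table in enumerate(groups):
            X = table.X.to_numpy(dtype=float)
            y = np.asarray(table.labels)
            folds = stratified_folds(y, n_folds, seed=seed + g)
            self._data.append((X, y, folds, np.unique(y)))
        self.feature_names = groups[0].feature_names
        self._cache: dict[bytes, tuple[float, float, float]] = {}
        self.evaluations = 0

    def _make(self, name: str):
        return LDA() if name == "lda" else GaussianNB()

    def __call__(self, mask: np.ndarray) -> tuple[float, float, float]:
        """Returns (fitness, fm_all, fm_min) for a feature mask."""
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if mask.sum() == 0:
            raise ValueError("mask selects no features")
        cols = np.nonzero(mask)[0]
        fm_alls, fm_mins = [], []
        for X, y, folds, classes in self._data:
            Xs = X[:, cols]
            per_class = []
            for w in self._wrappers:
                cm, _ = cross_validated_fm(Xs, y, self._make(w), folds, classes)
                fm, _, _, _, _ = f_measure(cm)
                per_class.append(fm)
            fm_avg = np.mean(per_class, axis=0)  # average the wrappers per class
            fm_alls.append(fm_avg.mean())
            fm_mins.append(fm_avg.min())
        fm_all = float(np.mean(fm_alls))
        fm_min = float(np.mean(fm_mins))
        f = fitness_from_fm(fm_all, fm_min, self.alpha)
        self._cache[key] = (f, fm_all, fm_min)
        self.evaluations += 1
        return f, fm_all, fm_min


def adaptive_probability(
    f: float, f_mean: float, f_max: float, prange: tuple[float, float]
) -> float:
    """Fitness-adaptive operator probability.

    ``prange = (p1, p2)``: the fittest individual gets the protective
    p1, below-average individuals the exploratory p2, with linear
    interpolation in between.  A degenerate population (f_max == f_mean)
    gets p1 for at/above-average fitness.
    """
    p1, p2 = prange
    if f < f_mean:
        return p2
    if f_max <= f_mean:
        return p1
    return p1 + (p2 - p1) * (f_max - f) / (f_max - f_mean)


def cofan(
    parent1: Individual, parent2: Individual, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Fixed-cardinality two-point crossover on active-index lists."""
    a1, a2 = parent1.active(), parent2.active()
    if len(a1) != len(a2):
        raise ValueError("parents must share the activation number")
    shared = np.intersect1d(a1, a2)
    h1 = np.setdiff1d(a1, shared)
    h2 = np.setdiff1d(a2, shared)
    d = len(h1)
    m = len(parent1.mask)
    if d == 0:
        return Individual(parent1.mask.copy()), Individual(parent2.mask.copy())
    lo, hi = np.sort(rng.integers(0, d + 1, size=2))
    c1 = np.concatenate([shared, h1[:lo], h2[lo:hi], h1[hi:]])
    c2 = np.concatenate([shared, h2[:lo], h1[lo:hi], h2[hi:]])
    out = []
    for idx in (c1, c2):
        mask = np.zeros(m, dtype=bool)
        mask[idx.astype(int)] = True
        out.append(Individual(mask=mask))
    return out[0], out[1]


def mofan(
    parent: Individual, p_mut: float, rng: np.random.Generator
) -> Individual:
    """Fixed-cardinality mutation: migrate bits, never change the count."""
    active = parent.active()
    inactive = np.nonzero(~parent.mask)[0]
    leave = active[rng.random(len(active)) < p_mut]
    m = min(len(leave), len(inactive))
    mask = parent.mask.copy()
    if m > 0:
        enter = rng.choice(inactive, size=m, replace=False)
        mask[leave[:m]] = False
        mask[enter] = True
    return Individual(mask=mask)


def _tournament(
    pop: list[Individual], size: int, rng: np.random.Generator
) -> Individual:
    picks = rng.integers(0, len(pop), size=size)
    return max((pop[i] for i in picks), key=lambda ind: ind.fitness)


def run_gfsfan(
    table: FeatureTable,
    config: GAConfig,
    ensemble: ResampledEnsemble | None = None,
) -> GFSFANResult:
    """Run the full two-stage selection.

    Fisher-Index selection probabilities are computed on ``table``;
    fitness is evaluated on the resampled ``ensemble`` groups when
    given, otherwise directly on ``table``.
    """
    m = table.n_features
    if config.ninit > m:
        raise ValueError("ninit exceeds the number of features")
    rng = np.random.default_rng(config.seed)
    groups = ensemble.groups if ensemble is not None else [table]
    evaluate = WrapperFitness(
        groups, n_folds=config.n_folds, alpha=config.alpha, seed=config.seed
    )

    report = fisher_index(table)
    sp_by_rank = selection_probabilities(m, config.p_select_max, config.p_select_min)
    sp = np.empty(m)
    sp[report.ranking] = sp_by_rank

    def score(ind: Individual) -> Individual:
        ind.fitness, ind.fm_all, ind.fm_min = evaluate(ind.mask)
        return ind

    if config.ninit == m:  # single-point search space
        ind = score(Individual(mask=np.ones(m, dtype=bool)))
        return GFSFANResult(
            selected=list(table.feature_names),
            mask=ind.mask,
            fitness=ind.fitness,
            fm_all=ind.fm_all,
            fm_min=ind.fm_min,
            history_best=[ind.fitness],
            history_mean=[ind.fitness],
            config=config,
        )

    pop = [
        score(init_individual(sp, config.ninit, rng))
        for _ in range(config.population)
    ]
    history_best: list[float] = []
    history_mean: list[float] = []

    for _ in range(config.max_iterations):
        fvals = np.array([ind.fitness for ind in pop])
        f_max, f_mean = float(fvals.max()), float(fvals.mean())
        history_best.append(f_max)
        history_mean.append(f_mean)
        elite_idx = int(np.argmax(fvals))

        offspring: list[Individual] = []
        while len(offspring) < config.population:
            p1 = _tournament(pop, config.tournament_size, rng)
            p2 = _tournament(pop, config.tournament_size, rng)
            f_pair = max(p1.fitness, p2.fitness)
            pc = adaptive_probability(f_pair, f_mean, f_max, config.crossover_range)
            if rng.random() < pc:
                c1, c2 = cofan(p1, p2, rng)
            else:
                c1, c2 = Individual(p1.mask.copy()), Individual(p2.mask.copy())
            pm = adaptive_probability(f_pair, f_mean, f_max, config.mutation_range)
            for child in (c1, c2):
                child = mofan(child, pm, rng)
                assert child.popcount == config.ninit
                offspring.append(score(child))

        # crowding replacement with single-elite protection
        for child in offspring[: config.population]:
            cohort = rng.integers(0, len(pop), size=config.crowding_cohort)
            cohort = [i for i in cohort if i != elite_idx] or [
                int(rng.integers(0, len(pop)))
            ]
            sims = [np.sum(pop[i].mask & child.mask) for i in cohort]
            target = cohort[int(np.argmax(sims))]
            if child.fitness > pop[target].fitness:
                pop[target] = child
        elite_idx = int(np.argmax([ind.fitness for ind in pop]))

    fvals = np.array([ind.fitness for ind in pop])
    history_best.append(float(fvals.max()))
    history_mean.append(float(fvals.mean()))
    best = pop[int(np.argmax(fvals))]
    names = [table.feature_names[i] for i in best.active()]
    return GFSFANResult(
        selected=names,
        mask=best.mask,
        fitness=best.fitness,
        fm_all=best.fm_all,
        fm_min=best.fm_min,
        history_best=history_best,
        history_mean=history_mean,
        config=config,
    )
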