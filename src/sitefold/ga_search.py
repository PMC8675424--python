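"""Multi-objective genetic-algorithm search over binary feature masks.

Individuals are feature subsets (binary masks over the canonical feature
order).  Fitness is the leave-one-site-out mean AUC of a cheap fixed-strength
ridge logistic classifier restricted to the masked columns, so the search
pressure is toward *site-generalizable* signal, not toward site fingerprints.

Selection and survival are multi-objective in the age-fitness Pareto style:
dominance considers (higher fitness, smaller subset, younger age), random
newcomers are injected each generation with age zero, and survival fills the
next population front by front (NSGA-style nondominated sorting).  Several
isolated populations ("islands") evolve independently and are merged only at
output time; the final result is the top-K unique masks ever evaluated,
ranked by (fitness desc, size asc, lexicographic mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from . import classifiers, cv_engine
from .data_model import MultiSiteDataset, site_composition


@dataclass(eq=False)
class FeatureSubset:
    """A GA individual: a binary inclusion mask with cached fitness."""

    mask: np.ndarray  # bool vector over canonical feature order
    fitness: float | None = None
    age: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        self._size = int(self.mask.sum())

    @property
    def size(self) -> int:
        return self._size

    @property
    def key(self) -> bytes:
        return np.packbits(self.mask).tobytes()


def default_ga_classifier() -> classifiers.ClassifierSpec:
    """Fixed-strength ridge used inside the GA: quick to train, and the
    exploratory stage shows classifier choice barely moves performance."""
    return classifiers.ClassifierSpec(family="ridge_logistic", fixed_params={"C": 1.0})


@dataclass
class GAConfig:
    population_size: int = 100
    n_generations: int = 100
    tournament_size: int = 2
    mutation_rate: float | None = None  # default 2 / n_features
    crossover_rate: float = 0.5
    n_islands: int = 3
    k_top: int = 200
    init_prob: float = 0.1
    n_newcomers: int = 1
    clf: classifiers.ClassifierSpec = field(default_factory=default_ga_classifier)
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.mutation_rate is not None and not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in (0, 1)")
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")


@dataclass
class SearchVariantResult:
    variant_id: str
    subsets: list[FeatureSubset]  # top-k_top unique, ranked
    config: GAConfig
    n_evaluations: int  # fitness evaluations actually computed
    n_requests: int = 0  # including cache hits
    feature_names: list[str] = field(default_factory=list)


class FitnessCache:
    """Memoizes fitness by (dataset fingerprint, mask)."""

    def __init__(self, fingerprint: str):
        self.fingerprint = fingerprint
        self._table: dict[bytes, float] = {}
        self._evaluators: dict[tuple, object] = {}  # keyed by (fold_sites, C)
        self.hits = 0
        self.misses = 0

    def get(self, key: bytes):
        val = self._table.get(key)
        if val is not None:
            self.hits += 1
        return val

    def put(self, key: bytes, value: float):
        self.misses += 1
        self._table[key] = value

    def items(self):
        return self._table.items()


def ridge_logistic_newton(
    Z: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, float]:
    """Damped-Newton minimizer of the L2-penalized logistic loss.

    Minimizes ``sum_i log(1 + exp(-t_i * (Z_i w + b))) + ||w||^2 / (2C)``
    with an unpenalized intercept — the same objective sklearn's
    ``LogisticRegression(penalty="l2", C=C)`` solves.  Used in the GA fitness
    inner loop where millions of tiny fits make per-call overhead matter;
    agreement with the library solver is asserted in the test suite.
    """
    n, p = Z.shape
    t = 2.0 * y - 1.0
    w = np.zeros(p)
    b = 0.0
    lam = 1.0 / C
    for _ in range(max_iter):
        eta = Z @ w + b
        mu = 1.0 / (1.0 + np.exp(-eta))  # P(y=1)
        g_w = Z.T @ (mu - y) + lam * w
        g_b = float(np.sum(mu - y))
        if max(np.abs(g_w).max(initial=0.0), abs(g_b)) < tol * n:
            break
        s = np.clip(mu * (1 - mu), 1e-10, None)
        Zs = Z * s[:, None]
        H = np.empty((p + 1, p + 1))
        H[:p, :p] = Z.T @ Zs
        H[:p, :p][np.diag_indices(p)] += lam
        H[:p, p] = H[p, :p] = Zs.sum(axis=0)
        H[p, p] = s.sum()
        try:
            step = np.linalg.solve(H, np.concatenate([g_w, [g_b]]))
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, np.concatenate([g_w, [g_b]]), rcond=None)[0]
        # backtracking keeps the objective from diverging on separable folds
        obj0 = np.logaddexp(0.0, -t * eta).sum() + 0.5 * lam * (w @ w)
        alpha = 1.0
        for _ in range(20):
            w_new = w - alpha * step[:p]
            b_new = b - alpha * step[p]
            eta_new = Z @ w_new + b_new
            obj = np.logaddexp(0.0, -t * eta_new).sum() + 0.5 * lam * (w_new @ w_new)
            if obj <= obj0 + 1e-12:
                break
            alpha *= 0.5
        w, b = w_new, b_new
    return w, b


def _fast_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks; equals ``cv_engine.compute_auc`` but
    skips per-call validation (this sits in the GA's innermost loop)."""
    pos = labels == 1
    m = int(pos.sum())
    n = labels.size - m
    ranks = cv_engine._midrank(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


class _LosoRidgeEvaluator:
    """Fast leave-site-out evaluator for the fixed-strength ridge.

    Per fold the full-width standardization (training-row statistics) is
    precomputed once; a mask then just selects columns of the standardized
    matrices, which is identical to standardizing the masked columns.
    """

    def __init__(self, ds: MultiSiteDataset, fold_sites, C: float = 1.0):
        self.C = float(C)
        self.folds = []
        site = np.asarray(ds.site)
        for s in fold_sites:
            held = site == s
            if not held.any():
                raise ValueError(f"fold site {s!r} absent from dataset")
            if len(np.unique(ds.y[held])) < 2:
                raise ValueError(f"fold site {s!r} lacks one of the classes")
            Xtr = ds.X[~held]
            mean = Xtr.mean(axis=0)
            scale = Xtr.std(axis=0)
            scale[scale == 0] = 1.0
            self.folds.append(
                (
                    (Xtr - mean) / scale,
                    ds.y[~held].astype(float),
                    (ds.X[held] - mean) / scale,
                    ds.y[held],
                )
            )

    def __call__(self, mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        aucs = []
        for Ztr, ytr, Zte, yte in self.folds:
            w, b = ridge_logistic_newton(Ztr[:, idx], ytr, C=self.C)
            aucs.append(_fast_auc(Zte[:, idx] @ w + b, yte))
        return float(np.mean(aucs))


def evaluate_fitness(
    mask,
    ds: MultiSiteDataset,
    fold_sites,
    clf: classifiers.ClassifierSpec | None = None,
    cache: FitnessCache | None = None,
) -> float:
    """LOSO mean AUC of the classifier restricted to the masked columns."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot evaluate an empty feature mask")
    clf = clf or default_ga_classifier()
    key = np.packbits(mask).tobytes()
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    if clf.family == "ridge_logistic" and clf.fixed_params is not None:
        C = clf.fixed_params.get("C", 1.0)
        if cache is not None:
            # fold standardization depends only on (dataset, fold set), so the
            # evaluator is built once per cache and reused for every mask
            ev_key = (tuple(fold_sites), C)
            evaluator = cache._evaluators.get(ev_key)
            if evaluator is None:
                evaluator = _LosoRidgeEvaluator(ds, fold_sites, C=C)
                cache._evaluators[ev_key] = evaluator
        else:
            evaluator = _LosoRidgeEvaluator(ds, fold_sites, C=C)
        value = evaluator(mask)
    else:
        value = cv_engine.leave_site_out_cv(ds, clf, fold_sites, feature_mask=mask).mean
    if cache is not None:
        cache.put(key, value)
    return value


def _rank_key(ind: FeatureSubset):
    return (-ind.fitness, ind.size, ind.age)


def tournament_select(
    population: list[FeatureSubset], t: int, rng: np.random.Generator
) -> FeatureSubset:
    """Draw ``t`` individuals with replacement; keep the best.

    "Best" is lexicographic: higher fitness first, then smaller subset,
    then younger — the same ordering used to layer Pareto fronts.
    """
    if not population:
        raise ValueError("population is empty")
    idx = rng.integers(0, len(population), size=max(1, t))
    picked = [population[i] for i in idx]
    return min(picked, key=_rank_key)


def mutate_mask(mask: np.ndarray, m: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``m``; an all-zero result
    is repaired by setting one uniformly chosen bit."""
    mask = np.asarray(mask, bool)
    flips = rng.random(mask.size) < m
    out = mask ^ flips
    if not out.any():
        out = out.copy()
        out[rng.integers(0, out.size)] = True
    return out


def uniform_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Child takes each bit from either parent with probability 1/2."""
    take_a = rng.random(a.size) < 0.5
    return np.where(take_a, a, b)


def _nondominated_sort(pop: list[FeatureSubset]) -> list[list[FeatureSubset]]:
    # vectorized pairwise dominance on (fitness max, size min, age min)
    n = len(pop)
    fit = np.array([p.fitness for p in pop])
    size = np.array([p.size for p in pop])
    age = np.array([p.age for p in pop])
    ge = (
        (fit[:, None] >= fit[None, :])
        & (size[:, None] <= size[None, :])
        & (age[:, None] <= age[None, :])
    )
    gt = (
        (fit[:, None] > fit[None, :])
        | (size[:, None] < size[None, :])
        | (age[:, None] < age[None, :])
    )
    dom = ge & gt  # dom[i, j]: i dominates j
    fronts: list[list[FeatureSubset]] = []
    alive = np.ones(n, bool)
    while alive.any():
        idx = np.flatnonzero(alive)
        sub = dom[np.ix_(idx, idx)]
        front = idx[sub.sum(axis=0) == 0]
        fronts.append([pop[i] for i in front])
        alive[front] = False
    return fronts


def _survival_select(pool: list[FeatureSubset], size: int) -> list[FeatureSubset]:
    chosen: list[FeatureSubset] = []
    for front in _nondominated_sort(pool):
        front = sorted(front, key=_rank_key)
        room = size - len(chosen)
        if room <= 0:
            break
        chosen.extend(front[:room])
    return chosen


def _random_mask(p: int, init_prob: float, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(p) < init_prob
    if not mask.any():
        mask[rng.integers(0, p)] = True
    return mask


def run_ga_variant(
    ds: MultiSiteDataset,
    config: GAConfig,
    fold_sites: list[str] | None = None,
    variant_id: str = "variant",
    min_per_class: int = 5,
) -> SearchVariantResult:
    """Run one full GA search variant and return its top-k unique subsets.

    ``n_islands`` isolated populations evolve for ``n_generations`` each
    (init -> evaluate -> tournament parents -> crossover/mutate -> newcomer
    injection -> Pareto survival); every evaluated mask is archived via the
    shared memoizing cache, and the archive — merged across islands — yields
    the ranked top ``k_top``.  Fully reproducible for a given seed.
    """
    if fold_sites is None:
        fold_sites = site_composition(ds, min_per_class=min_per_class).fold_sites
    if len(fold_sites) < 2:
        raise ValueError("GA fitness needs at least 2 balanced fold sites")
    p = ds.n_features
    m = config.mutation_rate if config.mutation_rate is not None else 2.0 / p
    cache = FitnessCache(ds.fingerprint())
    n_requests = 0

    def evaluated(mask: np.ndarray, age: int) -> FeatureSubset:
        nonlocal n_requests
        n_requests += 1
        fit = evaluate_fitness(mask, ds, fold_sites, config.clf, cache=cache)
        return FeatureSubset(mask=mask, fitness=fit, age=age)

    for island in range(config.n_islands):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 0x6A, island])
        )
        pop = [
            evaluated(_random_mask(p, config.init_prob, rng), 0)
            for _ in range(config.population_size)
        ]
        for _ in range(config.n_generations):
            offspring = []
            n_children = config.population_size - config.n_newcomers
            for _ in range(n_children):
                parent1 = tournament_select(pop, config.tournament_size, rng)
                lineage_age = parent1.age
                if rng.random() < config.crossover_rate:
                    parent2 = tournament_select(pop, config.tournament_size, rng)
                    child = uniform_crossover(parent1.mask, parent2.mask, rng)
                    lineage_age = max(lineage_age, parent2.age)
                else:
                    child = parent1.mask
                child = mutate_mask(child, m, rng)
                # offspring inherit the lineage age; only newcomers reset it
                offspring.append(evaluated(child, lineage_age))
            newcomers = [
                evaluated(_random_mask(p, config.init_prob, rng), 0)
                for _ in range(config.n_newcomers)
            ]
            for ind in pop + offspring:
                ind.age += 1
            pop = _survival_select(pop + offspring + newcomers, config.population_size)

    ranked = sorted(
        (
            FeatureSubset(mask=np.unpackbits(np.frombuffer(key, np.uint8))[:p].astype(bool), fitness=fit)
            for key, fit in cache.items()
        ),
        key=lambda s: (-s.fitness, s.size, tuple(s.mask.astype(int))),
    )
    return SearchVariantResult(
        variant_id=variant_id,
        subsets=ranked[: config.k_top],
        config=config,
        n_evaluations=cache.misses,
        n_requests=n_requests,
        feature_names=list(ds.feature_names),
    )


def compact_preset(
    population_size: int = 60,
    n_generations: int = 40,
    n_islands: int = 3,
    seed: int = 0,
    k_top: int = 200,
    clf: classifiers.ClassifierSpec | None = None,
    init_probs: tuple[float, ...] = (0.05, 0.1, 0.2),
) -> list[GAConfig]:
    """Small preset of search variants differing in initialization density.

    Initialization density is the sparsity-pressure knob: sparser starts
    push the Pareto front toward smaller subsets.  Averaging importances
    over even a couple of variants washes out per-run hitchhiker features
    that a single search can entrench, so this preset is the recommended
    desk-scale alternative to the full six-variant grid.
    """
    return [
        GAConfig(
            population_size=population_size,
            n_generations=n_generations,
            n_islands=n_islands,
            init_prob=ip,
            k_top=k_top,
            clf=clf or default_ga_classifier(),
            seed=(seed * 10 + i) % 2**31,
        )
        for i, ip in enumerate(init_probs)
    ]


def six_variant_preset(
    population_size: int = 100,
    n_generations: int = 100,
    seed: int = 0,
    clf: classifiers.ClassifierSpec | None = None,
    k_top: int = 200,
    n_islands: int = 3,
) -> list[GAConfig]:
    """Six named search variants: {small, large} x {population, generations,
    sparsity pressure} — a grid over search size, scope and objective
    weighting.  Sparsity pressure is varied through the initialization
    density (sparser starts bias the Pareto front toward smaller subsets).
    """
    base = dict(
        k_top=k_top,
        n_islands=n_islands,
        clf=clf or default_ga_classifier(),
    )
    small_p, large_p = max(2, population_size // 2), population_size
    small_g, large_g = max(1, n_generations // 2), n_generations
    grid = [
        ("v1_small_pop", dict(population_size=small_p, n_generations=large_g, init_prob=0.1)),
        ("v2_large_pop", dict(population_size=large_p, n_generations=large_g, init_prob=0.1)),
        ("v3_short", dict(population_size=large_p, n_generations=small_g, init_prob=0.1)),
        ("v4_long_sparse", dict(population_size=large_p, n_generations=large_g, init_prob=0.05)),
        ("v5_small_sparse", dict(population_size=small_p, n_generations=large_g, init_prob=0.05)),
        ("v6_dense", dict(population_size=large_p, n_generations=large_g, init_prob=0.2)),
    ]
    configs = []
    for i, (_, kw) in enumerate(grid):
        configs.append(GAConfig(seed=seed + i, **base, **kw))
    return configs
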