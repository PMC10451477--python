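"""Metaheuristic wrapper selection of column subsets, plus the Friedman test.

Both selectors pick a fixed-size subset of candidate columns of a
(samples x candidates) matrix by minimizing a fitness function — by default
the training mean-square error of a softmax discriminant classifier mapped
onto the class-target scale.  Candidates may be spectral features (the usual
axis) or, transposed, subject columns; :func:`select_subjects_per_class`
applies the latter with the per-class defaults of 30 Adeno / 6 Meso.

Particle swarm optimization uses binary particles: one bit per candidate,
velocities squashed through a logistic into bit probabilities, then repaired
to exactly ``subset_size`` set bits (highest probability wins, ties to the
lowest index).  Harmony search improvises new subsets slot-wise from a
harmony memory with memory-consideration rate HMCR and pitch-adjustment
rate PAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .classifiers import Standardizer, TargetMap, make_classifier
from .errors import InvalidConfigError

Fitness = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    subset_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise InvalidConfigError("swarm_size must be >= 2")
        if self.subset_size < 1:
            raise InvalidConfigError("subset_size must be >= 1")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise InvalidConfigError("inertia, cognitive and social weights must be > 0")
        if self.iterations < 0:
            raise InvalidConfigError("iterations must be >= 0")


@dataclass(frozen=True)
class HSConfig:
    memory_size: int = 20
    iterations: int = 200
    hmcr: float = 0.9
    par: float = 0.3
    subset_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.memory_size < 2:
            raise InvalidConfigError("memory_size must be >= 2")
        if not (0 < self.hmcr < 1) or not (0 < self.par < 1):
            raise InvalidConfigError("HMCR and PAR must lie in (0, 1)")
        if self.subset_size < 1:
            raise InvalidConfigError("subset_size must be >= 1")
        if self.iterations < 0:
            raise InvalidConfigError("iterations must be >= 0")


@dataclass
class SelectionResult:
    selected_indices: np.ndarray
    best_fitness: float
    fitness_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_indices = np.sort(np.asarray(self.selected_indices, dtype=int))
        if len(np.unique(self.selected_indices)) != len(self.selected_indices):
            raise InvalidConfigError("selected indices must be unique")


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    k: int
    n: int
    rank_sums: np.ndarray


def make_fitness(
    features: np.ndarray,
    labels: np.ndarray,
    targets: TargetMap | None = None,
    classifier: str = "sdc",
    standardize: bool = True,
    **classifier_params,
) -> Fitness:
    """Build the default wrapper fitness: training MSE of a base learner.

    ``features`` is (n_samples, n_candidates); a subset indexes candidate
    columns.  The learner is refit per evaluation; observed values are its
    outputs on the class-target scale and the MSE follows the standard
    (1/N)·Σ(O−T)² definition.
    """
    features = np.asarray(features, dtype=float)
    targets = targets or TargetMap()
    labels = np.asarray(labels, dtype=object)
    if classifier == "sdc":
        classifier_params.setdefault("epochs", 100)

    t_true = targets.target_vector(labels)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(subset: np.ndarray) -> float:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise InvalidConfigError("subset must be non-empty")
        key = tuple(sorted(int(i) for i in subset))
        if key in cache:
            return cache[key]
        X = features[:, subset]
        if standardize:
            X = Standardizer().fit_transform(X)
        clf = make_classifier(classifier, targets=targets, **classifier_params)
        clf.fit(X, labels)
        observed = clf.observed_targets(X)
        value = float(np.mean((observed - t_true) ** 2))
        cache[key] = value
        return value

    return fitness


def fitness_mse(
    subset: Sequence[int],
    features: np.ndarray,
    labels: np.ndarray,
    targets: TargetMap | None = None,
    **kwargs,
) -> float:
    """Training MSE of the base learner restricted to ``subset`` columns."""
    features = np.asarray(features, dtype=float)
    subset = np.asarray(subset, dtype=int)
    if np.any(subset < 0) or np.any(subset >= features.shape[1]):
        raise IndexError(
            f"subset indices out of range for {features.shape[1]} candidates"
        )
    return make_fitness(features, labels, targets=targets, **kwargs)(subset)


def _repair_bits(bits: np.ndarray, prob: np.ndarray, k: int) -> np.ndarray:
    """Force exactly k set bits, keeping/adding the highest-probability ones.

    Ties break to the lowest index for determinism.
    """
    bits = bits.astype(bool).copy()
    n_set = int(bits.sum())
    if n_set > k:
        on = np.flatnonzero(bits)
        drop = on[np.argsort(prob[on], kind="stable")[: n_set - k]]
        bits[drop] = False
    elif n_set < k:
        off = np.flatnonzero(~bits)
        add = off[np.argsort(-prob[off], kind="stable")[: k - n_set]]
        bits[add] = True
    return bits.astype(float)


def pso_select(
    features: np.ndarray,
    labels: np.ndarray,
    config: PSOConfig,
    fitness: Fitness | None = None,
) -> SelectionResult:
    """Binary PSO over candidate columns; returns the best-ever subset."""
    features = np.asarray(features, dtype=float)
    n = features.shape[1]
    if config.subset_size > n:
        raise InvalidConfigError(
            f"subset_size {config.subset_size} exceeds {n} candidates"
        )
    fitness = fitness or make_fitness(features, labels)
    rng = np.random.default_rng(config.seed)

    swarm = np.zeros((config.swarm_size, n))
    velocity = rng.uniform(-1.0, 1.0, size=(config.swarm_size, n))
    for p in range(config.swarm_size):
        swarm[p, rng.choice(n, size=config.subset_size, replace=False)] = 1.0

    def subset_of(bits: np.ndarray) -> np.ndarray:
        return np.flatnonzero(bits > 0.5)

    pbest = swarm.copy()
    pbest_fit = np.array([fitness(subset_of(x)) for x in swarm])
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    trace = [gbest_fit]

    for _ in range(config.iterations):
        r1 = rng.random((config.swarm_size, n))
        r2 = rng.random((config.swarm_size, n))
        velocity = (
            config.inertia * velocity
            + config.cognitive * r1 * (pbest - swarm)
            + config.social * r2 * (gbest - swarm)
        )
        prob = 1.0 / (1.0 + np.exp(-np.clip(velocity, -10, 10)))
        sampled = (rng.random((config.swarm_size, n)) < prob).astype(float)
        for p in range(config.swarm_size):
            bits = _repair_bits(sampled[p], prob[p], config.subset_size)
            swarm[p] = bits
            fit = fitness(subset_of(bits))
            if fit < pbest_fit[p]:
                pbest[p], pbest_fit[p] = bits.copy(), fit
                if fit < gbest_fit:
                    gbest, gbest_fit = bits.copy(), float(fit)
        trace.append(gbest_fit)

    return SelectionResult(subset_of(gbest), gbest_fit, trace)


def hs_select(
    features: np.ndarray,
    labels: np.ndarray,
    config: HSConfig,
    fitness: Fitness | None = None,
) -> SelectionResult:
    """Harmony-search improvisation over candidate columns."""
    features = np.asarray(features, dtype=float)
    n = features.shape[1]
    k = config.subset_size
    if k > n:
        raise InvalidConfigError(f"subset_size {k} exceeds {n} candidates")
    fitness = fitness or make_fitness(features, labels)
    rng = np.random.default_rng(config.seed)

    memory = [
        np.sort(rng.choice(n, size=k, replace=False)) for _ in range(config.memory_size)
    ]
    mem_fit = np.array([fitness(m) for m in memory])
    best_i = int(np.argmin(mem_fit))
    best, best_fit = memory[best_i].copy(), float(mem_fit[best_i])
    trace = [best_fit]
    memory_support = np.unique(np.concatenate(memory))

    for _ in range(config.iterations):
        new = np.empty(k, dtype=int)
        for slot in range(k):
            if rng.random() < config.hmcr:
                value = int(memory[rng.integers(config.memory_size)][slot])
                if rng.random() < config.par:
                    value = int(np.clip(value + rng.choice([-1, 1]), 0, n - 1))
            else:
                value = int(rng.integers(n))
            new[slot] = value
        # repair duplicates: prefer unused values from the memory support
        used = set()
        for slot in range(k):
            if new[slot] in used:
                pool = [v for v in memory_support if v not in used and v not in new[slot + 1 :]]
                if not pool:
                    pool = [v for v in range(n) if v not in used and v not in new[slot + 1 :]]
                new[slot] = int(pool[int(rng.integers(len(pool)))])
            used.add(int(new[slot]))
        new = np.sort(new)
        fit = fitness(new)
        worst = int(np.argmax(mem_fit))
        if fit < mem_fit[worst]:
            memory[worst] = new
            mem_fit[worst] = fit
            memory_support = np.unique(np.concatenate(memory))
        if fit < best_fit:
            best, best_fit = new.copy(), float(fit)
        trace.append(best_fit)

    return SelectionResult(best, best_fit, trace)


def select_subjects_per_class(
    features,  # SpectralFeatures
    method: str = "pso",
    subset_sizes: dict[str, int] | None = None,
    seed: int = 0,
    **config_kwargs,
) -> dict[str, SelectionResult]:
    """Select representative subject columns per class (defaults 30 Adeno, 6 Meso).

    For class c, candidates are that class's subject columns; the fitness
    trains the base learner on the selected columns of c together with all
    subjects of the other class and scores the training MSE on everyone.
    """
    sizes = {"Adeno": 30, "Meso": 6}
    if subset_sizes:
        sizes.update(subset_sizes)
    out: dict[str, SelectionResult] = {}
    X_all = features.values.T  # subjects x features
    labels = features.labels
    targets = TargetMap()
    for cls in ("Adeno", "Meso"):
        cls_idx = np.flatnonzero(labels == cls)
        other_idx = np.flatnonzero(labels != cls)
        k = min(sizes[cls], cls_idx.size)

        def fitness(subset: np.ndarray, cls_idx=cls_idx, other_idx=other_idx) -> float:
            train = np.concatenate([cls_idx[subset], other_idx])
            Xt = Standardizer().fit_transform(X_all[train])
            clf = make_classifier("sdc", targets=targets, epochs=100)
            clf.fit(Xt, labels[train])
            observed = clf.observed_targets(Xt)
            t_true = targets.target_vector(labels[train])
            return float(np.mean((observed - t_true) ** 2))

        cand = np.zeros((1, cls_idx.size))  # only the candidate count matters
        if method == "pso":
            cfg = PSOConfig(subset_size=k, seed=seed, **config_kwargs)
            res = pso_select(cand, labels, cfg, fitness)
        elif method == "hs":
            cfg = HSConfig(subset_size=k, seed=seed, **config_kwargs)
            res = hs_select(cand, labels, cfg, fitness)
        else:
            raise InvalidConfigError(f"unknown selection method {method!r}")
        out[cls] = SelectionResult(
            cls_idx[res.selected_indices], res.best_fitness, res.fitness_trace
        )
    return out


def friedman_test(performance: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a blocks x methods performance matrix.

    Within-block ranks (average ranks on ties) are summed per method and

        X²r = 12 / (n·k·(k+1)) · Σ R_i² − 3·n·(k+1)

    is referred to a chi-square distribution with k−1 degrees of freedom.
    """
    perf = np.asarray(performance, dtype=float)
    if perf.ndim != 2 or perf.shape[1] < 2:
        raise InvalidConfigError("need at least 2 methods (columns)")
    if perf.shape[0] < 2:
        raise InvalidConfigError("need at least 2 blocks (rows)")
    n, k = perf.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, perf)
    rank_sums = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    statistic = max(statistic, 0.0)  # guard tiny negative round-off under heavy ties
    p_value = float(stats.chi2.sf(statistic, df=k - 1))
    return FriedmanResult(float(statistic), p_value, k=k, n=n, rank_sums=rank_sums)
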