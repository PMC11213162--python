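"""Wrapper feature selection over the feature table by binary PSO and SA.

Both optimizers search the space of binary feature masks; the fitness of a
mask is the stratified inner-cross-validated accuracy of an RBF-kernel SVM on
the masked, per-fold-standardized features. Selection is intended to run
strictly inside each outer training fold of the nested cross-validation so
the held-out fold never influences the chosen mask.

The particle swarm uses the standard inertia/cognitive/social velocity update
(swarm 20, c1 = c2 = 1.5, w = 0.72) with velocities squashed through a sigmoid
into per-bit Bernoulli position updates. Simulated annealing flips one bit
per step, always accepts improvements, and accepts worse neighbors with the
Boltzmann probability exp(-theta/T), theta being the shortfall against the
best solution so far; the temperature starts at 10 and cools geometrically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "PSOConfig",
    "SAConfig",
    "SelectionResult",
    "fitness",
    "make_fitness",
    "pso_select",
    "sa_select",
    "boltzmann_accept",
]


@dataclasses.dataclass
class PSOConfig:
    swarm_size: int = 20
    cognitive: float = 1.5
    social: float = 1.5
    inertia: float = 0.72
    iterations: int = 50
    v_max: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclasses.dataclass
class SAConfig:
    t_initial: float = 10.0
    cooling_ratio: float = 0.95
    iters_per_temp: int = 20
    t_min: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_ratio < 1.0):
            raise ValueError("cooling_ratio must lie in (0, 1)")
        if not (self.t_initial > self.t_min > 0):
            raise ValueError("need t_initial > t_min > 0")


@dataclasses.dataclass
class SelectionResult:
    mask: np.ndarray  # boolean over features
    best_fitness: float
    fitness_trace: np.ndarray  # best-so-far per iteration
    n_selected: int
    optimizer: str
    seed: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.n_selected = int(self.mask.sum())
        if self.n_selected < 1:
            raise ValueError("selection result must keep at least one feature")

    def to_json(self, feature_names: Sequence[str] | None = None) -> str:
        names = (list(np.asarray(feature_names)[self.mask])
                 if feature_names is not None else None)
        return json.dumps({
            "optimizer": self.optimizer,
            "seed": self.seed,
            "n_selected": self.n_selected,
            "best_fitness": self.best_fitness,
            "mask": self.mask.astype(int).tolist(),
            "selected_features": names,
            "fitness_trace": np.asarray(self.fitness_trace).tolist(),
        }, indent=2)

    def save(self, path: str | Path, feature_names: Sequence[str] | None = None) -> None:
        Path(path).write_text(self.to_json(feature_names))


def default_svm(cost: float = 1.0, gamma: str | float = "scale"):
    """RBF-kernel SVM behind a standardizer; gamma defaults to the
    1/(n_features * feature_variance) rule."""
    return make_pipeline(StandardScaler(),
                         SVC(kernel="rbf", C=cost, gamma=gamma))


def fitness(mask: np.ndarray, features: np.ndarray, labels: np.ndarray,
            inner_folds: int = 5, svm=None, seed: int = 0) -> float:
    """Mean stratified ``inner_folds``-fold CV accuracy of the SVM on the
    masked features; an empty mask scores 0 (penalty)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("fitness needs two classes")
    x = np.asarray(features, dtype=float)[:, mask]
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(x, labels):
        if np.unique(labels[train]).size < 2:
            raise ValueError("single-class inner training fold")
        model = svm() if svm is not None else default_svm()
        model.fit(x[train], labels[train])
        accs.append(float(np.mean(model.predict(x[test]) == labels[test])))
    return float(np.mean(accs))


def make_fitness(features: np.ndarray, labels: np.ndarray, inner_folds: int = 5,
                 svm=None, seed: int = 0) -> Callable[[np.ndarray], float]:
    """Memoizing fitness closure: a mask's score is a pure function of the
    mask under the fixed fold split, so repeat evaluations are cached."""
    cache: dict[bytes, float] = {}

    def fn(mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=bool).tobytes()
        if key not in cache:
            cache[key] = fitness(mask, features, labels, inner_folds=inner_folds,
                                 svm=svm, seed=seed)
        return cache[key]

    return fn


def boltzmann_accept(theta: float, temperature: float,
                     rng: np.random.Generator) -> bool:
    """Accept a worse move with probability exp(-theta/temperature), theta
    being the fitness shortfall against the best solution so far."""
    with np.errstate(over="ignore"):
        return bool(rng.random() < np.exp(-theta / temperature))


def _repair_empty(best_mask: np.ndarray, fitness_fn, n_features: int) -> tuple[np.ndarray, float]:
    """All-zero best mask: fall back to the best single feature."""
    best = (-np.inf, 0)
    for j in range(n_features):
        m = np.zeros(n_features, dtype=bool)
        m[j] = True
        best = max(best, (fitness_fn(m), j))
    mask = np.zeros(n_features, dtype=bool)
    mask[best[1]] = True
    return mask, best[0]


def pso_select(features: np.ndarray, labels: np.ndarray,
               config: PSOConfig | None = None,
               fitness_fn: Callable[[np.ndarray], float] | None = None,
               ) -> SelectionResult:
    """Binary particle swarm over feature masks, global-best topology."""
    config = config or PSOConfig()
    features = np.asarray(features, dtype=float)
    n = features.shape[1]
    fn = fitness_fn or make_fitness(features, labels, seed=config.seed)
    rng = np.random.default_rng(config.seed)

    positions = rng.random((config.swarm_size, n)) < 0.5
    velocities = rng.uniform(-1.0, 1.0, size=(config.swarm_size, n))
    pbest = positions.copy()
    pbest_fit = np.array([fn(p) for p in positions])
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    trace = [gbest_fit]
    for _ in range(config.iterations):
        r1 = rng.random((config.swarm_size, n))
        r2 = rng.random((config.swarm_size, n))
        pos_f = positions.astype(float)
        velocities = (config.inertia * velocities
                      + config.cognitive * r1 * (pbest.astype(float) - pos_f)
                      + config.social * r2 * (gbest.astype(float)[None, :] - pos_f))
        np.clip(velocities, -config.v_max, config.v_max, out=velocities)
        prob = 1.0 / (1.0 + np.exp(-velocities))
        positions = rng.random((config.swarm_size, n)) < prob
        for i in range(config.swarm_size):
            f = fn(positions[i])
            if f > pbest_fit[i]:
                pbest[i] = positions[i].copy()
                pbest_fit[i] = f
                if f > gbest_fit:
                    gbest, gbest_fit = positions[i].copy(), float(f)
        trace.append(gbest_fit)

    if not gbest.any():
        gbest, gbest_fit = _repair_empty(gbest, fn, n)
    return SelectionResult(mask=gbest, best_fitness=gbest_fit,
                           fitness_trace=np.array(trace), n_selected=int(gbest.sum()),
                           optimizer="pso", seed=config.seed)


def sa_select(features: np.ndarray, labels: np.ndarray,
              config: SAConfig | None = None,
              fitness_fn: Callable[[np.ndarray], float] | None = None,
              ) -> SelectionResult:
    """Simulated annealing over feature masks with single-bit-flip moves."""
    config = config or SAConfig()
    features = np.asarray(features, dtype=float)
    n = features.shape[1]
    fn = fitness_fn or make_fitness(features, labels, seed=config.seed)
    rng = np.random.default_rng(config.seed)

    current = rng.random(n) < 0.5
    current_fit = fn(current)
    best, best_fit = current.copy(), current_fit

    trace = [best_fit]
    temperature = config.t_initial
    while temperature > config.t_min:
        for _ in range(config.iters_per_temp):
            neighbor = current.copy()
            j = rng.integers(n)
            neighbor[j] = ~neighbor[j]
            f = fn(neighbor)
            if f > best_fit:
                best, best_fit = neighbor.copy(), f
                current, current_fit = neighbor, f
            elif f >= current_fit:
                current, current_fit = neighbor, f
            else:
                if boltzmann_accept(best_fit - f, temperature, rng):
                    current, current_fit = neighbor, f
            trace.append(best_fit)
        temperature *= config.cooling_ratio

    if not best.any():
        best, best_fit = _repair_empty(best, fn, n)
    return SelectionResult(mask=best, best_fitness=best_fit,
                           fitness_trace=np.array(trace), n_selected=int(best.sum()),
                           optimizer="sa", seed=config.seed)
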