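"""Particle swarm optimization for classifier hyperparameter tuning.

Canonical inertia-weighted PSO: each particle carries a position and
velocity in the search space, remembers its personal best (pbest) and is
attracted toward both pbest and the swarm's global best (gbest),

    V <- w*V + c1*r1*(pbest - p) + c2*r2*(gbest - p),     p <- p + V,

with r1, r2 drawn per dimension per particle and positions clamped to the
bounds.  Defaults follow the pipeline's study settings: 10 particles, 10
iterations, inertia w = 0.85, cognitive and social constants c1 = c2 = 2.

With c1 + c2 = 4 the swarm sits outside the classical stability region
(c1 + c2 < 2(1 + w)), so a fixed velocity cap leaves particles oscillating
around the optimum instead of settling onto it.  Velocities are therefore
clamped to an *annealed* cap, half the dimension range shrunk by a factor w
per iteration, which preserves early exploration and restores fine late
convergence without introducing any new constant.

The objective being maximized is the classifier fitness

    fitness = 1 - RMSE(one-hot truth, predicted class probabilities),

bounded above by 1 (a ``1 - MSE`` variant is available behind a flag).
Integer-valued dimensions (filter counts, batch sizes) are kept continuous
inside the swarm and rounded only when a position is decoded into a
hyperparameter configuration.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "Dimension",
    "SearchSpace",
    "Particle",
    "SwarmState",
    "fitness",
    "init_swarm",
    "step",
    "optimize",
    "optimize_hyperparameters",
]


@dataclasses.dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    kind: str = "continuous"  # continuous | integer | categorical
    choices: Optional[tuple] = None

    def __post_init__(self):
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError("categorical dimension needs choices")
            object.__setattr__(self, "low", 0.0)
            object.__setattr__(self, "high", float(len(self.choices)) - 1e-9)
        if not self.low < self.high:
            raise ValueError(f"dimension {self.name}: lower bound must be "
                             "strictly below upper")

    def decode(self, value: float):
        if self.kind == "continuous":
            return float(value)
        if self.kind == "integer":
            return int(round(value))
        return self.choices[int(np.clip(np.floor(value), 0,
                                        len(self.choices) - 1))]


@dataclasses.dataclass
class SearchSpace:
    dimensions: List[Dimension]

    @property
    def lows(self) -> np.ndarray:
        return np.asarray([d.low for d in self.dimensions])

    @property
    def highs(self) -> np.ndarray:
        return np.asarray([d.high for d in self.dimensions])

    def decode(self, position: np.ndarray) -> Dict[str, object]:
        return {d.name: d.decode(v) for d, v in zip(self.dimensions, position)}


@dataclasses.dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclasses.dataclass
class SwarmState:
    particles: List[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int
    w: float = 0.85
    c1: float = 2.0
    c2: float = 2.0
    rng: np.random.Generator = dataclasses.field(
        default_factory=np.random.default_rng)


def fitness(predictions: np.ndarray, truth: Sequence[int],
            variant: str = "rmse") -> float:
    """Classifier fitness 1 - RMSE (or 1 - MSE) of probabilities vs one-hot truth."""
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    truth = np.asarray(truth)
    if predictions.shape[0] == 0:
        raise ValueError("empty predictions")
    if predictions.shape[0] != len(truth):
        raise ValueError("predictions and truth lengths differ")
    onehot = np.zeros_like(predictions)
    onehot[np.arange(len(truth)), truth.astype(int)] = 1.0
    mse = float(np.mean((onehot - predictions) ** 2))
    if variant == "rmse":
        return 1.0 - float(np.sqrt(mse))
    if variant == "mse":
        return 1.0 - mse
    raise ValueError("variant must be 'rmse' or 'mse'")


def init_swarm(space: SearchSpace, objective: Callable[[np.ndarray], float],
               n_particles: int = 10, seed: int = 0, w: float = 0.85,
               c1: float = 2.0, c2: float = 2.0) -> SwarmState:
    """Uniformly initialized particles, each evaluated once."""
    lows, highs = space.lows, space.highs
    if np.any(highs - lows <= 0):
        raise ValueError("every dimension must have positive width")
    rng = np.random.default_rng(seed)
    span = highs - lows
    particles = []
    gbest_pos, gbest_fit = None, -np.inf
    for _ in range(n_particles):
        pos = rng.uniform(lows, highs)
        vel = rng.uniform(-span / 2, span / 2)
        fit = objective(pos)
        if not np.isfinite(fit):
            warnings.warn("objective returned a non-finite value at init")
            fit = -np.inf
        particles.append(Particle(position=pos, velocity=vel,
                                  pbest_position=pos.copy(), pbest_fitness=fit))
        if fit > gbest_fit:
            gbest_fit, gbest_pos = fit, pos.copy()
    return SwarmState(particles=particles, gbest_position=gbest_pos,
                      gbest_fitness=gbest_fit, iteration=0, w=w, c1=c1, c2=c2,
                      rng=rng)


def step(swarm: SwarmState, objective: Callable[[np.ndarray], float],
         space: SearchSpace) -> SwarmState:
    """One synchronous PSO iteration (in place); gbest never decreases."""
    lows, highs = space.lows, space.highs
    span = highs - lows
    vmax = (span / 2.0) * swarm.w ** swarm.iteration  # annealed velocity cap
    for part in swarm.particles:
        r1 = swarm.rng.uniform(size=len(lows))
        r2 = swarm.rng.uniform(size=len(lows))
        part.velocity = (swarm.w * part.velocity
                         + swarm.c1 * r1 * (part.pbest_position - part.position)
                         + swarm.c2 * r2 * (swarm.gbest_position - part.position))
        part.velocity = np.clip(part.velocity, -vmax, vmax)
        part.position = np.clip(part.position + part.velocity, lows, highs)
        fit = objective(part.position)
        if not np.isfinite(fit):
            warnings.warn("objective returned a non-finite value; "
                          "particle update skipped")
            continue
        if fit > part.pbest_fitness:
            part.pbest_fitness = fit
            part.pbest_position = part.position.copy()
        if fit > swarm.gbest_fitness:
            swarm.gbest_fitness = fit
            swarm.gbest_position = part.position.copy()
    swarm.iteration += 1
    return swarm


def optimize(objective: Callable[[np.ndarray], float], space: SearchSpace,
             n_particles: int = 10, n_iterations: int = 10, seed: int = 0,
             w: float = 0.85, c1: float = 2.0, c2: float = 2.0):
    """Run PSO to maximize ``objective``; returns (best position, best fitness, trace).

    The trace holds the gbest fitness after initialization and after each
    iteration; it is non-decreasing by construction.
    """
    swarm = init_swarm(space, objective, n_particles=n_particles, seed=seed,
                       w=w, c1=c1, c2=c2)
    trace = [swarm.gbest_fitness]
    for _ in range(n_iterations):
        step(swarm, objective, space)
        trace.append(swarm.gbest_fitness)
    return swarm.gbest_position, swarm.gbest_fitness, trace


def default_search_space() -> SearchSpace:
    """Hyperparameter box for the compact CNN."""
    return SearchSpace([
        Dimension("learning_rate", np.log10(3e-4), np.log10(3e-2),
                  kind="continuous"),  # log10 scale
        Dimension("filters", 4, 16, kind="integer"),
        Dimension("hidden", 8, 48, kind="integer"),
    ])


def optimize_hyperparameters(space: SearchSpace, train_data, val_data,
                             n_particles: int = 10, n_iterations: int = 10,
                             seed: int = 0, search_epochs: int = 2,
                             fitness_variant: str = "rmse"):
    """PSO over CNN hyperparameters against held-out validation fitness.

    ``train_data``/``val_data`` are (X, y) pairs of feature vectors (or
    images) and integer labels.  Each particle's position decodes into a
    classifier configuration which is trained for ``search_epochs`` epochs
    and scored with the probability fitness on the validation set.  Returns
    (best decoded config, best fitness, per-iteration gbest trace).
    """
    from .mlcnn import CnnConfig, MLCNN, train_model

    X_tr, y_tr = train_data
    X_val, y_val = val_data
    input_shape = np.asarray(X_tr[0]).shape
    n_classes = int(max(np.max(y_tr), np.max(y_val))) + 1

    def objective(position: np.ndarray) -> float:
        params = space.decode(position)
        lr = 10.0 ** params["learning_rate"] if "learning_rate" in params else 1e-3
        f = int(params.get("filters", 8))
        hidden = int(params.get("hidden", 32))
        cfg = CnnConfig(filters_per_layer=(f, 2 * f, 2 * f),
                        hidden_units=(hidden, max(hidden // 2, 2)),
                        epochs=search_epochs, learning_rate=lr,
                        n_classes=n_classes, seed=seed)
        model = MLCNN(cfg, input_shape)
        try:
            train_model(model, X_tr, y_tr)
        except FloatingPointError:
            return float("nan")
        probs = np.asarray([model.predict_proba(x) for x in X_val])
        return fitness(probs, y_val, variant=fitness_variant)

    best_pos, best_fit, trace = optimize(objective, space,
                                         n_particles=n_particles,
                                         n_iterations=n_iterations, seed=seed)
    return space.decode(best_pos), best_fit, trace
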