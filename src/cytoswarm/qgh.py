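"""Quantum-behaved swarm search over binary feature-subset masks.

A wrapper feature selector: each particle carries a real-valued position
whose logistic transform gives the probability of switching each feature
group on; fitness is the macro-F1 of a fuzzy C-means classifier on an
internal stratified validation split, minus a small parsimony penalty
proportional to the fraction of groups kept.

The position update is the quantum-behaved (QPSO-style) rule: with
attractor p = phi * pbest + (1 - phi) * gbest (phi ~ U(0,1) per dimension)
and mean-best position mbest (componentwise mean of all personal bests),

    x' = p +/- beta * |mbest - x| * ln(1/u),   u ~ U(0,1),

where the contraction-expansion coefficient beta anneals linearly over the
iterations.  Bits are drawn as Bernoulli(sigmoid(x')); an all-zero mask is
repaired by switching one uniformly chosen bit on.  The swarm is velocity-
free.  An exhaustive-search oracle over all nonempty masks (d <= 16) is
provided for verification at small dimension.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .evaluation import confusion_matrix, prf, stratified_split
from .fcm import FCMConfig, fcm_predict, fit_classifier

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "SelectionResult",
    "subset_fitness",
    "qgh_init",
    "qgh_step",
    "optimize_masks",
    "qgh_run",
    "exhaustive_subset_search",
]


@dataclass
class SwarmConfig:
    """Swarm hyperparameters.

    ``beta_start``/``beta_end`` bound the linearly annealed contraction-
    expansion coefficient; ``size_penalty`` is the parsimony weight per
    fraction of selected groups; ``seed_all_ones`` plants one all-features
    particle so the selected subset can never score below the full set on
    the internal split.
    """

    n_particles: int = 20
    n_iterations: int = 50
    beta_start: float = 1.0
    beta_end: float = 0.5
    size_penalty: float = 0.01
    seed: int = 0
    seed_all_ones: bool = True

    def __post_init__(self) -> None:
        if not (self.beta_start >= self.beta_end > 0):
            raise ValueError("need beta_start >= beta_end > 0")
        if self.size_penalty < 0:
            raise ValueError("size_penalty must be >= 0")
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")


@dataclass
class Particle:
    position: np.ndarray
    mask: np.ndarray
    fitness: float
    pbest_position: np.ndarray
    pbest_mask: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_mask: np.ndarray
    gbest_fitness: float
    history: list[float]
    evaluations: int


@dataclass
class SelectionResult:
    """Outcome of one selection run."""

    best_mask: np.ndarray
    best_fitness: float
    history: list[float]
    evaluations: int
    group_names: list[str] | None = None
    config: SwarmConfig | None = None

    def to_dict(self) -> dict:
        return {
            "best_mask": np.asarray(self.best_mask, dtype=int).tolist(),
            "best_fitness": float(self.best_fitness),
            "history": list(map(float, self.history)),
            "evaluations": int(self.evaluations),
            "group_names": self.group_names,
            "config": dataclasses.asdict(self.config) if self.config else None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.random(position.shape) < _sigmoid(position)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def subset_fitness(
    mask,
    features,
    labels,
    fcm_config: FCMConfig,
    split_seed: int,
    size_penalty: float = 0.0,
) -> float:
    """Wrapper fitness of one mask: validation macro-F1 minus size penalty.

    A stratified 70/30 split of the supplied (training) data is fixed by
    ``split_seed``; the FCM classifier is fitted on the 70% and scored on
    the 30%, so the fitness is a deterministic function of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("fitness of an empty mask is undefined")
    labels = np.asarray(labels)
    X = features.select(mask)
    tr, va = stratified_split(labels, test_fraction=0.3, seed=split_seed)
    classes = list(np.unique(labels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_classifier(X[tr], labels[tr], fcm_config, classes=classes)
        pred, _ = fcm_predict(model, X[va])
        cm = confusion_matrix(labels[va], pred, classes)
        macro_f1 = prf(cm, warn=False)["macro_f1"]
    return float(macro_f1) - size_penalty * mask.sum() / mask.size


def qgh_init(config: SwarmConfig, d: int, rng: np.random.Generator, fitness_fn) -> SwarmState:
    """Initialize the swarm: N(0,1) positions, binarized masks, all evaluated."""
    if d < 1:
        raise ValueError("d must be >= 1")
    particles = []
    evaluations = 0
    for i in range(config.n_particles):
        position = rng.normal(0.0, 1.0, size=d)
        mask = _repair(_binarize(position, rng), rng)
        if i == 0 and config.seed_all_ones:
            mask = np.ones(d, dtype=bool)
        fitness = float(fitness_fn(mask))
        evaluations += 1
        particles.append(
            Particle(
                position=position,
                mask=mask,
                fitness=fitness,
                pbest_position=position.copy(),
                pbest_mask=mask.copy(),
                pbest_fitness=fitness,
            )
        )
    best = max(particles, key=lambda p: p.pbest_fitness)
    return SwarmState(
        particles=particles,
        gbest_position=best.pbest_position.copy(),
        gbest_mask=best.pbest_mask.copy(),
        gbest_fitness=best.pbest_fitness,
        history=[best.pbest_fitness],
        evaluations=evaluations,
    )


def qgh_step(
    state: SwarmState,
    fitness_fn,
    iteration: int,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """One synchronous swarm update; gbest can only improve."""
    span = max(config.n_iterations - 1, 1)
    t = min(iteration, span) / span
    beta = config.beta_start + (config.beta_end - config.beta_start) * t

    mbest = np.mean([p.pbest_position for p in state.particles], axis=0)
    d = mbest.size
    for p in state.particles:
        phi = rng.random(d)
        attractor = phi * p.pbest_position + (1.0 - phi) * state.gbest_position
        u = rng.random(d)
        sign = np.where(rng.random(d) < 0.5, 1.0, -1.0)
        p.position = attractor + sign * beta * np.abs(mbest - p.position) * np.log(1.0 / u)
        p.mask = _repair(_binarize(p.position, rng), rng)
        p.fitness = float(fitness_fn(p.mask))
        state.evaluations += 1
        if p.fitness > p.pbest_fitness:
            p.pbest_fitness = p.fitness
            p.pbest_position = p.position.copy()
            p.pbest_mask = p.mask.copy()
            if p.fitness > state.gbest_fitness:
                state.gbest_fitness = p.fitness
                state.gbest_position = p.position.copy()
                state.gbest_mask = p.mask.copy()
    state.history.append(state.gbest_fitness)
    return state


def optimize_masks(fitness_fn, d: int, config: SwarmConfig) -> SelectionResult:
    """Run the swarm on an arbitrary mask-fitness function."""
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 97])
    cache: dict[bytes, float] = {}

    def cached(mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=bool).tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(mask))
        return cache[key]

    state = qgh_init(config, d, rng, cached)
    for it in range(config.n_iterations):
        qgh_step(state, cached, it, config, rng)
    return SelectionResult(
        best_mask=state.gbest_mask.copy(),
        best_fitness=state.gbest_fitness,
        history=list(state.history),
        evaluations=state.evaluations,
        config=config,
    )


def qgh_run(
    features,
    labels,
    swarm_config: SwarmConfig | None = None,
    fcm_config: FCMConfig | None = None,
) -> SelectionResult:
    """Select a feature-group subset for the FCM classifier.

    ``features`` is a GroupedFeatures over the *training* data only; the
    internal validation split is derived from the swarm seed and fixed for
    the whole run.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("feature selection needs at least 2 classes")
    swarm_config = swarm_config or SwarmConfig()
    fcm_config = fcm_config or FCMConfig()
    split_seed = int(
        np.random.default_rng([int(swarm_config.seed) & 0x7FFFFFFF, 11]).integers(2**31)
    )

    def fitness(mask) -> float:
        return subset_fitness(
            mask,
            features,
            labels,
            fcm_config,
            split_seed,
            size_penalty=swarm_config.size_penalty,
        )

    result = optimize_masks(fitness, features.n_groups, swarm_config)
    result.group_names = list(features.group_names)
    return result


def exhaustive_subset_search(fitness_fn, d: int) -> tuple[np.ndarray, float]:
    """Evaluate every nonempty mask (d <= 16); deterministic argmax.

    Ties break toward fewer set bits, then lexicographically smaller bit
    tuples.
    """
    if d > 16:
        raise ValueError("exhaustive search supports at most d = 16")
    if d < 1:
        raise ValueError("d must be >= 1")
    best_mask = None
    best_fitness = -np.inf
    best_key = None
    for code in range(1, 2**d):
        mask = np.array([(code >> b) & 1 for b in range(d)], dtype=bool)
        fitness = float(fitness_fn(mask))
        key = (int(mask.sum()), tuple(int(v) for v in mask))
        if fitness > best_fitness or (fitness == best_fitness and key < best_key):
            best_mask, best_fitness, best_key = mask, fitness, key
    return best_mask, best_fitness
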