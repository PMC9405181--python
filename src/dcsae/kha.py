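"""Krill herd algorithm (KHA) and DCSAE hyperparameter tuning.

KHA moves each candidate ("krill") under three summed velocity fields: motion
induced by neighbours and by the best individual, foraging toward a
fitness-weighted food centroid, and random diffusion that decays linearly to
zero over the run.  The induced-motion inertia weight decreases linearly from
0.9 to 0.1, and the attraction to the incumbent best is amplified by
C_best = 2(rand + I/I_max) so exploitation grows late in the run.

The tuner maps krill coordinates in the unit cube to DCSAE hyperparameters
(linear or logarithmic scales, optional integer rounding) and minimizes the
percentage classification error on a held-out validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .model import DcsaeConfig, TrainingError, make_views, predict, train_dcsae

__all__ = [
    "KhaConfig",
    "KrillSwarm",
    "HyperparamSpace",
    "SpaceEntry",
    "inertia_weight",
    "induced_motion",
    "food_position",
    "foraging_motion",
    "physical_diffusion",
    "kha_step",
    "optimize",
    "error_rate_fitness",
    "tune_dcsae",
]

_EPS = 1e-10


@dataclass
class KhaConfig:
    """KHA run parameters.

    ``n_max`` (maximum induced speed) defaults to 0.01; the induced-motion
    inertia runs linearly from ``inertia_start`` (0.9) to ``inertia_end``
    (0.1) over the iterations.  Foraging speed and maximum diffusion use the
    standard krill-herd constants; ``time_scale`` is the C_t factor of the
    position update Δt = C_t * sum(ub - lb).
    """

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    n_krill: int = 20
    max_iterations: int = 100
    n_max: float = 0.01
    inertia_start: float = 0.9
    inertia_end: float = 0.1
    foraging_speed: float = 0.02
    foraging_inertia_start: float = 0.9
    foraging_inertia_end: float = 0.1
    diffusion_max: float = 0.005
    time_scale: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.lower_bounds.shape != self.upper_bounds.shape:
            raise ValueError("bound vectors must share a shape")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("lower bounds must not exceed upper bounds")
        if self.n_krill < 2 or self.max_iterations < 1:
            raise ValueError("need at least 2 krill and 1 iteration")

    @property
    def n_dims(self) -> int:
        return self.lower_bounds.shape[0]

    @property
    def delta_t(self) -> float:
        return self.time_scale * float(np.sum(self.upper_bounds - self.lower_bounds))


@dataclass
class KrillSwarm:
    """Positions, fitness and carried motion state of the herd."""

    positions: np.ndarray  # (n, D)
    fitness: np.ndarray  # (n,)
    induced: np.ndarray  # N_i, carried between iterations
    foraging: np.ndarray  # F_i, carried between iterations
    best_position: np.ndarray
    best_fitness: float

    @classmethod
    def init(
        cls, config: KhaConfig, fitness_fn: Callable, rng: np.random.Generator
    ) -> "KrillSwarm":
        shape = (config.n_krill, config.n_dims)
        pos = config.lower_bounds + rng.uniform(size=shape) * (
            config.upper_bounds - config.lower_bounds
        )
        fit = np.array([float(fitness_fn(x)) for x in pos])
        if not np.isfinite(fit).all():
            raise ValueError("fitness function returned a non-finite value")
        b = int(fit.argmin())
        return cls(
            pos,
            fit,
            np.zeros(shape),
            np.zeros(shape),
            pos[b].copy(),
            float(fit[b]),
        )


def inertia_weight(iteration: int, config: KhaConfig) -> float:
    """Linear schedule from inertia_start to inertia_end over the run."""
    frac = iteration / config.max_iterations
    return config.inertia_start + (config.inertia_end - config.inertia_start) * frac


def _unit(vec: np.ndarray) -> np.ndarray:
    return vec / (np.linalg.norm(vec) + _EPS)


def induced_motion(
    swarm: KrillSwarm, iteration: int, config: KhaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Neighbour- and best-induced motion N_i = N_max * alpha_i + w_n * N_old.

    alpha_i sums a local term over neighbours within the sensing distance
    (one fifth of the mean pairwise distance) and a target term toward the
    swarm's best individual scaled by C_best = 2(rand + I/I_max).  Fitness
    differences are normalized by the worst-best spread.
    """
    n = config.n_krill
    pos, fit = swarm.positions, swarm.fitness
    k_best, k_worst = float(fit.min()), float(fit.max())
    spread = k_worst - k_best + _EPS
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = X_j - X_i
    dist = np.linalg.norm(diff, axis=2)
    sensing = dist.sum() / (5.0 * n * (n - 1)) if n > 1 else 0.0
    w_n = inertia_weight(iteration, config)
    c_best = 2.0 * (rng.uniform() + iteration / config.max_iterations)
    best_idx = int(fit.argmin())
    new = np.zeros_like(pos)
    for i in range(n):
        alpha = np.zeros(config.n_dims)
        neighbors = np.flatnonzero((dist[i] < sensing) & (np.arange(n) != i))
        for j in neighbors:
            k_hat = (fit[i] - fit[j]) / spread
            alpha += k_hat * diff[i, j] / (dist[i, j] + _EPS)
        if i != best_idx:
            k_hat_best = (fit[i] - fit[best_idx]) / spread
            alpha += c_best * k_hat_best * _unit(diff[i, best_idx])
        new[i] = config.n_max * alpha + w_n * swarm.induced[i]
    return new


def food_position(swarm: KrillSwarm) -> np.ndarray:
    """Fitness-weighted centroid sum(X_i / K_i) / sum(1 / K_i) (minimization)."""
    weights = 1.0 / (swarm.fitness + _EPS)
    return (weights[:, None] * swarm.positions).sum(axis=0) / weights.sum()


def foraging_motion(
    swarm: KrillSwarm, food: np.ndarray, iteration: int, config: KhaConfig
) -> np.ndarray:
    """Foraging F_i = V_f * (beta_food + beta_best) + w_f * F_old."""
    frac = iteration / config.max_iterations
    w_f = config.foraging_inertia_start + (
        config.foraging_inertia_end - config.foraging_inertia_start
    ) * frac
    c_food = 2.0 * (1.0 - frac)
    fit = swarm.fitness
    k_best, k_worst = float(fit.min()), float(fit.max())
    spread = k_worst - k_best + _EPS
    food_fit = float(fit.min())  # food attractiveness proxied by the best fitness
    new = np.zeros_like(swarm.positions)
    for i in range(config.n_krill):
        k_hat_food = (fit[i] - food_fit) / spread
        beta_food = c_food * k_hat_food * _unit(food - swarm.positions[i])
        k_hat_best = (fit[i] - swarm.best_fitness) / spread
        beta_best = k_hat_best * _unit(swarm.best_position - swarm.positions[i])
        new[i] = config.foraging_speed * (beta_food + beta_best) + w_f * swarm.foraging[i]
    return new


def physical_diffusion(
    iteration: int, config: KhaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random diffusion D_max * (1 - I/I_max) * delta, delta ~ U[-1, 1]^D.

    Exactly zero at the final iteration.
    """
    decay = 1.0 - iteration / config.max_iterations
    delta = rng.uniform(-1.0, 1.0, size=(config.n_krill, config.n_dims))
    return config.diffusion_max * decay * delta


def kha_step(
    swarm: KrillSwarm,
    iteration: int,
    config: KhaConfig,
    fitness_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> KrillSwarm:
    """One Lagrangian update X <- X + Δt(N + F + D), clipped to bounds."""
    n_i = induced_motion(swarm, iteration, config, rng)
    food = food_position(swarm)
    f_i = foraging_motion(swarm, food, iteration, config)
    d_i = physical_diffusion(iteration, config, rng)
    new_pos = swarm.positions + config.delta_t * (n_i + f_i + d_i)
    np.clip(new_pos, config.lower_bounds, config.upper_bounds, out=new_pos)
    fit = np.array([float(fitness_fn(x)) for x in new_pos])
    if not np.isfinite(fit).all():
        raise ValueError("fitness function returned a non-finite value")
    swarm.positions = new_pos
    swarm.fitness = fit
    swarm.induced = n_i
    swarm.foraging = f_i
    b = int(fit.argmin())
    if fit[b] < swarm.best_fitness:
        swarm.best_fitness = float(fit[b])
        swarm.best_position = new_pos[b].copy()
    return swarm


def optimize(
    fitness_fn: Callable[[np.ndarray], float], config: KhaConfig
) -> tuple[np.ndarray, float, list[float]]:
    """Run KHA; returns (best position, best fitness, incumbent trace)."""
    rng = np.random.default_rng(config.rng_seed)
    swarm = KrillSwarm.init(config, fitness_fn, rng)
    trace = [swarm.best_fitness]
    for it in range(1, config.max_iterations + 1):
        kha_step(swarm, it, config, fitness_fn, rng)
        trace.append(swarm.best_fitness)
    return swarm.best_position, swarm.best_fitness, trace


# ---------------------------------------------------------------------------
# Hyperparameter tuning


def error_rate_fitness(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Percentage classification error: misclassified / total * 100."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have the same length")
    if predicted.shape[0] < 1:
        raise ValueError("need at least one sample")
    return float((predicted != actual).mean() * 100.0)


@dataclass
class SpaceEntry:
    """One tunable dimension: name, scale, range, and value kind."""

    name: str
    low: float
    high: float
    scale: Literal["linear", "log"] = "linear"
    kind: Literal["real", "integer"] = "real"

    def decode(self, coord: float) -> float | int:
        coord = float(np.clip(coord, 0.0, 1.0))
        if self.scale == "log":
            value = 10 ** (
                np.log10(self.low) + coord * (np.log10(self.high) - np.log10(self.low))
            )
        else:
            value = self.low + coord * (self.high - self.low)
        value = float(np.clip(value, self.low, self.high))
        if self.kind == "integer":
            return int(np.floor(value + 0.5))
        return value


@dataclass
class HyperparamSpace:
    """Mapping from [0, 1]^D krill coordinates to DcsaeConfig fields."""

    entries: list[SpaceEntry] = field(default_factory=list)

    @classmethod
    def default(cls) -> "HyperparamSpace":
        return cls(
            [
                SpaceEntry("learning_rate", 1e-4, 1e-1, scale="log"),
                SpaceEntry("recon_weight", 1e-3, 1e1, scale="log"),
                SpaceEntry("sparsity_weight_f", 1e-4, 1e0, scale="log"),
                SpaceEntry("sparsity_target_f", 0.01, 0.5),
                SpaceEntry("first_hidden_f", 8, 64, kind="integer"),
            ]
        )

    @property
    def n_dims(self) -> int:
        return len(self.entries)

    def decode(self, coords: Sequence[float], base: DcsaeConfig) -> DcsaeConfig:
        """Decode a krill position into a concrete DcsaeConfig."""
        updates: dict = {}
        for entry, coord in zip(self.entries, coords):
            value = entry.decode(coord)
            if entry.name == "first_hidden_f":
                updates["hidden_sizes_f"] = (int(value), *base.hidden_sizes_f[1:])
            elif entry.name == "first_hidden_g":
                updates["hidden_sizes_g"] = (int(value), *base.hidden_sizes_g[1:])
            else:
                updates[entry.name] = value
        return replace(base, **updates)


def tune_dcsae(
    values: np.ndarray,
    labels: np.ndarray,
    space: HyperparamSpace | None = None,
    kha: KhaConfig | None = None,
    base: DcsaeConfig | None = None,
    validation_fraction: float = 0.25,
    inner_epochs: int = 10,
) -> tuple[DcsaeConfig, float, list[float], list[dict]]:
    """KHA search for DCSAE hyperparameters on a held-out split.

    Each krill decodes to a config trained for ``inner_epochs`` (a short
    budget; retrain the winner at full budget afterwards) and scored by the
    percentage error on the validation split.  A diverging configuration is
    assigned the worst fitness (100) and the search continues.  Returns the
    best config, its validation error, the incumbent trace, and the per-
    evaluation log.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("tuning requires at least 2 classes")
    if space is None:
        space = HyperparamSpace.default()
    if base is None:
        base = DcsaeConfig()
    if kha is None:
        kha = KhaConfig(
            np.zeros(space.n_dims), np.ones(space.n_dims), n_krill=10, max_iterations=10
        )
    if kha.n_dims != space.n_dims:
        raise ValueError("KHA bound dimension must match the space")
    rng = np.random.default_rng(kha.rng_seed)
    n = values.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    log: list[dict] = []

    def fitness(coords: np.ndarray) -> float:
        cfg = space.decode(coords, base)
        cfg = replace(cfg, epochs=inner_epochs)
        try:
            model = train_dcsae(make_views(values[tr_idx], labels[tr_idx], cfg.view_mode), cfg)
            pred, _ = predict(model, values[val_idx])
            err = error_rate_fitness(pred, labels[val_idx])
        except (TrainingError, FloatingPointError, np.linalg.LinAlgError):
            err = 100.0
        log.append({"coords": coords.tolist(), "error": err})
        return err

    best_coords, best_err, trace = optimize(fitness, kha)
    best_config = space.decode(best_coords, base)
    return best_config, best_err, trace, log
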