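"""Coyote optimization algorithm (COA) and its feature-selection wrapper.

COA is a population metaheuristic that organizes candidate solutions into
packs of coyotes.  Each iteration a coyote moves under the joint influence of
the pack alpha (its best member) and the pack's cultural tendency (the
componentwise median of social states), accepting the move only if it lowers
the cost.  Packs also breed: a pup inherits coordinates from two parents with
two dimensions forced from each, scatters the rest with probability
``Prs = 1/D``, and replaces the worst pack member when strictly better.

The wrapper binarizes continuous positions in [0, 1]^D at a threshold into
feature masks and scores them with the weighted fitness

    fitness = alpha * error_rate(mask) + beta * |selected| / |total|

so that classification error dominates (default alpha = 0.99) while a small
pressure rewards compact subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = [
    "CoaConfig",
    "CoyotePopulation",
    "FsFitnessConfig",
    "FeatureMask",
    "init_population",
    "social_tendency",
    "update_coyote",
    "birth_pup",
    "replace_with_pup",
    "optimize",
    "fs_fitness",
    "make_cv_error_estimator",
    "select_features",
]


@dataclass
class CoaConfig:
    """COA run parameters.

    ``scatter_probability`` (Prs) and ``association_probability`` (Pra)
    default to 1/D and (1 - Prs)/2; coyotes_per_pack is capped at 14, the
    pack size that preserves the algorithm's search behaviour.
    """

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    n_packs: int = 4
    coyotes_per_pack: int = 10
    max_iterations: int = 50
    scatter_probability: float | None = None
    association_probability: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.lower_bounds.shape != self.upper_bounds.shape:
            raise ValueError("bound vectors must share a shape")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("lower bounds must not exceed upper bounds")
        if self.n_packs < 1 or self.max_iterations < 1:
            raise ValueError("n_packs and max_iterations must be positive")
        if not 1 <= self.coyotes_per_pack <= 14:
            raise ValueError("coyotes_per_pack must be in 1..14")
        D = self.lower_bounds.shape[0]
        if self.scatter_probability is None:
            self.scatter_probability = 1.0 / D
        if self.association_probability is None:
            self.association_probability = (1.0 - self.scatter_probability) / 2.0
        if not 0.0 < self.scatter_probability <= 1.0:
            raise ValueError("scatter_probability must be in (0, 1]")
        if not 0.0 <= self.association_probability < 1.0:
            raise ValueError("association_probability must be in [0, 1)")

    @property
    def n_dims(self) -> int:
        return self.lower_bounds.shape[0]


@dataclass
class CoyotePopulation:
    """Packs of candidate solutions with per-coyote costs."""

    positions: np.ndarray  # (n_packs, Nc, D)
    costs: np.ndarray  # (n_packs, Nc)
    iteration: int = 0

    @property
    def alpha_index(self) -> np.ndarray:
        """Index of the lowest-cost coyote of each pack."""
        return self.costs.argmin(axis=1)

    def best(self) -> tuple[np.ndarray, float]:
        flat = int(self.costs.argmin())
        p, c = np.unravel_index(flat, self.costs.shape)
        return self.positions[p, c].copy(), float(self.costs[p, c])


def init_population(
    config: CoaConfig, cost_fn: Callable[[np.ndarray], float], rng: np.random.Generator
) -> CoyotePopulation:
    """Random initialization lb + r * (ub - lb), costs evaluated."""
    shape = (config.n_packs, config.coyotes_per_pack, config.n_dims)
    r = rng.uniform(size=shape)
    positions = config.lower_bounds + r * (config.upper_bounds - config.lower_bounds)
    costs = np.array(
        [[_eval(cost_fn, x) for x in pack] for pack in positions], dtype=float
    )
    return CoyotePopulation(positions, costs)


def _eval(cost_fn: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    c = float(cost_fn(x))
    if not np.isfinite(c):
        raise ValueError("cost function returned a non-finite value")
    return c


def social_tendency(pack_positions: np.ndarray) -> np.ndarray:
    """Cultural tendency of a pack: the componentwise median of social states.

    Odd pack sizes take the middle ranked value, even sizes the mean of the
    two middle ranked values.
    """
    pack_positions = np.asarray(pack_positions, dtype=float)
    if pack_positions.ndim != 2 or pack_positions.shape[0] < 1:
        raise ValueError("pack_positions must be a non-empty Nc x D matrix")
    return np.median(pack_positions, axis=0)


def update_coyote(
    position: np.ndarray,
    cost: float,
    alpha: np.ndarray,
    tendency: np.ndarray,
    pack_positions: np.ndarray,
    config: CoaConfig,
    cost_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Greedy social-state update under alpha and cultural influence.

    Candidate = X + r1*(alpha - X_r1) + r2*(Y - X_r2) with r1, r2 ~ U[0,1]
    and X_r1, X_r2 random pack members; clipped to bounds; adopted only when
    its cost is strictly lower.
    """
    nc = pack_positions.shape[0]
    r1, r2 = rng.uniform(size=2)
    cr1, cr2 = rng.integers(nc), rng.integers(nc)
    candidate = (
        position
        + r1 * (alpha - pack_positions[cr1])
        + r2 * (tendency - pack_positions[cr2])
    )
    np.clip(candidate, config.lower_bounds, config.upper_bounds, out=candidate)
    new_cost = _eval(cost_fn, candidate)
    if new_cost < cost:
        return candidate, new_cost
    return position.copy(), cost


def birth_pup(
    pack_positions: np.ndarray, config: CoaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Breed a pup from two distinct parents.

    Two random dimensions are forced from parent 1 and parent 2 respectively.
    Each remaining dimension j draws r_j ~ U[0,1] and inherits from parent 1
    when r_j >= Prs + Pra, from parent 2 when r_j < Prs, and otherwise takes
    a fresh uniform value within bounds (the scatter event).
    """
    nc, D = pack_positions.shape
    if nc < 2:
        raise ValueError("breeding requires at least 2 coyotes per pack")
    p1, p2 = rng.choice(nc, size=2, replace=False)
    if D >= 2:
        i1, i2 = rng.choice(D, size=2, replace=False)
    else:
        i1 = i2 = 0
    r = rng.uniform(size=D)
    fresh = config.lower_bounds + rng.uniform(size=D) * (
        config.upper_bounds - config.lower_bounds
    )
    prs = config.scatter_probability
    pra = config.association_probability
    pup = np.where(r >= prs + pra, pack_positions[p1], fresh)
    from_p2 = r < prs
    pup = np.where(from_p2, pack_positions[p2], pup)
    pup[i1] = pack_positions[p1][i1]
    pup[i2] = pack_positions[p2][i2]
    return pup


def replace_with_pup(
    pack_positions: np.ndarray,
    pack_costs: np.ndarray,
    pup: np.ndarray,
    pup_cost: float,
) -> None:
    """In place: the pup replaces the worst pack member when strictly better."""
    worst = int(pack_costs.argmax())
    if pup_cost < pack_costs[worst]:
        pack_positions[worst] = pup
        pack_costs[worst] = pup_cost


def optimize(
    cost_fn: Callable[[np.ndarray], float], config: CoaConfig
) -> tuple[np.ndarray, float, list[float]]:
    """Run COA; returns (best position, best cost, best-so-far trace)."""
    rng = np.random.default_rng(config.rng_seed)
    pop = init_population(config, cost_fn, rng)
    best_x, best_c = pop.best()
    trace = [best_c]
    for _ in range(config.max_iterations):
        for p in range(config.n_packs):
            pack_pos = pop.positions[p]
            pack_costs = pop.costs[p]
            alpha = pack_pos[int(pack_costs.argmin())].copy()
            tendency = social_tendency(pack_pos)
            for c in range(config.coyotes_per_pack):
                pack_pos[c], pack_costs[c] = update_coyote(
                    pack_pos[c],
                    float(pack_costs[c]),
                    alpha,
                    tendency,
                    pack_pos,
                    config,
                    cost_fn,
                    rng,
                )
            if config.coyotes_per_pack >= 2:
                pup = birth_pup(pack_pos, config, rng)
                replace_with_pup(pack_pos, pack_costs, pup, _eval(cost_fn, pup))
        pop.iteration += 1
        x, c = pop.best()
        if c < best_c:
            best_x, best_c = x, c
        trace.append(best_c)
    return best_x, best_c, trace


# ---------------------------------------------------------------------------
# Feature-selection wrapper


@dataclass
class FeatureMask:
    """Boolean feature subset with the binarization threshold that made it."""

    selected: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


@dataclass
class FsFitnessConfig:
    """Weights and error estimator for the subset fitness.

    ``error_estimator`` maps a boolean mask to a classifier error rate in
    [0, 1]; ``alpha_weight`` trades error against the selected fraction
    (beta_weight = 1 - alpha_weight).
    """

    total_features: int
    error_estimator: Callable[[np.ndarray], float]
    alpha_weight: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_weight <= 1.0:
            raise ValueError("alpha_weight must be in [0, 1]")
        if self.total_features < 1:
            raise ValueError("total_features must be positive")

    @property
    def beta_weight(self) -> float:
        return 1.0 - self.alpha_weight


def fs_fitness(mask: FeatureMask, config: FsFitnessConfig) -> float:
    """Weighted error/subset-size fitness of a feature mask.

    An all-false mask is assigned the worst error (1.0) without calling the
    estimator, keeping the objective total.
    """
    if mask.selected.shape[0] != config.total_features:
        raise ValueError("mask dimension does not match total_features")
    if mask.n_selected == 0:
        error = 1.0
    else:
        error = float(config.error_estimator(mask.selected))
        if not 0.0 <= error <= 1.0:
            raise ValueError(f"error estimator returned {error}, outside [0, 1]")
    frac = mask.n_selected / config.total_features
    return config.alpha_weight * error + config.beta_weight * frac


def make_cv_error_estimator(
    values: np.ndarray,
    labels: np.ndarray,
    n_splits: int = 3,
    seed: int = 0,
) -> Callable[[np.ndarray], float]:
    """Cross-validated error of a fast linear classifier on masked features.

    Ridge classification keeps the wrapper loop cheap; the estimator is a
    plain callable so heavier models can be swapped in.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)

    def estimator(mask: np.ndarray) -> float:
        cols = np.flatnonzero(mask)
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        scores = cross_val_score(
            RidgeClassifier(), values[:, cols], labels, cv=cv, scoring="accuracy"
        )
        return 1.0 - float(scores.mean())

    return estimator


def select_features(
    values: np.ndarray,
    labels: np.ndarray,
    coa: CoaConfig | None = None,
    fit: FsFitnessConfig | None = None,
    threshold: float = 0.5,
    feature_names: Sequence[str] | None = None,
) -> tuple[FeatureMask, float, list[float]]:
    """COA wrapper feature selection over [0, 1]^D positions.

    Each continuous position is binarized at ``threshold`` before fitness
    evaluation.  Returns the best mask, its fitness, and the non-increasing
    best-cost trace.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("feature selection requires at least 2 classes")
    D = values.shape[1]
    if coa is None:
        coa = CoaConfig(np.zeros(D), np.ones(D))
    if coa.n_dims != D:
        raise ValueError("COA bound dimension must equal the feature count")
    if fit is None:
        fit = FsFitnessConfig(
            total_features=D,
            error_estimator=make_cv_error_estimator(values, labels, seed=coa.rng_seed),
        )

    cache: dict[bytes, float] = {}

    def cost(position: np.ndarray) -> float:
        sel = position > threshold
        key = np.packbits(sel).tobytes()
        if key not in cache:
            cache[key] = fs_fitness(FeatureMask(sel, threshold), fit)
        return cache[key]

    best_x, best_c, trace = optimize(cost, coa)
    return FeatureMask(best_x > threshold, threshold), best_c, trace
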