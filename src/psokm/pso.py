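"""Particle swarm optimization and the swarm-seeded K-means hybrid.

Each particle carries a position X and velocity V; per iteration the
velocity blends inertia, attraction toward the particle's personal best
(Pbest) and attraction toward the swarm best (Gbest):

    V <- w*V + c1*r1*(Pbest - X) + c2*r2*(Gbest - X)
    X <- X + V

with r1, r2 uniform on (0, 1), drawn fresh per particle per iteration.
Defaults follow the values established empirically in the swarm
literature: inertia w ≈ 0.73, cognitive and social weights
c1 = c2 = 1.49, and 20–30 iterations.

For clustering, a particle position is the row-wise flattening of a
candidate (k, dim) centroid set and the fitness is the clustering SSE;
after the swarm finishes, K-means refines the best centroid set
(:func:`pso_km`), so the hybrid can only improve on the swarm's answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .kmeans import CentroidSet, Partition, kmeans, sse_objective


@dataclass
class PSOConfig:
    """Swarm hyper-parameters.

    w : inertia factor in [0, 1] (default 0.73).
    c1, c2 : cognitive and social acceleration weights (default 1.49 each).
    iterations : fixed number of swarm iterations (default 30).
    swarm_size : number of particles (default 30).
    v_max_fraction : velocity cap as a fraction of each dimension's bound
        width (default 0.5).
    per_dimension_r : draw r1, r2 per dimension instead of one scalar per
        particle per iteration.
    """

    w: float = 0.73
    c1: float = 1.49
    c2: float = 1.49
    iterations: int = 30
    swarm_size: int = 30
    v_max_fraction: float = 0.5
    per_dimension_r: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError(f"inertia w must be in [0, 1], got {self.w}")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be >= 0")
        if self.iterations < 1 or self.swarm_size < 1:
            raise ValueError("iterations and swarm_size must be >= 1")
        if not 0 < self.v_max_fraction <= 1:
            raise ValueError("v_max_fraction must be in (0, 1]")


@dataclass
class Particle:
    """One candidate solution with velocity and personal-best memory."""

    position: np.ndarray
    velocity: np.ndarray
    pbest: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    """The whole swarm at one iteration, with the global best."""

    particles: list[Particle]
    gbest: np.ndarray
    gbest_fitness: float
    iteration: int = 0


def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    config: PSOConfig,
    r1: float | np.ndarray,
    r2: float | np.ndarray,
    v_max: np.ndarray | None = None,
) -> np.ndarray:
    """One velocity update; the result is clamped to ±v_max componentwise."""
    velocity, position, pbest, gbest = (
        np.asarray(a, dtype=float) for a in (velocity, position, pbest, gbest)
    )
    if not velocity.shape == position.shape == pbest.shape == gbest.shape:
        raise ValueError("velocity, position, pbest and gbest must share a shape")
    new_v = (
        config.w * velocity
        + config.c1 * np.asarray(r1) * (pbest - position)
        + config.c2 * np.asarray(r2) * (gbest - position)
    )
    if v_max is not None:
        new_v = np.clip(new_v, -v_max, v_max)
    return new_v


def update_position(
    position: np.ndarray,
    velocity: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Move a particle; positions leaving the bounds are reflected back in.

    Returns the new (position, velocity): a reflected component's velocity
    is negated so the particle heads back into the box.
    """
    position = np.asarray(position, dtype=float)
    velocity = np.asarray(velocity, dtype=float).copy()
    if position.shape != velocity.shape:
        raise ValueError("position and velocity must share a shape")
    new_pos = position + velocity
    if bounds is not None:
        low, high = bounds
        width = high - low
        for _ in range(64):  # repeated reflection for wildly out-of-range steps
            below = new_pos < low
            above = new_pos > high
            if not (below.any() or above.any()):
                break
            new_pos = np.where(below, 2 * low - new_pos, new_pos)
            new_pos = np.where(above, 2 * high - new_pos, new_pos)
            velocity = np.where(below | above, -velocity, velocity)
        np.clip(new_pos, low, high, out=new_pos)
    return new_pos, velocity


def pso_optimize(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    bounds: tuple[Sequence[float], Sequence[float]],
    config: PSOConfig | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize ``fitness`` over a box with a particle swarm.

    Returns ``(gbest, gbest_fitness, history)`` where ``history`` holds the
    swarm-best fitness after each iteration (non-increasing). Non-finite
    fitness values abort with a diagnostic.
    """
    config = config or PSOConfig()
    config.validate()
    if dim < 1:
        raise ValueError("dim must be >= 1")
    low = np.broadcast_to(np.asarray(bounds[0], dtype=float), (dim,)).copy()
    high = np.broadcast_to(np.asarray(bounds[1], dtype=float), (dim,)).copy()
    if not np.all(low < high):
        raise ValueError("bounds must satisfy low < high per dimension")
    v_max = config.v_max_fraction * (high - low)
    rng = np.random.default_rng(config.seed)

    def eval_fitness(x: np.ndarray) -> float:
        val = float(fitness(x))
        if not np.isfinite(val):
            raise FloatingPointError(f"fitness returned non-finite value {val} at {x}")
        return val

    particles: list[Particle] = []
    for _ in range(config.swarm_size):
        pos = rng.uniform(low, high)
        fit = eval_fitness(pos)
        particles.append(
            Particle(position=pos, velocity=np.zeros(dim), pbest=pos.copy(), pbest_fitness=fit)
        )
    best = min(particles, key=lambda p: p.pbest_fitness)
    state = SwarmState(particles, gbest=best.pbest.copy(), gbest_fitness=best.pbest_fitness)

    history: list[float] = []
    r_shape = (dim,) if config.per_dimension_r else ()
    for t in range(1, config.iterations + 1):
        for p in state.particles:
            r1 = rng.uniform(size=r_shape) if r_shape else rng.uniform()
            r2 = rng.uniform(size=r_shape) if r_shape else rng.uniform()
            p.velocity = update_velocity(
                p.velocity, p.position, p.pbest, state.gbest, config, r1, r2, v_max
            )
            p.position, p.velocity = update_position(p.position, p.velocity, (low, high))
            fit = eval_fitness(p.position)
            if fit < p.pbest_fitness:
                p.pbest = p.position.copy()
                p.pbest_fitness = fit
                if fit < state.gbest_fitness:
                    state.gbest = p.position.copy()
                    state.gbest_fitness = fit
        state.iteration = t
        history.append(state.gbest_fitness)
    return state.gbest, state.gbest_fitness, history


def pso_km(
    points: np.ndarray,
    k: int,
    pso_config: PSOConfig | None = None,
    km_max_iter: int = 300,
    km_tol: float = 1e-6,
) -> Partition:
    """Hybrid clustering: swarm search over centroid space, K-means polish.

    A particle encodes k concatenated centroids (length k*dim); the fitness
    is the clustering SSE; the box bounds are the per-feature data ranges
    tiled k times. The swarm's best centroid set then initializes a single
    K-means run, whose result is returned — refinement never increases the
    SSE, so the hybrid's final SSE is at most the swarm's.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    pso_config = pso_config or PSOConfig()
    dim = points.shape[1]
    low = np.tile(points.min(axis=0), k)
    high = np.tile(points.max(axis=0), k)
    # guard degenerate constant features so low < high holds
    flat = high <= low
    high[flat] = low[flat] + 1e-9

    def fitness(flat_pos: np.ndarray) -> float:
        return sse_objective(points, CentroidSet.from_flat(flat_pos, k))

    gbest, _, _ = pso_optimize(fitness, dim=k * dim, bounds=(low, high), config=pso_config)
    return kmeans(
        points,
        k,
        init=CentroidSet.from_flat(gbest, k),
        max_iter=km_max_iter,
        tol=km_tol,
    )
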