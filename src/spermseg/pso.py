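"""Particle swarm optimization of the four ICM parameters (f, g, h, n).

A global-best swarm searches the unit hypercube [0, 1]^4; a scaling map
turns each raw position into a valid parameter set (0 < g < f < 1, h < 0,
n in {1..n_max}).  Each evaluation runs the pulse network on the
LoG-filtered stimulus and scores the resulting mask by its
feature-mutual-information error against the original frame.  Velocities
follow the classic update

    v' = w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)

with a linearly decaying inertia w(t) = 0.9 - 0.5 t / t_max and per-
dimension clamping, and positions are clipped back into the unit box.
Personal and global bests are replaced only on strict improvement.  The
search stops once the best fitness reaches the configured tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spermseg.fitness import FitnessConfig, _entropy, _joint_counts, quantise
from spermseg.icm import ICMParams, run_icm

__all__ = [
    "Particle",
    "SwarmConfig",
    "OptimizationResult",
    "inertia",
    "scale_particle",
    "update_velocity",
    "update_position",
    "minimize",
    "optimize",
]

_DIM = 4  # f, g, h, n


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyper-parameters.

    population
        Number of particles (default 50).
    c1, c2
        Cognitive and social acceleration coefficients (default 2, 2).
    max_iterations
        Ceiling on swarm iterations after the initial evaluation.  The MI
        fitness typically converges within the first handful of
        iterations, so the ceiling mostly bounds the cost of frames whose
        best reachable error sits just above the stopping tolerance.
    v_max
        Per-dimension velocity clamp in the unit box.
    seed
        Seed for position/velocity initialisation and the r1, r2 draws.
    h_range
        (low, high) magnitudes mapped to the negative threshold amplitude.
    n_max
        Largest pulse-iteration count the scaling map can select.
    """

    population: int = 50
    c1: float = 2.0
    c2: float = 2.0
    max_iterations: int = 15
    v_max: float = 0.25
    seed: int = 0
    h_range: tuple[float, float] = (0.1, 10.0)
    n_max: int = 5

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError(f"population must be >= 1, got {self.population}")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration coefficients must be positive")
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        lo, hi = self.h_range
        if not (0 < lo <= hi):
            raise ValueError(f"h_range magnitudes must satisfy 0 < low <= high, got {self.h_range}")


@dataclass
class OptimizationResult:
    """Outcome of one per-image swarm run."""

    best_params: ICMParams
    best_fitness: float
    best_mask: np.ndarray
    best_mi: float
    evaluations_used: int
    convergence_trace: list[float]
    best_position: np.ndarray


def inertia(t: int, t_max: int) -> float:
    """Linearly decaying inertia weight: 0.9 at t=0 down to 0.4 at t=t_max."""
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration {t} outside [0, {t_max}]")
    return 0.9 - 0.5 * (t / t_max)


def scale_particle(position: np.ndarray, config: SwarmConfig = SwarmConfig()) -> ICMParams:
    """Map a raw [0,1]^4 position onto a valid ICM parameter set.

    f spans (0, 1) through [0.05, 0.99]; g is a fraction of f so g < f holds
    by construction; h is negative with magnitude in ``h_range``; n is an
    integer in {1, ..., n_max}.
    """
    p = np.clip(np.asarray(position, dtype=float), 0.0, 1.0)
    if p.shape != (_DIM,):
        raise ValueError(f"expected a 4-vector, got shape {p.shape}")
    f = 0.05 + 0.94 * p[0]
    g = f * (0.05 + 0.9 * p[1])
    h_lo, h_hi = config.h_range
    h = -(h_lo + p[2] * (h_hi - h_lo))
    n = 1 + int(round(p[3] * (config.n_max - 1)))
    return ICMParams(f=f, g=g, h=h, n_iterations=n)


def update_velocity(
    particle: Particle,
    gbest: np.ndarray,
    w: float,
    config: SwarmConfig,
    r1: np.ndarray,
    r2: np.ndarray,
) -> np.ndarray:
    v = (
        w * particle.velocity
        + config.c1 * r1 * (particle.pbest_position - particle.position)
        + config.c2 * r2 * (gbest - particle.position)
    )
    return np.clip(v, -config.v_max, config.v_max)


def update_position(position: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    return np.clip(position + velocity, 0.0, 1.0)


def minimize(
    objective,
    config: SwarmConfig,
    tolerance: float = 0.0,
) -> tuple[np.ndarray, float, int, list[float]]:
    """Run the swarm on an arbitrary objective over [0, 1]^4.

    Returns (gbest position, gbest fitness, evaluations used, per-iteration
    gbest trace).  The trace starts at the initial evaluation and is
    non-increasing by construction.
    """
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(0.0, 1.0, size=(config.population, _DIM))
    velocities = rng.uniform(-config.v_max, config.v_max, size=(config.population, _DIM))

    particles = [
        Particle(
            position=positions[i].copy(),
            velocity=velocities[i].copy(),
            pbest_position=positions[i].copy(),
            pbest_fitness=float("inf"),
        )
        for i in range(config.population)
    ]

    gbest_pos = particles[0].position.copy()
    gbest_fit = float("inf")
    evaluations = 0

    def evaluate_all() -> None:
        nonlocal gbest_pos, gbest_fit, evaluations
        for part in particles:
            fit = float(objective(part.position))
            evaluations += 1
            if fit < part.pbest_fitness:
                part.pbest_fitness = fit
                part.pbest_position = part.position.copy()
            if fit < gbest_fit:
                gbest_fit = fit
                gbest_pos = part.position.copy()

    evaluate_all()
    trace = [gbest_fit]
    for t in range(1, config.max_iterations + 1):
        if gbest_fit <= tolerance:
            break
        w = inertia(t - 1, config.max_iterations)
        r1 = rng.uniform(0.0, 1.0, size=(config.population, _DIM))
        r2 = rng.uniform(0.0, 1.0, size=(config.population, _DIM))
        for i, part in enumerate(particles):
            part.velocity = update_velocity(part, gbest_pos, w, config, r1[i], r2[i])
            part.position = update_position(part.position, part.velocity)
        evaluate_all()
        trace.append(gbest_fit)
    return gbest_pos, gbest_fit, evaluations, trace


def optimize(
    image: np.ndarray,
    s_image: np.ndarray,
    config: SwarmConfig = SwarmConfig(),
    fitness_config: FitnessConfig = FitnessConfig(),
) -> OptimizationResult:
    """Tune (f, g, h, n) for one frame.

    ``image`` is the original grayscale frame (the X of the MI fitness);
    ``s_image`` its LoG-filtered stimulus driving the pulse network.
    """
    image = np.asarray(image, dtype=float)
    s_image = np.asarray(s_image, dtype=float)
    if image.shape != s_image.shape:
        raise ValueError(f"frame {image.shape} and stimulus {s_image.shape} differ")

    bins = fitness_config.intensity_bins
    x_idx = quantise(image, bins)
    hx = _entropy(np.bincount(x_idx.ravel(), minlength=bins) / x_idx.size)

    def mi_of_mask(mask: np.ndarray) -> float:
        counts = _joint_counts(x_idx, mask, bins)
        total = counts.sum()
        hy = _entropy(counts.sum(axis=0) / total)
        hxy = _entropy(counts.ravel() / total)
        return max(hx + hy - hxy, 0.0)

    def objective(position: np.ndarray) -> float:
        params = scale_particle(position, config)
        mask, _ = run_icm(s_image, params)
        return abs(mi_of_mask(mask) - fitness_config.mi_target)

    gbest_pos, gbest_fit, evaluations, trace = minimize(
        objective, config, tolerance=fitness_config.tolerance
    )

    best_params = scale_particle(gbest_pos, config)
    best_mask, _ = run_icm(s_image, best_params)
    return OptimizationResult(
        best_params=best_params,
        best_fitness=gbest_fit,
        best_mask=best_mask,
        best_mi=mi_of_mask(best_mask),
        evaluations_used=evaluations,
        convergence_trace=trace,
        best_position=gbest_pos,
    )
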