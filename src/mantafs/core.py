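"""Swarm state and the optimization loops.

Two engines live here, both minimizing a mask-valued objective:

* :func:`run_bpso_mrfl` — binary PSO with manta-ray foraging learning.  Each
  iteration every particle draws a branch uniform: with probability 1/2 it
  enters cyclone learning (which itself picks between a random-reference
  exploration step, more likely early when ``t/T`` is small, and a
  global-best exploitation step), otherwise chain learning, where a particle's
  cognitive attractor is the personal best of the particle directly ahead of
  it in fixed index order.  After the main phase the whole swarm performs a
  somersault resampling pivoting around the global best.  Two evaluation
  sweeps per iteration: ``N + 2*N*T`` objective calls in total.

* :func:`run_bpso_baseline` — classic global-best BPSO (constant learning
  factors 2, linearly decreasing inertia) with either the S-shaped or the
  V-shaped transfer function.  One evaluation sweep per iteration.

The objective is any callable ``mask -> FitnessRecord``; in normal use it is
a :class:`~mantafs.fitness.MaskEvaluator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fitness import FitnessRecord
from .strategies import (
    binarize_sshape,
    binarize_vshape,
    chain_coefficients,
    cyclone_coefficients,
    inertia_weight,
    random_reference,
    somersault_update,
    velocity_update,
)

__all__ = [
    "SwarmConfig",
    "Particle",
    "Swarm",
    "RunResult",
    "init_swarm",
    "update_bests",
    "run_bpso_mrfl",
    "run_bpso_baseline",
]

Objective = Callable[[np.ndarray], FitnessRecord]


@dataclass
class SwarmConfig:
    """Optimizer parameters (defaults follow the standard configuration:
    N=20 particles, T=100 iterations, inertia 0.9→0.4, cyclone-random
    constants 2)."""

    n_particles: int = 20
    n_iterations: int = 100
    w_max: float = 0.9
    w_min: float = 0.4
    c5: float = 2.0
    c6: float = 2.0
    v_clamp: float = 6.0
    branch_threshold: float = 0.5
    per_dimension_random: bool = True

    def validate(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not 0 <= self.w_min <= self.w_max:
            raise ValueError("require 0 <= w_min <= w_max")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = np.inf
    pbest_record: FitnessRecord | None = None


@dataclass
class Swarm:
    """Index-ordered particle list; the order defines the foraging chain and
    is never re-sorted."""

    particles: list[Particle]
    gbest_position: np.ndarray | None = None
    gbest_fitness: float = np.inf
    gbest_record: FitnessRecord | None = None
    t: int = 0

    def __len__(self) -> int:
        return len(self.particles)


@dataclass
class RunResult:
    """Outcome of one optimizer run."""

    best_mask: np.ndarray
    best_fitness: float
    best_error: float
    subset_size: int
    fitness_trace: np.ndarray
    evaluations_used: int
    seed: int | None = None


def init_swarm(config: SwarmConfig, D: int, rng: np.random.Generator) -> Swarm:
    """Fresh swarm: each position bit is 1 iff a uniform draw is < 0.5 and each
    velocity entry is uniform in [-1, 1]; personal bests start at the initial
    positions (unevaluated, fitness +inf)."""
    config.validate()
    if D < 1:
        raise ValueError("D must be >= 1")
    particles = []
    for _ in range(config.n_particles):
        bits = (rng.random(D) < 0.5).astype(np.int8)
        vel = rng.uniform(-1.0, 1.0, size=D)
        particles.append(Particle(bits, vel, bits.copy()))
    return Swarm(particles)


def update_bests(swarm: Swarm, records: list[FitnessRecord]) -> Swarm:
    """Replace personal bests on strict improvement, then set the global best
    to the minimum personal best (ties to the lowest particle index)."""
    if len(records) != len(swarm.particles):
        raise ValueError("need exactly one fitness record per particle")
    for p, rec in zip(swarm.particles, records):
        if rec is None:
            raise ValueError("missing fitness record")
        if rec.fitness < p.pbest_fitness:
            p.pbest_fitness = rec.fitness
            p.pbest_position = p.position.copy()
            p.pbest_record = rec
    best_i = int(np.argmin([p.pbest_fitness for p in swarm.particles]))
    best = swarm.particles[best_i]
    if best.pbest_fitness < swarm.gbest_fitness or swarm.gbest_position is None:
        swarm.gbest_fitness = best.pbest_fitness
        swarm.gbest_position = best.pbest_position.copy()
        swarm.gbest_record = best.pbest_record
    return swarm


def _evaluate_swarm(swarm: Swarm, objective: Objective) -> None:
    records = [objective(p.position) for p in swarm.particles]
    update_bests(swarm, records)


def _result(swarm: Swarm, trace: list[float], n_evals: int, seed: int | None) -> RunResult:
    rec = swarm.gbest_record
    return RunResult(
        best_mask=swarm.gbest_position.copy(),
        best_fitness=swarm.gbest_fitness,
        best_error=rec.error if rec is not None else float("nan"),
        subset_size=int(swarm.gbest_position.sum()),
        fitness_trace=np.asarray(trace),
        evaluations_used=n_evals,
        seed=seed,
    )


def run_bpso_mrfl(
    objective: Objective,
    D: int,
    config: SwarmConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RunResult:
    """Full manta-ray-learning BPSO loop (see module docstring).

    ``objective`` maps a 0/1 mask of length ``D`` to a FitnessRecord and is
    called exactly ``N + 2*N*T`` times.  The returned trace holds the global
    best fitness after initialization and after each of the ``T`` iterations
    and is non-increasing by construction.
    """
    config = config or SwarmConfig()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    swarm = init_swarm(config, D, rng)
    evals = _CountingObjective(objective)
    _evaluate_swarm(swarm, evals)
    trace = [swarm.gbest_fitness]

    T = config.n_iterations
    per_dim = config.per_dimension_random
    for t in range(1, T + 1):
        swarm.t = t
        w = inertia_weight(t, T, config.w_max, config.w_min)
        c1, c2 = chain_coefficients(t, T)
        c3, c4 = cyclone_coefficients(t, T)
        gbest = swarm.gbest_position
        front = [p.pbest_position for p in swarm.particles]  # pre-iteration pbests
        for i, p in enumerate(swarm.particles):
            attractor = front[i] if i == 0 else front[i - 1]
            if rng.random() < config.branch_threshold:  # cyclone learning
                if t / T < rng.random():  # random-reference exploration
                    reference = random_reference(D, rng)
                    a, b = config.c5, config.c6
                else:  # global-best exploitation
                    reference, a, b = gbest, c3, c4
            else:  # chain learning
                reference, a, b = gbest, c1, c2
            p.velocity = velocity_update(
                p.position, p.velocity, attractor, reference, w, a, b,
                rng=rng, v_clamp=config.v_clamp, per_dimension=per_dim,
            )
            p.position = binarize_vshape(p.position, p.velocity, rng=rng)
        _evaluate_swarm(swarm, evals)

        gbest = swarm.gbest_position
        for p in swarm.particles:  # somersault: unconditional replacement
            p.position = somersault_update(p.pbest_position, gbest, rng=rng, per_dimension=per_dim)
        _evaluate_swarm(swarm, evals)
        trace.append(swarm.gbest_fitness)

    return _result(swarm, trace, evals.n_calls, seed)


def run_bpso_baseline(
    objective: Objective,
    D: int,
    config: SwarmConfig | None = None,
    rng: np.random.Generator | int | None = None,
    transfer: str = "s",
) -> RunResult:
    """Classic global-best BPSO with constant learning factors c1 = c2 = 2,
    linearly decreasing inertia, and an S- or V-shaped transfer function.
    ``N + N*T`` objective calls."""
    if transfer not in ("s", "v"):
        raise ValueError("transfer must be 's' or 'v'")
    config = config or SwarmConfig()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    swarm = init_swarm(config, D, rng)
    evals = _CountingObjective(objective)
    _evaluate_swarm(swarm, evals)
    trace = [swarm.gbest_fitness]

    T = config.n_iterations
    per_dim = config.per_dimension_random
    for t in range(1, T + 1):
        swarm.t = t
        w = inertia_weight(t, T, config.w_max, config.w_min)
        gbest = swarm.gbest_position
        for p in swarm.particles:
            p.velocity = velocity_update(
                p.position, p.velocity, p.pbest_position, gbest, w, 2.0, 2.0,
                rng=rng, v_clamp=config.v_clamp, per_dimension=per_dim,
            )
            if transfer == "s":
                p.position = binarize_sshape(p.velocity, rng=rng)
            else:
                p.position = binarize_vshape(p.position, p.velocity, rng=rng)
        _evaluate_swarm(swarm, evals)
        trace.append(swarm.gbest_fitness)

    return _result(swarm, trace, evals.n_calls, seed)


class _CountingObjective:
    """Counts objective calls without disturbing memoization in the callee."""

    def __init__(self, objective: Objective) -> None:
        self._objective = objective
        self.n_calls = 0

    def __call__(self, mask: np.ndarray) -> FitnessRecord:
        self.n_calls += 1
        return self._objective(mask)
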