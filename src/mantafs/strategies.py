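"""Velocity/position update rules for the manta-ray learning strategies.

This module is the pure computation layer of the optimizer: the time-varying
coefficient schedules, the three velocity update modes (chain, cyclone with a
global-best reference, cyclone with a random reference), the somersault
position resampling, and the two transfer functions that map real velocities
back into the binary search space.

Conventions
-----------
Positions and personal/global bests are 0/1 integer vectors of length ``D``
(one bit per candidate feature).  Velocities are real vectors of the same
length, clamped to ``[-v_clamp, +v_clamp]``.  All random draws come from a
caller-supplied :class:`numpy.random.Generator`; every function also accepts
explicit draw arrays so that single updates can be checked by hand.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "inertia_weight",
    "chain_coefficients",
    "cyclone_coefficients",
    "random_reference",
    "velocity_update",
    "binarize_vshape",
    "binarize_sshape",
    "somersault_update",
]

#: Somersault range factor; the pivoting step spans twice the pbest-to-gbest gap.
SOMERSAULT_FACTOR = 2.0


def inertia_weight(t: int, T: int, w_max: float = 0.9, w_min: float = 0.4) -> float:
    """Linearly decreasing inertia weight ``w(t) = w_max - (w_max - w_min) * t/T``.

    At ``t = 0`` this is ``w_max`` and at ``t = T`` it is ``w_min``.  A zero
    iteration budget (``T = 0``) degenerates to ``w_max``.
    """
    if T == 0:
        return w_max
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, T={T}]")
    if not 0 <= w_min <= w_max:
        raise ValueError("require 0 <= w_min <= w_max")
    return w_max - (w_max - w_min) * (t / T)


def chain_coefficients(t: int, T: int) -> tuple[float, float]:
    """Chain-learning factors ``c1 = 2*erf(0.5 - t/T)``, ``c2 = 3*erf(1.7 - t/T)``.

    ``c1`` weighs the pull toward the particle ahead in the foraging chain
    (or the particle's own best, for the chain head); ``c2`` weighs the pull
    toward the global best.  Both decay monotonically with ``t``; ``c1``
    changes sign at the half-way point ``t/T = 0.5``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    frac = t / T
    return 2.0 * float(erf(0.5 - frac)), 3.0 * float(erf(1.7 - frac))


def cyclone_coefficients(t: int, T: int) -> tuple[float, float]:
    """Cyclone-learning factors: ``c3`` mirrors ``c2`` and ``c4`` mirrors ``c1``.

    The cyclone phase swaps the schedule roles — the large, slowly decaying
    factor multiplies the chain-neighbour term and the sign-changing factor
    multiplies the reference term — so ``c3(t) > c4(t)`` throughout a run.
    """
    c1, c2 = chain_coefficients(t, T)
    return c2, c1


def random_reference(
    D: int,
    rng: np.random.Generator,
    low: float = 0.0,
    high: float = 1.0,
) -> np.ndarray:
    """A fresh random reference position in the (relaxed) search space.

    Entries are ``low + u * (high - low)`` with iid uniform ``u``.  For the
    binary feature space the bounds are ``[0, 1]``; the reference is kept
    continuous because it only ever enters a velocity difference.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    return low + rng.random(D) * (high - low)


def velocity_update(
    x: np.ndarray,
    v: np.ndarray,
    attractor: np.ndarray,
    reference: np.ndarray,
    w: float,
    c_attractor: float,
    c_reference: float,
    rng: np.random.Generator | None = None,
    v_clamp: float = 6.0,
    r1: np.ndarray | float | None = None,
    r2: np.ndarray | float | None = None,
    per_dimension: bool = True,
) -> np.ndarray:
    """One velocity update ``v' = w*v + c_a*r1*(attractor - x) + c_b*r2*(reference - x)``.

    Parameters
    ----------
    x, v
        Current position (bits) and velocity.
    attractor
        Cognitive pull: the particle's own personal best for the chain head,
        otherwise the personal best of the particle directly ahead.
    reference
        Social pull: the global best (chain and exploitative cyclone) or a
        continuous random reference (explorative cyclone).
    w, c_attractor, c_reference
        Inertia weight and the coefficient pair for the active mode.
    r1, r2
        Optional explicit uniform draws in [0, 1]; drawn from ``rng`` when
        omitted (per dimension by default, scalar if ``per_dimension`` is
        False).
    v_clamp
        Symmetric velocity bound applied after the update.

    Returns
    -------
    numpy.ndarray
        The clamped new velocity.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    attractor = np.asarray(attractor, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if not (x.shape == v.shape == attractor.shape == reference.shape):
        raise ValueError("position, velocity, attractor and reference must share length D")
    if r1 is None or r2 is None:
        if rng is None:
            raise ValueError("rng is required when r1/r2 are not given")
        size = x.shape[0] if per_dimension else None
        r1 = rng.random(size) if r1 is None else r1
        r2 = rng.random(size) if r2 is None else r2
    v_new = w * v + c_attractor * np.asarray(r1) * (attractor - x) + c_reference * np.asarray(r2) * (reference - x)
    return np.clip(v_new, -v_clamp, v_clamp)


def binarize_vshape(
    x: np.ndarray,
    v: np.ndarray,
    rng: np.random.Generator | None = None,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """V-shaped transfer: flip bit ``j`` with probability ``tanh(|v_j|)``.

    The magnitude of the velocity, not its sign, drives the flip probability;
    a zero velocity leaves the bit untouched, so this rule is the identity map
    at ``v = 0``.  ``u`` may supply the uniform draws explicitly.
    """
    x = np.asarray(x)
    v = np.asarray(v, dtype=float)
    if x.shape != v.shape:
        raise ValueError("position and velocity must share length D")
    if u is None:
        if rng is None:
            raise ValueError("rng is required when u is not given")
        u = rng.random(x.shape[0])
    tf = np.tanh(np.abs(v))
    flip = np.asarray(u) < tf
    return np.where(flip, 1 - x, x).astype(np.int8)


def binarize_sshape(
    v: np.ndarray,
    rng: np.random.Generator | None = None,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """S-shaped transfer: set bit ``j`` to 1 with probability ``sigmoid(v_j)``.

    Used by the classic BPSO baseline.  Unlike the V-shaped rule the new bit
    is independent of the previous position, which is what makes plain BPSO
    drift near convergence (a zero velocity still rewrites the bit at random).
    """
    v = np.asarray(v, dtype=float)
    if u is None:
        if rng is None:
            raise ValueError("rng is required when u is not given")
        u = rng.random(v.shape[0])
    with np.errstate(over="ignore"):
        tf = 1.0 / (1.0 + np.exp(-v))
    return (np.asarray(u) < tf).astype(np.int8)


def somersault_update(
    pbest: np.ndarray,
    gbest: np.ndarray,
    rng: np.random.Generator | None = None,
    r1: np.ndarray | float | None = None,
    r2: np.ndarray | float | None = None,
    per_dimension: bool = True,
) -> np.ndarray:
    """Somersault resampling pivoting around the global best.

    Computes ``x_new = pbest + 2*r1*(gbest - r2*pbest)`` with fresh uniform
    draws and thresholds at 0.5 (``> 0.5`` maps to 1, everything else —
    including exactly 0.5 — to 0, biasing ties toward smaller subsets).

    Where ``pbest`` and ``gbest`` agree the output bit equals the shared value
    for any draws: agreeing 1-bits give ``1 + 2*r1*(1 - r2) >= 1`` and agreeing
    0-bits give 0, so consensus coordinates are a fixed point and only the
    disagreements are renegotiated.
    """
    pbest = np.asarray(pbest, dtype=float)
    gbest = np.asarray(gbest, dtype=float)
    if pbest.shape != gbest.shape:
        raise ValueError("pbest and gbest must share length D")
    if r1 is None or r2 is None:
        if rng is None:
            raise ValueError("rng is required when r1/r2 are not given")
        size = pbest.shape[0] if per_dimension else None
        r1 = rng.random(size) if r1 is None else r1
        r2 = rng.random(size) if r2 is None else r2
    x_new = pbest + SOMERSAULT_FACTOR * np.asarray(r1) * (gbest - np.asarray(r2) * pbest)
    return (x_new > 0.5).astype(np.int8)
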