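"""Immediate reward rules for the escort, swarm and locomotion tasks.

Rewards are pure functions of the limited-perception indicators (plus the
last applied force for the energy term).  The magnitudes are configurable;
only their ordering is structural: ``r_target > r_pursuit > 0 > r_recede``
and ``r_intrude < 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perception import EscortObservation, LocomotionObservation, SwarmObservation

__all__ = [
    "RewardConstants",
    "reward_escort",
    "reward_swarm",
    "reward_locomotion",
    "reward_swarm_batch",
]


@dataclass
class RewardConstants:
    r_target: float = 1.0
    r_pursuit: float = 0.1
    r_recede: float = -0.1
    r_intrude: float = -0.5
    c_energy: float = 0.1

    def __post_init__(self) -> None:
        if not (self.r_target > self.r_pursuit > 0.0 > self.r_recede):
            raise ValueError("reward ordering must satisfy r_target > r_pursuit > 0 > r_recede")
        if self.r_intrude >= 0.0:
            raise ValueError("r_intrude must be negative")
        if self.c_energy < 0.0:
            raise ValueError("c_energy must be non-negative")


def reward_escort(obs: EscortObservation, k: RewardConstants) -> float:
    """In the band -> r_target; else approaching -> r_pursuit; else r_recede."""
    if obs.S_d:
        return k.r_target
    if obs.S_a:
        return k.r_pursuit
    return k.r_recede


def reward_swarm(obs: SwarmObservation, k: RewardConstants) -> float:
    """Group-centre escort reward with an additive comfort-zone penalty."""
    if obs.S_gc:
        base = k.r_target
    elif obs.S_ga:
        base = k.r_pursuit
    else:
        base = k.r_recede
    if obs.S_cz:
        base += k.r_intrude
    return base


def reward_swarm_batch(
    S_cz: np.ndarray, S_ca: np.ndarray, S_gc: np.ndarray, S_ga: np.ndarray, k: RewardConstants
) -> np.ndarray:
    """Vectorized :func:`reward_swarm` over per-agent indicator arrays."""
    base = np.where(S_gc > 0, k.r_target, np.where(S_ga > 0, k.r_pursuit, k.r_recede))
    return base + np.where(S_cz > 0, k.r_intrude, 0.0)


def reward_locomotion(obs: LocomotionObservation, k: RewardConstants) -> float:
    """Leader-distance escort reward, comfort-zone penalty, energy cost.

    The quadratic energy penalty is only active in the settled state
    (inside the target distance with an empty comfort zone).
    """
    if obs.S_d:
        base = k.r_target
        if not obs.S_cz:
            base -= k.c_energy * float(np.dot(obs.last_force, obs.last_force))
    elif obs.S_ca:
        base = k.r_pursuit
    else:
        base = k.r_recede
    if obs.S_cz:
        base += k.r_intrude
    return base
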