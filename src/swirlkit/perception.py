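"""Limited-perception observation encodings.

Agents never see absolute coordinates.  What they perceive is a handful of
binary indicators (inside/outside a distance band, approaching/receding),
unit direction vectors, and their own last applied force.  All indicator
conventions are fixed here once:

* Heaviside boundary: ``H(0) = 1`` (the band boundary counts as inside);
* approach indicators use a backward difference of distances and are 0 on
  the first step of an episode;
* the direction of a (near-)zero vector is the sentinel ``(0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kinematics import AgentKinematics, EnvConfig, Vec2

__all__ = [
    "EscortObservation",
    "SwarmObservation",
    "LocomotionObservation",
    "band_indicator",
    "radius_indicator",
    "approach_indicator",
    "unit_dir",
    "nearest_neighbor",
    "perceived_indices",
    "group_stats",
    "encode_escort",
    "encode_swarm",
    "encode_swarm_batch",
    "encode_locomotion",
    "ESCORT_DIM",
    "SWARM_DIM",
    "locomotion_dim",
]

_EPS_DIR = 1e-12

ESCORT_DIM = 8
SWARM_DIM = 12


def locomotion_dim(n_followers: int) -> int:
    """State length for the locomotion task with ``n_followers`` followers."""
    return 9 + 4 * (n_followers - 1)


def band_indicator(distance: float, d_t: float, e_t: float) -> float:
    """H(e_t - |d_t - distance|): 1 inside the band [d_t-e_t, d_t+e_t]."""
    if e_t <= 0:
        raise ValueError("e_t must be positive")
    return 1.0 if e_t - abs(d_t - distance) >= 0.0 else 0.0


def radius_indicator(distance: float, d_t: float) -> float:
    """H(d_t - distance): 1 inside the disk of radius d_t (boundary inside)."""
    return 1.0 if d_t - distance >= 0.0 else 0.0


def approach_indicator(dist_now: float, dist_prev: Optional[float]) -> float:
    """1 iff the distance strictly decreased since the previous step.

    ``dist_prev is None`` marks the first step of an episode and yields 0,
    as does an exact tie (the discretized -d/dt is then 0).
    """
    if dist_prev is None:
        return 0.0
    return 1.0 if dist_now < dist_prev else 0.0


def unit_dir(v: Vec2) -> Vec2:
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(v[0], v[1]))
    if n <= _EPS_DIR:
        return np.zeros(2)
    return v / n


def nearest_neighbor(i: int, positions: np.ndarray, R_p: float = np.inf) -> Optional[int]:
    """Index of the closest other agent within radius ``R_p`` of agent ``i``.

    Ties break toward the lowest index; returns ``None`` when no other agent
    lies within the perception zone.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        raise ValueError("nearest_neighbor needs at least 2 agents")
    d = np.linalg.norm(positions - positions[i], axis=1)
    d[i] = np.inf
    j = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    if d[j] > R_p:
        return None
    return j


def perceived_indices(i: int, positions: np.ndarray, R_p: float) -> np.ndarray:
    """Indices of agents agent ``i`` can perceive: itself plus all within R_p."""
    positions = np.asarray(positions, dtype=float)
    d = np.linalg.norm(positions - positions[i], axis=1)
    mask = d <= R_p
    mask[i] = True
    return np.flatnonzero(mask)


def group_stats(positions: np.ndarray, velocities: np.ndarray) -> tuple[Vec2, Vec2]:
    """Arithmetic mean position and velocity of the supplied (perceived) agents."""
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if positions.shape[0] == 0:
        raise ValueError("group_stats requires at least one perceived agent")
    return positions.mean(axis=0), velocities.mean(axis=0)


# ---------------------------------------------------------------------------
# Observation containers


@dataclass
class EscortObservation:
    """8-component escort state: (S_d, S_a, leader dir, self dir, last force)."""

    S_d: float
    S_a: float
    leader_dir: Vec2
    self_dir: Vec2
    last_force: Vec2

    def vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.S_d, self.S_a], self.leader_dir, self.self_dir, self.last_force]
        )


@dataclass
class SwarmObservation:
    """12-component swarm state.

    Order: (S_cz, S_ca, S_gc, S_ga, neighbor dir, self dir, last force,
    group-velocity dir).
    """

    S_cz: float
    S_ca: float
    S_gc: float
    S_ga: float
    neighbor_dir: Vec2
    self_dir: Vec2
    last_force: Vec2
    group_dir: Vec2

    def vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.S_cz, self.S_ca, self.S_gc, self.S_ga],
                self.neighbor_dir,
                self.self_dir,
                self.last_force,
                self.group_dir,
            ]
        )


@dataclass
class LocomotionObservation:
    """High-perception locomotion state for one follower.

    Order: relative leader position, relative positions of the other
    followers (by index), self velocity, relative velocities of the other
    followers, last force, then (S_cz, S_ca, S_d).
    """

    rel_leader: Vec2
    rel_others: np.ndarray  # (n_followers-1, 2)
    self_velocity: Vec2
    rel_velocities: np.ndarray  # (n_followers-1, 2)
    last_force: Vec2
    S_cz: float
    S_ca: float
    S_d: float

    def vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.rel_leader,
                self.rel_others.ravel(),
                self.self_velocity,
                self.rel_velocities.ravel(),
                self.last_force,
                [self.S_cz, self.S_ca, self.S_d],
            ]
        )


# ---------------------------------------------------------------------------
# Encoders


def encode_escort(
    leader_pos: Vec2,
    leader_vel: Vec2,
    follower: AgentKinematics,
    prev_dist: Optional[float],
    cfg: EnvConfig,
) -> tuple[EscortObservation, float]:
    """Encode the follower's view; returns (observation, current distance)."""
    dist = float(np.linalg.norm(np.asarray(leader_pos) - follower.position))
    obs = EscortObservation(
        S_d=band_indicator(dist, cfg.d_t, cfg.e_t),
        S_a=approach_indicator(dist, prev_dist),
        leader_dir=unit_dir(leader_vel),
        self_dir=unit_dir(follower.velocity),
        last_force=np.asarray(follower.last_force, dtype=float).copy(),
    )
    return obs, dist


def encode_swarm(
    i: int,
    positions: np.ndarray,
    velocities: np.ndarray,
    last_forces: np.ndarray,
    prev_nn_dist: Optional[float],
    prev_gc_dist: Optional[float],
    cfg: EnvConfig,
) -> tuple[SwarmObservation, float, float]:
    """Encode agent ``i``'s limited view of the swarm.

    Under a finite perception radius the "group" is the perceived subset
    including the agent itself.  Returns (observation, nn distance, distance
    to the perceived group centre) -- the distances feed the next step's
    approach indicators.
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    j = nearest_neighbor(i, positions, cfg.R_p)
    if j is None:
        nn_dist = np.inf
        S_cz = 0.0
        neighbor_dir = np.zeros(2)
    else:
        nn_dist = float(np.linalg.norm(positions[i] - positions[j]))
        S_cz = radius_indicator(nn_dist, cfg.d_cz)
        neighbor_dir = unit_dir(velocities[j])
    idx = perceived_indices(i, positions, cfg.R_p)
    x_gc, v_gc = group_stats(positions[idx], velocities[idx])
    gc_dist = float(np.linalg.norm(positions[i] - x_gc))
    obs = SwarmObservation(
        S_cz=S_cz,
        S_ca=approach_indicator(nn_dist, prev_nn_dist),
        S_gc=radius_indicator(gc_dist, cfg.d_t),
        S_ga=approach_indicator(gc_dist, prev_gc_dist),
        neighbor_dir=neighbor_dir,
        self_dir=unit_dir(velocities[i]),
        last_force=np.asarray(last_forces[i], dtype=float).copy(),
        group_dir=unit_dir(v_gc),
    )
    return obs, nn_dist, gc_dist


def encode_swarm_batch(
    positions: np.ndarray,
    velocities: np.ndarray,
    last_forces: np.ndarray,
    prev_nn_dist: Optional[np.ndarray],
    prev_gc_dist: Optional[np.ndarray],
    cfg: EnvConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`encode_swarm` for all N agents at once.

    ``positions`` etc. may carry a leading batch dimension (B, N, 2) for
    simulating several independent swarms simultaneously; without it the
    shapes are (N, 2) and the outputs are (N, 12), (N,), (N,).  Must agree
    elementwise with the scalar encoder (tested).
    """
    positions = np.asarray(positions, dtype=float)
    single = positions.ndim == 2
    if single:
        positions = positions[None]
        velocities = np.asarray(velocities, dtype=float)[None]
        last_forces = np.asarray(last_forces, dtype=float)[None]
        prev_nn_dist = None if prev_nn_dist is None else np.asarray(prev_nn_dist)[None]
        prev_gc_dist = None if prev_gc_dist is None else np.asarray(prev_gc_dist)[None]
    else:
        velocities = np.asarray(velocities, dtype=float)
        last_forces = np.asarray(last_forces, dtype=float)
    B, N, _ = positions.shape

    diff = positions[:, :, None, :] - positions[:, None, :, :]
    dmat = np.sqrt(np.einsum("bijk,bijk->bij", diff, diff))
    ii = np.arange(N)
    dmat[:, ii, ii] = np.inf

    nn = np.argmin(dmat, axis=2)  # (B, N); first index wins ties
    bb = np.arange(B)[:, None]
    nn_dist = dmat[bb, ii[None, :], nn]
    has_nn = nn_dist <= cfg.R_p

    speeds = np.sqrt(np.einsum("bij,bij->bi", velocities, velocities))
    safe = np.maximum(speeds, _EPS_DIR)[..., None]
    vel_dirs = np.where(speeds[..., None] > _EPS_DIR, velocities / safe, 0.0)

    neighbor_dir = np.where(has_nn[..., None], np.take_along_axis(vel_dirs, nn[..., None], axis=1), 0.0)
    S_cz = np.where(has_nn & (cfg.d_cz - nn_dist >= 0.0), 1.0, 0.0)

    # perceived-subset group stats (self always included)
    if np.isinf(cfg.R_p):
        x_gc = np.broadcast_to(positions.mean(axis=1, keepdims=True), positions.shape)
        v_gc = np.broadcast_to(velocities.mean(axis=1, keepdims=True), velocities.shape)
    else:
        percep = dmat <= cfg.R_p
        percep[:, ii, ii] = True
        counts = percep.sum(axis=2)
        x_gc = np.einsum("bij,bjk->bik", percep, positions) / counts[..., None]
        v_gc = np.einsum("bij,bjk->bik", percep, velocities) / counts[..., None]
    gc_off = positions - x_gc
    gc_dist = np.sqrt(np.einsum("bij,bij->bi", gc_off, gc_off))
    S_gc = np.where(cfg.d_t - gc_dist >= 0.0, 1.0, 0.0)

    v_gc_norm = np.sqrt(np.einsum("bij,bij->bi", v_gc, v_gc))
    group_dir = np.where(
        v_gc_norm[..., None] > _EPS_DIR, v_gc / np.maximum(v_gc_norm, _EPS_DIR)[..., None], 0.0
    )

    S_ca = np.zeros((B, N)) if prev_nn_dist is None else (nn_dist < prev_nn_dist).astype(float)
    S_ga = np.zeros((B, N)) if prev_gc_dist is None else (gc_dist < prev_gc_dist).astype(float)

    obs = np.concatenate(
        [
            S_cz[..., None],
            S_ca[..., None],
            S_gc[..., None],
            S_ga[..., None],
            neighbor_dir,
            vel_dirs,
            last_forces,
            group_dir,
        ],
        axis=2,
    )
    nn_dist_out = np.where(has_nn, nn_dist, np.inf)
    if single:
        return obs[0], nn_dist_out[0], gc_dist[0]
    return obs, nn_dist_out, gc_dist


def encode_locomotion(
    i: int,
    leader_pos: Vec2,
    positions: np.ndarray,
    velocities: np.ndarray,
    last_forces: np.ndarray,
    prev_nn_dist: Optional[float],
    cfg: EnvConfig,
) -> tuple[LocomotionObservation, float]:
    """Encode follower ``i``'s view in the locomotion task.

    ``positions``/``velocities`` hold the followers only (leader excluded);
    relative quantities are ordered by follower index, skipping self.
    Returns (observation, nearest-neighbour distance).
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    n = positions.shape[0]
    others = [j for j in range(n) if j != i]
    rel_others = positions[others] - positions[i]
    rel_vels = velocities[others] - velocities[i]

    if n >= 2:
        j = nearest_neighbor(i, positions, np.inf)
        nn_dist = float(np.linalg.norm(positions[i] - positions[j]))
        S_cz = radius_indicator(nn_dist, cfg.d_cz)
    else:
        nn_dist = np.inf
        S_cz = 0.0
    leader_dist = float(np.linalg.norm(np.asarray(leader_pos) - positions[i]))
    obs = LocomotionObservation(
        rel_leader=np.asarray(leader_pos, dtype=float) - positions[i],
        rel_others=rel_others,
        self_velocity=velocities[i].copy(),
        rel_velocities=rel_vels,
        last_force=np.asarray(last_forces[i], dtype=float).copy(),
        S_cz=S_cz,
        S_ca=approach_indicator(nn_dist, prev_nn_dist),
        S_d=radius_indicator(leader_dist, cfg.d_t),
    )
    return obs, nn_dist
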