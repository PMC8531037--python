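"""2D kinematics of agents: action limits, Euler stepping, leader trajectories.

Agents move in an inert plane.  Three control regimes are supported:

* mode ``A`` -- the action is a velocity, bounded in norm by ``v_max``;
* mode ``B`` -- the action is a velocity, bounded by ``v_max``, and the
  implied acceleration is capped at ``a_max``;
* mode ``C`` -- the action is a force (unit agent mass, so force equals
  acceleration), bounded in norm by ``F_max``.  This is the regime used by
  the swarm and locomotion tasks.

The integration scheme is semi-implicit Euler: the velocity is updated
first, then the position advances with the *new* velocity.  The scheme is
fixed and documented so trajectories are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "Vec2",
    "AgentKinematics",
    "EnvConfig",
    "LeaderPath",
    "leader_position",
    "clip_action",
    "step",
]

#: 2-component float array; used for positions, velocities and forces.
Vec2 = np.ndarray

_ZERO2 = np.zeros(2)


def _as_vec2(v, name: str = "vector") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"{name} must have shape (2,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values: {arr}")
    return arr


@dataclass
class AgentKinematics:
    """Position, velocity and the most recent applied force of one agent."""

    position: Vec2
    velocity: Vec2
    last_force: Vec2 = field(default_factory=lambda: _ZERO2.copy())

    def __post_init__(self) -> None:
        self.position = _as_vec2(self.position, "position")
        self.velocity = _as_vec2(self.velocity, "velocity")
        self.last_force = _as_vec2(self.last_force, "last_force")


@dataclass
class EnvConfig:
    """Scalar knobs of the escort / swarm environments.

    ``d_t`` is the target distance (band centre for the escort task, disk
    radius for the swarm task), ``e_t`` the half-width of the acceptable
    escort band, ``d_cz`` the comfort-zone radius and ``R_p`` the perception
    radius (``inf`` = unlimited perception).
    """

    dt: float = 0.1
    T: int = 500
    F_max: float = 1.0
    v_max: float = 1.0
    a_max: float = 1.0
    gamma: float = 0.9
    d_t: float = 2.0
    e_t: float = 0.5
    d_cz: float = 0.5
    R_p: float = math.inf
    N: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("dt", self.dt > 0),
            ("T", self.T >= 1),
            ("gamma", 0.0 < self.gamma < 1.0),
            ("e_t", self.e_t > 0),
            ("d_cz", self.d_cz > 0),
            ("F_max", self.F_max > 0),
            ("v_max", self.v_max > 0),
            ("a_max", self.a_max > 0),
            ("d_t", self.d_t > 0),
            ("R_p", self.R_p > 0),
            ("N", self.N >= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid EnvConfig field(s): {', '.join(bad)}")


def clip_action(a: Vec2, bound: float) -> Vec2:
    """Rescale ``a`` onto the disk of radius ``bound``, preserving direction."""
    if bound <= 0:
        raise ValueError("bound must be positive")
    a = np.asarray(a, dtype=float)
    norm = math.hypot(a[0], a[1])
    if norm <= bound:
        return a.copy()
    return a * (bound / norm)


def step(
    kin: AgentKinematics,
    action: Vec2,
    mode: str,
    cfg: EnvConfig,
    external_force: Vec2 | None = None,
) -> AgentKinematics:
    """Advance one agent by one Euler step under the given control regime.

    Mode ``A``: action is the new velocity (norm-clipped at ``v_max``).
    Mode ``B``: like A, but the velocity change per unit time is capped at
    ``a_max``.  Mode ``C``: action is a force (clipped at ``F_max``); with
    unit mass the velocity integrates the total force, then the position
    integrates the new velocity.
    """
    action = _as_vec2(action, "action")
    ext = _ZERO2 if external_force is None else _as_vec2(external_force, "external_force")
    dt = cfg.dt

    if mode == "A":
        v_new = clip_action(action, cfg.v_max)
        return AgentKinematics(kin.position + v_new * dt, v_new, kin.last_force.copy())
    if mode == "B":
        v_req = clip_action(action, cfg.v_max)
        dv = v_req - kin.velocity
        dv_norm = math.hypot(dv[0], dv[1])
        cap = cfg.a_max * dt
        if dv_norm > cap:
            dv = dv * (cap / dv_norm)
        v_new = kin.velocity + dv
        return AgentKinematics(kin.position + v_new * dt, v_new, kin.last_force.copy())
    if mode == "C":
        force = clip_action(action, cfg.F_max)
        v_new = kin.velocity + (force + ext) * dt
        return AgentKinematics(kin.position + v_new * dt, v_new, force)
    raise ValueError(f"unknown stepping mode {mode!r}; expected 'A', 'B' or 'C'")


# ---------------------------------------------------------------------------
# Leader trajectories


_PATH_KINDS = ("circle", "ellipse", "eight", "spiral", "triangle")


class LeaderPath:
    """Predefined leader trajectory traversed at constant speed.

    Supported kinds: ``circle`` (radius), ``ellipse`` (semi-axes ``a``/``b``),
    ``eight`` (Gerono lemniscate of half-width ``a``), ``spiral``
    (Archimedean, ``r = pitch * phi``) and ``triangle`` (piecewise-linear
    loop through ``vertices`` -- deliberately non-smooth).

    Non-circular closed curves are reparametrized to arc length with a dense
    chord table, so the leader's speed along the curve is uniform.
    """

    def __init__(self, kind: str = "circle", speed: float = 0.5, **params):
        if kind not in _PATH_KINDS:
            raise ValueError(f"unknown leader path kind {kind!r}; expected one of {_PATH_KINDS}")
        if speed <= 0:
            raise ValueError("leader speed must be positive")
        self.kind = kind
        self.speed = float(speed)
        self.params = dict(params)
        if kind == "triangle":
            verts = params.get("vertices", [(2.0, 0.0), (-1.0, 1.8), (-1.0, -1.8)])
            self._vertices = np.asarray(verts, dtype=float)
            if self._vertices.shape[0] < 3:
                raise ValueError("triangle path needs at least 3 vertices")
            closed = np.vstack([self._vertices, self._vertices[:1]])
            seg = np.diff(closed, axis=0)
            self._seg_len = np.linalg.norm(seg, axis=1)
            self._cum = np.concatenate([[0.0], np.cumsum(self._seg_len)])
            self._closed = closed
        elif kind in ("ellipse", "eight", "spiral"):
            self._build_arclength_table()

    # parametric curves in an auxiliary parameter u
    def _raw_point(self, u: np.ndarray) -> np.ndarray:
        p = self.params
        if self.kind == "ellipse":
            a, b = p.get("a", 2.0), p.get("b", 1.0)
            return np.stack([a * np.cos(u), b * np.sin(u)], axis=-1)
        if self.kind == "eight":
            a = p.get("a", 2.0)
            return np.stack([a * np.sin(u), a * np.sin(u) * np.cos(u)], axis=-1)
        if self.kind == "spiral":
            pitch = p.get("pitch", 0.15)
            return np.stack([pitch * u * np.cos(u), pitch * u * np.sin(u)], axis=-1)
        raise AssertionError(self.kind)

    def _build_arclength_table(self, n: int = 4096) -> None:
        if self.kind == "spiral":
            u = np.linspace(0.0, self.params.get("turns", 6.0) * 2 * np.pi, n)
        else:
            u = np.linspace(0.0, 2 * np.pi, n)
        pts = self._raw_point(u)
        chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(chord)])
        self._table_u = u
        self._table_s = s
        self._total_len = s[-1]

    def position(self, t: float) -> Vec2:
        if t < 0:
            raise ValueError("time must be non-negative")
        s = self.speed * t
        if self.kind == "circle":
            R = self.params.get("radius", 2.0)
            phi = s / R
            return np.array([R * math.cos(phi), R * math.sin(phi)])
        if self.kind == "triangle":
            s = s % self._cum[-1]
            i = int(np.searchsorted(self._cum, s, side="right") - 1)
            i = min(i, len(self._seg_len) - 1)
            frac = (s - self._cum[i]) / self._seg_len[i]
            return self._closed[i] + frac * (self._closed[i + 1] - self._closed[i])
        if self.kind == "spiral":
            s = min(s, self._total_len)  # spiral is open: clamp at the outer end
        else:
            s = s % self._total_len
        u = float(np.interp(s, self._table_s, self._table_u))
        return self._raw_point(np.asarray(u)).reshape(2)

    def velocity(self, t: float, h: float = 1e-6) -> Vec2:
        """Central-difference velocity; one-sided at t=0 and at path corners."""
        if t < h:
            return (self.position(t + h) - self.position(t)) / h
        return (self.position(t + h) - self.position(t - h)) / (2 * h)


def leader_position(path: LeaderPath, t: float) -> Vec2:
    """Point on the leader's curve at time ``t`` (constant-speed traversal)."""
    return path.position(t)
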