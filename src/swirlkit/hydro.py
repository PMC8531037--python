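"""Rotne-Prager hydrodynamics: mobility blocks, force solves, dissipation,
direct configuration optimization and the RL locomotion environment.

Spherical agents of radius ``a`` move in a viscous fluid at low Reynolds
number.  Velocities respond linearly to the forces applied to all agents
through the pairwise mobility tensor

    zeta_ij = (1/(6 pi eta a)) [ (3a/4x)(I + xx^T) + (1/2)(a/x)^3 (I - 3 xx^T) ],
    zeta_ii = I/(6 pi eta a),

restricted here to the plane of motion.  For a swarm translating rigidly at
velocity v the required agent forces solve the 2N linear system, and the
dissipated power is P = (6 pi eta a)^{-1} sum_i ||F_i||^2.  All reported
specific powers P/N are in units of the power of a solely moving agent.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .kinematics import EnvConfig
from .perception import encode_locomotion, locomotion_dim
from .policy import PolicyParams, forward, init_params, sample_action, weighted_logprob_grad
from .reinforce import TrainConfig, make_optimizer, returns_to_go
from .rewards import RewardConstants, reward_locomotion

__all__ = [
    "HydroParams",
    "pair_block",
    "mobility_matrix",
    "solve_common_velocity",
    "solo_power",
    "specific_power",
    "optimize_configuration",
    "OptimizationResult",
    "LocomotionEnv",
    "train_locomotion",
]

logger = logging.getLogger(__name__)


@dataclass
class HydroParams:
    """Fluid/agent constants.  Defaults make the Stokes drag coefficient
    6*pi*eta*a equal to 1, so solo power equals ||v||^2."""

    a: float = 1.0
    eta_fluid: float = 1.0 / (6.0 * math.pi)
    v_lead: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        if self.a <= 0 or self.eta_fluid <= 0:
            raise ValueError("agent radius and fluid viscosity must be positive")
        self.v_lead = np.asarray(self.v_lead, dtype=float)

    @property
    def drag(self) -> float:
        return 6.0 * math.pi * self.eta_fluid * self.a


def pair_block(x_ij: np.ndarray, p: HydroParams) -> np.ndarray:
    """In-plane 2x2 mobility block for a pair at separation vector ``x_ij``.

    A zero separation means the self block I/(6 pi eta a).  Separations
    below contact (2a) are outside the far-field theory's validity and are
    only warned about.
    """
    x_ij = np.asarray(x_ij, dtype=float)
    x = float(np.linalg.norm(x_ij))
    pref = 1.0 / p.drag
    if x == 0.0:
        return pref * np.eye(2)
    if x < 2 * p.a * (1.0 - 1e-9):
        import warnings

        warnings.warn(
            f"pair separation {x:.3g} below contact 2a={2 * p.a:.3g}; "
            "Rotne-Prager is a far-field theory",
            RuntimeWarning,
            stacklevel=2,
        )
    xb = x_ij / x
    outer = np.outer(xb, xb)
    eye = np.eye(2)
    return pref * ((3 * p.a / (4 * x)) * (eye + outer) + 0.5 * (p.a / x) ** 3 * (eye - 3 * outer))


def mobility_matrix(positions: np.ndarray, p: HydroParams) -> np.ndarray:
    """Assembled 2N x 2N block mobility matrix."""
    positions = np.asarray(positions, dtype=float)
    N = positions.shape[0]
    M = np.zeros((2 * N, 2 * N))
    for i in range(N):
        M[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = np.eye(2) / p.drag
        for j in range(i + 1, N):
            x_ij = positions[i] - positions[j]
            if np.allclose(x_ij, 0):
                raise ValueError(f"agents {i} and {j} coincide")
            blk = pair_block(x_ij, p)
            M[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = blk
            M[2 * j : 2 * j + 2, 2 * i : 2 * i + 2] = blk
    return M


def solve_common_velocity(
    positions: np.ndarray, v: np.ndarray, p: HydroParams
) -> tuple[np.ndarray, float]:
    """Agent forces and total dissipated power for rigid translation at ``v``.

    Solves sum_j zeta_ij F^e_j = -v for the environment forces; the agent
    forces are F^a = -F^e and P = (6 pi eta a)^{-1} sum ||F^a_i||^2.
    """
    positions = np.asarray(positions, dtype=float)
    v = np.asarray(v, dtype=float)
    N = positions.shape[0]
    M = mobility_matrix(positions, p)
    rhs = np.tile(v, N)
    try:
        F_a = np.linalg.solve(M, rhs).reshape(N, 2)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular mobility matrix (overlapping agents?)") from exc
    P = float(np.sum(F_a * F_a)) / p.drag
    return F_a, P


def solo_power(v: np.ndarray, p: HydroParams) -> float:
    """Stokes dissipation of a single agent moving at ``v``."""
    v = np.asarray(v, dtype=float)
    return p.drag * float(v @ v)


def specific_power(positions: np.ndarray, v: np.ndarray, p: HydroParams) -> float:
    """P/N in units of the solo power (1.0 = no hydrodynamic benefit)."""
    N = np.asarray(positions).shape[0]
    _, P = solve_common_velocity(positions, v, p)
    return P / (N * solo_power(v, p))


# ---------------------------------------------------------------------------
# Direct optimization of the swarm configuration


@dataclass
class OptimizationResult:
    best_positions: np.ndarray
    best_specific_power: float
    minima: list  # list of (positions, specific_power) for distinct global minima
    n_restarts: int


def _config_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Distance between centred configurations modulo agent permutation."""
    N = A.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(N)):
        d = float(np.max(np.linalg.norm(A - B[list(perm)], axis=1)))
        best = min(best, d)
    return best


def optimize_configuration(
    N: int,
    p: Optional[HydroParams] = None,
    v: Optional[np.ndarray] = None,
    min_sep: Optional[float] = None,
    restarts: int = 64,
    rng: Optional[np.random.Generator] = None,
    cluster_tol: float = 0.05,
    power_rel_tol: float = 1e-5,
) -> OptimizationResult:
    """Multi-start constrained minimization of the dissipated power.

    The centroid is pinned at the origin; the minimum pairwise separation is
    constrained to ``min_sep`` (default contact, 2a).  Distinct global
    minima -- configurations within ``power_rel_tol`` of the best power that
    differ modulo agent permutation -- are reported; the mirror symmetry
    about the motion axis is *not* quotiented out, so a mirror pair counts
    as two realizations.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    p = p or HydroParams()
    v = np.asarray(v if v is not None else p.v_lead, dtype=float)
    min_sep = 2 * p.a if min_sep is None else min_sep
    rng = rng or np.random.default_rng(0)

    if N == 1:
        return OptimizationResult(np.zeros((1, 2)), 1.0, [(np.zeros((1, 2)), 1.0)], 0)

    def objective(flat: np.ndarray) -> float:
        import warnings

        with warnings.catch_warnings():
            # intermediate SLSQP iterates may be slightly infeasible
            warnings.simplefilter("ignore", RuntimeWarning)
            return specific_power(flat.reshape(N, 2), v, p)

    cons = []
    for i in range(N):
        for j in range(i + 1, N):
            cons.append(
                {
                    "type": "ineq",
                    "fun": (lambda flat, i=i, j=j: np.linalg.norm(
                        flat.reshape(N, 2)[i] - flat.reshape(N, 2)[j]
                    ) - min_sep),
                }
            )
    cons.append({"type": "eq", "fun": lambda flat: flat.reshape(N, 2).mean(axis=0)})

    solutions = []
    box = 2.5 * min_sep * max(1.0, np.sqrt(N))
    for _ in range(restarts):
        while True:
            x0 = rng.uniform(-box, box, size=(N, 2))
            dists = [
                np.linalg.norm(x0[i] - x0[j]) for i in range(N) for j in range(i + 1, N)
            ]
            if min(dists) > min_sep:
                break
        x0 = x0 - x0.mean(axis=0)
        res = minimize(
            objective,
            x0.ravel(),
            method="SLSQP",
            constraints=cons,
            options={"maxiter": 400, "ftol": 1e-12},
        )
        if not res.success:
            continue
        pos = res.x.reshape(N, 2)
        seps = [np.linalg.norm(pos[i] - pos[j]) for i in range(N) for j in range(i + 1, N)]
        if min(seps) < min_sep - 1e-6:
            continue
        solutions.append((pos - pos.mean(axis=0), float(res.fun)))

    if not solutions:
        raise RuntimeError("no feasible local minimum found")
    solutions.sort(key=lambda s: s[1])
    best_P = solutions[0][1]
    global_sols = [s for s in solutions if s[1] <= best_P * (1 + power_rel_tol)]

    clusters: list[tuple[np.ndarray, float]] = []
    for pos, P in global_sols:
        if all(_config_distance(pos, c[0]) > cluster_tol for c in clusters):
            clusters.append((pos, P))
    return OptimizationResult(solutions[0][0], best_P, clusters, restarts)


# ---------------------------------------------------------------------------
# RL locomotion environment


class LocomotionEnv:
    """Leader + N followers in viscous fluid; followers learn to draft.

    The leader moves at exactly ``v_lead``: its force is solved jointly with
    the follower velocities from the mobility system each step.  Velocities
    are instantaneous (overdamped), positions advance by explicit Euler.
    Separations below contact either raise or are clamped to contact in the
    mobility evaluation, per ``overlap``.
    """

    def __init__(
        self,
        cfg: EnvConfig,
        p: Optional[HydroParams] = None,
        constants: Optional[RewardConstants] = None,
        overlap: str = "clamp",
        init_spread: float = 2.0,
    ):
        if cfg.N < 1:
            raise ValueError("need at least one follower")
        if overlap not in ("error", "clamp"):
            raise ValueError("overlap must be 'error' or 'clamp'")
        self.cfg = cfg
        self.p = p or HydroParams()
        self.k = constants or RewardConstants()
        self.overlap = overlap
        self.init_spread = init_spread
        self.T = cfg.T
        self.action_bound = cfg.F_max
        self.obs_dim = locomotion_dim(cfg.N)

    def _mobility(self, all_pos: np.ndarray) -> np.ndarray:
        if self.overlap == "error":
            n = all_pos.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    if np.linalg.norm(all_pos[i] - all_pos[j]) < 2 * self.p.a:
                        raise ValueError(f"agents {i} and {j} overlap")
            return mobility_matrix(all_pos, self.p)
        # clamp: evaluate each sub-contact pair at contact separation
        n = all_pos.shape[0]
        M = np.zeros((2 * n, 2 * n))
        for i in range(n):
            M[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = np.eye(2) / self.p.drag
            for j in range(i + 1, n):
                x_ij = all_pos[i] - all_pos[j]
                d = np.linalg.norm(x_ij)
                if d < 1e-12:
                    x_ij = np.array([2 * self.p.a, 0.0])
                    d = 2 * self.p.a
                elif d < 2 * self.p.a:
                    x_ij = x_ij * (2 * self.p.a / d)
                blk = pair_block(x_ij, self.p)
                M[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = blk
                M[2 * j : 2 * j + 2, 2 * i : 2 * i + 2] = blk
        return M

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        cfg = self.cfg
        self.leader_pos = np.zeros(2)
        # followers scattered behind/around the leader, non-overlapping
        pos = []
        while len(pos) < cfg.N:
            cand = rng.uniform(-self.init_spread, self.init_spread, size=2)
            if np.linalg.norm(cand) < 2.2 * self.p.a:
                continue
            if all(np.linalg.norm(cand - q) > 2.2 * self.p.a for q in pos):
                pos.append(cand)
        self.positions = np.array(pos)
        self.velocities = np.zeros((cfg.N, 2))
        self.last_forces = np.zeros((cfg.N, 2))
        self._prev_nn = [None] * cfg.N
        self._t = 0
        return self._observe()

    def _observe(self) -> np.ndarray:
        cfg = self.cfg
        obs = np.empty((cfg.N, self.obs_dim))
        new_nn = []
        for i in range(cfg.N):
            o, nn = encode_locomotion(
                i,
                self.leader_pos,
                self.positions,
                self.velocities,
                self.last_forces,
                self._prev_nn[i],
                cfg,
            )
            obs[i] = o.vector()
            new_nn.append(nn)
            self._last_obs_objs = getattr(self, "_last_obs_objs", [None] * cfg.N)
            self._last_obs_objs[i] = o
        self._prev_nn = new_nn
        return obs

    def step(self, actions: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        """Apply follower forces; returns (obs, rewards, info with power)."""
        cfg = self.cfg
        actions = np.asarray(actions, dtype=float)
        if not np.all(np.isfinite(actions)):
            raise FloatingPointError("non-finite actions in LocomotionEnv.step")
        norms = np.linalg.norm(actions, axis=1, keepdims=True)
        scale = np.minimum(1.0, cfg.F_max / np.maximum(norms, 1e-300))
        F_followers = actions * scale

        all_pos = np.vstack([self.leader_pos[None, :], self.positions])
        M = self._mobility(all_pos)
        # solve the leader force so that its velocity equals v_lead exactly
        M00 = M[:2, :2]
        coupling = M[:2, 2:] @ F_followers.ravel()
        F_leader = np.linalg.solve(M00, self.p.v_lead - coupling)
        F_all = np.concatenate([F_leader, F_followers.ravel()])
        v_all = (M @ F_all).reshape(-1, 2)

        self.leader_pos = self.leader_pos + v_all[0] * cfg.dt
        self.positions = self.positions + v_all[1:] * cfg.dt
        self.velocities = v_all[1:]
        self.last_forces = F_followers
        self._t += 1

        obs = self._observe()
        rewards = np.array(
            [reward_locomotion(o, self.k) for o in self._last_obs_objs]
        )
        power = float(np.sum(F_all.reshape(-1, 2) ** 2)) / self.p.drag
        info = {
            "power": power,
            "leader_force": F_leader,
            "velocities": v_all,
        }
        return obs, rewards, info


def train_locomotion(
    env: LocomotionEnv,
    cfg: TrainConfig,
    shared_policy: bool = True,
    hidden: int = 128,
) -> tuple[PolicyParams | list[PolicyParams], "pd.DataFrame"]:
    """REINFORCE training of the followers (pooled experience by default)."""
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    N = env.cfg.N
    d = env.obs_dim
    if shared_policy:
        policies = init_params(d, rng, hidden=hidden)
        opt = make_optimizer(cfg.optimizer, cfg.lr)
    else:
        policies = [init_params(d, rng, hidden=hidden) for _ in range(N)]
        opts = [make_optimizer(cfg.optimizer, cfg.lr) for _ in range(N)]

    rows = []
    for k in range(cfg.updates):
        S = np.empty((cfg.n, env.T, N, d))
        A = np.empty((cfg.n, env.T, N, 2))
        R = np.empty((cfg.n, env.T, N))
        for e in range(cfg.n):
            obs = env.reset(rng)
            for t in range(env.T):
                if shared_policy:
                    dist = forward(policies, obs)
                    clipped, raw = sample_action(dist, env.action_bound, rng)
                else:
                    clipped = np.empty((N, 2))
                    raw = np.empty((N, 2))
                    for i in range(N):
                        dist = forward(policies[i], obs[i])
                        clipped[i], raw[i] = sample_action(dist, env.action_bound, rng)
                S[e, t], A[e, t] = obs, raw
                obs, r, _info = env.step(clipped)
                R[e, t] = r
        G = returns_to_go(np.moveaxis(R, 1, 2), cfg.gamma)  # (n, N, T)
        mean_return = float(G[..., 0].mean())
        if cfg.baseline:
            G = G - G.mean(axis=(0, 1), keepdims=True)
        S_f = np.moveaxis(S, 1, 2)
        A_f = np.moveaxis(A, 1, 2)
        if shared_policy:
            n_traj = cfg.n * N
            grad = weighted_logprob_grad(
                policies,
                S_f.reshape(n_traj * env.T, d),
                A_f.reshape(n_traj * env.T, 2),
                G.reshape(n_traj * env.T) / n_traj,
            )
            policies = opt.step(policies, grad)
        else:
            policies = [
                opts[i].step(
                    policies[i],
                    weighted_logprob_grad(
                        policies[i],
                        S_f[:, i].reshape(cfg.n * env.T, d),
                        A_f[:, i].reshape(cfg.n * env.T, 2),
                        G[:, i].reshape(cfg.n * env.T) / cfg.n,
                    ),
                )
                for i in range(N)
            ]
        rows.append({"update": k, "mean_return": mean_return})
        if cfg.log_every and k % cfg.log_every == 0:
            print(f"locomotion update {k:4d}  mean_return {mean_return:+8.3f}")
    return policies, pd.DataFrame(rows)
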