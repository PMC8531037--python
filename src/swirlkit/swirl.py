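"""Multi-agent swarm environment and the swirling order parameter.

N identical agents move under scenario-C control (bounded forces, no drag)
and are rewarded individually for escorting the *group centre*: staying
within the target radius, approaching it otherwise, and keeping their
comfort zones free.  The emergent collective rotation is quantified by the
average angular velocity

    Omega = (1/N) sum_i (v_i - v_gc) x (x_i - x_gc) / ||x_i - x_gc||^2

where ``x`` is the 2D scalar cross product ``a_x b_y - a_y b_x``.  Under
this operand order a rigid counterclockwise rotation at rate w gives
Omega = -w; magnitudes |Omega| are reported.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np

from .kinematics import EnvConfig
from .perception import SWARM_DIM, encode_swarm_batch
from .policy import PolicyParams, forward, init_params, sample_action, weighted_logprob_grad
from .reinforce import TrainConfig, make_optimizer, returns_to_go
from .rewards import RewardConstants, reward_swarm_batch

__all__ = [
    "angular_velocity",
    "SwarmEnv",
    "run_swarm_episode",
    "train_swarm",
    "swarm_extent",
]

logger = logging.getLogger(__name__)

_EPS_CENTER = 1e-9

Policies = Union[PolicyParams, Sequence[PolicyParams]]


def angular_velocity(positions: np.ndarray, velocities: np.ndarray) -> float:
    """Signed mean angular velocity of the swarm about its centre of mass.

    Agents sitting exactly at the centre (within an epsilon) are excluded
    from the average with a logged warning.
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("angular velocity needs at least 2 agents")
    x_gc = positions.mean(axis=0)
    v_gc = velocities.mean(axis=0)
    r = positions - x_gc
    dv = velocities - v_gc
    r2 = np.einsum("ij,ij->i", r, r)
    ok = r2 > _EPS_CENTER**2
    if not np.all(ok):
        logger.warning("agent(s) at the swarm centre excluded from Omega: %s", np.flatnonzero(~ok))
    if not np.any(ok):
        raise ValueError("no agent off-centre; Omega undefined")
    cross = dv[ok, 0] * r[ok, 1] - dv[ok, 1] * r[ok, 0]
    return float(np.mean(cross / r2[ok]))


def swarm_extent(positions: np.ndarray) -> float:
    """RMS distance of the agents from their centre of mass."""
    positions = np.asarray(positions, dtype=float)
    r = positions - positions.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", r, r))))


class SwarmEnv:
    """Synchronous-stepping swarm of N scenario-C agents.

    Each step: all agents encode their (perception-limited) observations,
    all act, the world advances once, and individual rewards are computed
    from the post-step indicators.  An optional external force field adds
    the same force vector to every agent's dynamics.
    """

    obs_dim = SWARM_DIM

    def __init__(
        self,
        cfg: EnvConfig,
        constants: Optional[RewardConstants] = None,
        force_field=None,
        v0: float = 0.5,
        init_radius_factor: float = 2.0,
    ):
        if cfg.N < 2:
            raise ValueError("swarm tasks need N >= 2 agents")
        self.cfg = cfg
        self.k = constants or RewardConstants()
        self.force_field = force_field
        self.v0 = v0
        self.init_radius_factor = init_radius_factor
        self.T = cfg.T
        self.action_bound = cfg.F_max
        self._t = 0

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        cfg = self.cfg
        self._t = 0
        # positions uniform in a disk of radius init_radius_factor*d_t,
        # speeds uniform in [0, v0]
        ang = rng.uniform(0, 2 * np.pi, cfg.N)
        rad = self.init_radius_factor * cfg.d_t * np.sqrt(rng.uniform(0, 1, cfg.N))
        self.positions = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        sp = rng.uniform(0, self.v0, cfg.N)
        va = rng.uniform(0, 2 * np.pi, cfg.N)
        self.velocities = np.column_stack([sp * np.cos(va), sp * np.sin(va)])
        self.last_forces = np.zeros((cfg.N, 2))
        if self.force_field is not None:
            self.force_field.reset(rng)
        obs, self._nn_dist, self._gc_dist = encode_swarm_batch(
            self.positions, self.velocities, self.last_forces, None, None, cfg
        )
        return obs

    def step(self, forces: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Advance one synchronous step; returns (obs, rewards, Omega)."""
        cfg = self.cfg
        forces = np.asarray(forces, dtype=float)
        if not np.all(np.isfinite(forces)):
            raise FloatingPointError("non-finite forces in SwarmEnv.step")
        norms = np.linalg.norm(forces, axis=1, keepdims=True)
        scale = np.minimum(1.0, cfg.F_max / np.maximum(norms, 1e-300))
        forces = forces * scale
        ext = np.zeros(2) if self.force_field is None else self.force_field.force(self._t)
        self.velocities = self.velocities + (forces + ext) * cfg.dt
        self.positions = self.positions + self.velocities * cfg.dt
        self.last_forces = forces
        self._t += 1

        obs, nn_dist, gc_dist = encode_swarm_batch(
            self.positions, self.velocities, self.last_forces, self._nn_dist, self._gc_dist, cfg
        )
        self._nn_dist, self._gc_dist = nn_dist, gc_dist
        rewards = reward_swarm_batch(obs[:, 0], obs[:, 1], obs[:, 2], obs[:, 3], self.k)
        omega = angular_velocity(self.positions, self.velocities)
        return obs, rewards, omega


def _batch_angular_velocity(positions: np.ndarray, velocities: np.ndarray) -> np.ndarray:
    """Omega per swarm for batched (B, N, 2) states (no centre-guard: used
    only on generic random-init configurations where coincidence has
    probability zero)."""
    x_gc = positions.mean(axis=1, keepdims=True)
    v_gc = velocities.mean(axis=1, keepdims=True)
    r = positions - x_gc
    dv = velocities - v_gc
    r2 = np.einsum("bij,bij->bi", r, r)
    cross = dv[..., 0] * r[..., 1] - dv[..., 1] * r[..., 0]
    return (cross / np.maximum(r2, _EPS_CENTER**2)).mean(axis=1)


class _VectorSwarmEnv:
    """B independent copies of :class:`SwarmEnv` advanced in lock-step.

    Exists purely to amortize per-step Python overhead during training; the
    dynamics are identical to the scalar environment (covered by a parity
    test).  Each copy gets its own external-force field clone.
    """

    def __init__(self, env: SwarmEnv, B: int):
        self.cfg = env.cfg
        self.k = env.k
        self.v0 = env.v0
        self.init_radius_factor = env.init_radius_factor
        self.B = B
        if env.force_field is None:
            self.fields = None
        else:
            import copy

            self.fields = [copy.deepcopy(env.force_field) for _ in range(B)]
        self.action_bound = env.action_bound
        self.T = env.T

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        cfg, B = self.cfg, self.B
        ang = rng.uniform(0, 2 * np.pi, (B, cfg.N))
        rad = self.init_radius_factor * cfg.d_t * np.sqrt(rng.uniform(0, 1, (B, cfg.N)))
        self.positions = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=2)
        sp = rng.uniform(0, self.v0, (B, cfg.N))
        va = rng.uniform(0, 2 * np.pi, (B, cfg.N))
        self.velocities = np.stack([sp * np.cos(va), sp * np.sin(va)], axis=2)
        self.last_forces = np.zeros((B, cfg.N, 2))
        if self.fields is not None:
            for f in self.fields:
                f.reset(rng)
        self._t = 0
        obs, self._nn_dist, self._gc_dist = encode_swarm_batch(
            self.positions, self.velocities, self.last_forces, None, None, cfg
        )
        return obs

    def step(self, forces: np.ndarray):
        cfg = self.cfg
        norms = np.linalg.norm(forces, axis=2, keepdims=True)
        forces = forces * np.minimum(1.0, cfg.F_max / np.maximum(norms, 1e-300))
        if self.fields is not None:
            ext = np.stack([f.force(self._t) for f in self.fields])[:, None, :]
        else:
            ext = 0.0
        self.velocities = self.velocities + (forces + ext) * cfg.dt
        self.positions = self.positions + self.velocities * cfg.dt
        self.last_forces = forces
        self._t += 1
        obs, nn_dist, gc_dist = encode_swarm_batch(
            self.positions, self.velocities, self.last_forces, self._nn_dist, self._gc_dist, cfg
        )
        self._nn_dist, self._gc_dist = nn_dist, gc_dist
        rewards = reward_swarm_batch(
            obs[..., 0], obs[..., 1], obs[..., 2], obs[..., 3], self.k
        )
        omega = _batch_angular_velocity(self.positions, self.velocities)
        return obs, rewards, omega


def _act(policies: Policies, obs: np.ndarray, bound: float, rng: np.random.Generator):
    """Sample clipped and raw actions for all agents (shared or per-agent)."""
    if isinstance(policies, PolicyParams):
        dist = forward(policies, obs)
        return sample_action(dist, bound, rng)
    clipped = np.empty((len(policies), 2))
    raw = np.empty((len(policies), 2))
    for i, p in enumerate(policies):
        dist = forward(p, obs[i])
        clipped[i], raw[i] = sample_action(dist, bound, rng)
    return clipped, raw


def run_swarm_episode(
    policies: Policies,
    env: SwarmEnv,
    rng: np.random.Generator,
    record_trajectories: bool = False,
) -> dict:
    """Roll out one episode; returns states/actions/rewards/Omega arrays."""
    T, N = env.T, env.cfg.N
    states = np.empty((T, N, SWARM_DIM))
    raw_actions = np.empty((T, N, 2))
    rewards = np.empty((T, N))
    omega = np.empty(T)
    traj = np.empty((T, N, 6)) if record_trajectories else None

    obs = env.reset(rng)
    for t in range(T):
        clipped, raw = _act(policies, obs, env.action_bound, rng)
        states[t] = obs
        raw_actions[t] = raw
        obs, r, om = env.step(clipped)
        rewards[t] = r
        omega[t] = om
        if record_trajectories:
            traj[t] = np.concatenate([env.positions, env.velocities, env.last_forces], axis=1)
    out = {"states": states, "actions": raw_actions, "rewards": rewards, "omega": omega}
    out["final_positions"] = env.positions.copy()
    out["final_velocities"] = env.velocities.copy()
    if record_trajectories:
        out["trajectories"] = traj
    return out


def train_swarm(
    env: SwarmEnv,
    cfg: TrainConfig,
    shared_policy: bool = False,
    hidden: int = 128,
    initial: Optional[Policies] = None,
    optimizer_state=None,
) -> tuple[Policies, "pd.DataFrame"]:
    """Train the swarm with EPISODIC REINFORCE, each agent on its own rewards.

    With ``shared_policy`` a single network is updated from all agents'
    transitions (pooled experience); otherwise each agent owns an
    independent network and its gradient uses only that agent's rewards.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    N = env.cfg.N
    if initial is not None:
        policies = initial
    elif shared_policy:
        policies = init_params(SWARM_DIM, rng, hidden=hidden)
    else:
        policies = [init_params(SWARM_DIM, rng, hidden=hidden) for _ in range(N)]

    if optimizer_state is not None:
        opts = optimizer_state
    elif shared_policy:
        opts = make_optimizer(cfg.optimizer, cfg.lr)
    else:
        opts = [make_optimizer(cfg.optimizer, cfg.lr) for _ in range(N)]

    venv = _VectorSwarmEnv(env, cfg.n)
    T, d = env.T, SWARM_DIM
    rows = []
    for k in range(cfg.updates):
        states = np.empty((cfg.n, T, N, d))
        actions = np.empty((cfg.n, T, N, 2))
        rewards = np.empty((cfg.n, T, N))
        omegas = np.empty((cfg.n, T))
        obs = venv.reset(rng)  # (n, N, d)
        for t in range(T):
            if isinstance(policies, PolicyParams):
                dist = forward(policies, obs.reshape(cfg.n * N, d))
                clipped, raw = sample_action(dist, env.action_bound, rng)
                clipped = clipped.reshape(cfg.n, N, 2)
                raw = raw.reshape(cfg.n, N, 2)
            else:
                clipped = np.empty((cfg.n, N, 2))
                raw = np.empty((cfg.n, N, 2))
                for i in range(N):
                    dist = forward(policies[i], obs[:, i, :])
                    clipped[:, i], raw[:, i] = sample_action(dist, env.action_bound, rng)
            states[:, t] = obs
            actions[:, t] = raw
            obs, r, om = venv.step(clipped)
            rewards[:, t] = r
            omegas[:, t] = om

        G = returns_to_go(np.moveaxis(rewards, 1, 2), cfg.gamma)  # (n, N, T)
        mean_return = float(G[..., 0].mean())
        if cfg.baseline:
            G = G - G.mean(axis=(0, 1), keepdims=True)
        if cfg.normalize_advantages:
            G = G / (G.std() + 1e-8)
        omega_tail = float(np.mean(np.abs(omegas[:, -env.T // 4 :])))

        S_flat = np.moveaxis(states, 1, 2)  # (n, N, T, d)
        A_flat = np.moveaxis(actions, 1, 2)
        if shared_policy:
            n_traj = cfg.n * N
            grad = weighted_logprob_grad(
                policies,
                S_flat.reshape(n_traj * env.T, SWARM_DIM),
                A_flat.reshape(n_traj * env.T, 2),
                G.reshape(n_traj * env.T) / n_traj,
            )
            policies = opts.step(policies, grad)
        else:
            new_policies = []
            for i in range(N):
                grad = weighted_logprob_grad(
                    policies[i],
                    S_flat[:, i].reshape(cfg.n * env.T, SWARM_DIM),
                    A_flat[:, i].reshape(cfg.n * env.T, 2),
                    G[:, i].reshape(cfg.n * env.T) / cfg.n,
                )
                new_policies.append(opts[i].step(policies[i], grad))
            policies = new_policies

        ref = policies if isinstance(policies, PolicyParams) else policies[0]
        mean_sigma = float(np.mean(forward(ref, states[0, 0, 0]).sigma))
        rows.append(
            {
                "update": k,
                "mean_return": mean_return,
                "abs_omega_tail": omega_tail,
                "mean_sigma": mean_sigma,
            }
        )
        if cfg.log_every and k % cfg.log_every == 0:
            print(
                f"update {k:4d}  mean_return {mean_return:+8.2f}  |Omega| {omega_tail:.3f}"
                f"  sigma {mean_sigma:.3f}"
            )
    return policies, pd.DataFrame(rows)
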