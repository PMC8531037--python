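"""Desk-scale recipes for the headline experiments.

These wrap the package primitives into the concrete runs that the test
suite and the acceptance report execute: swirling emergence, external-force
resistance, and the hydrodynamic-optimum comparisons.  Scales (N, episode
length, update counts) are reduced to single-CPU budgets; every knob is a
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kinematics import EnvConfig
from .perturbation import ExternalForceField, resistance_curve
from .policy import PolicyParams, init_params
from .reinforce import TrainConfig
from .rewards import RewardConstants
from .swirl import Policies, SwarmEnv, run_swarm_episode, swarm_extent, train_swarm

__all__ = [
    "SwirlRecipe",
    "train_swirl_swarm",
    "train_until_swirling",
    "untrained_policy",
    "evaluate_swirl",
    "resistance_experiment",
]


@dataclass
class SwirlRecipe:
    """Hyperparameters of the desk-scale swirling-emergence run.

    The strong recede penalty keeps the swarm cohesive and in motion; the
    reduced episode length / update budget fit a single-CPU test run while
    still past the point where the collective-rotation signal emerges.
    """

    N: int = 20
    T: int = 200
    dt: float = 0.15
    d_t: float = 2.0
    d_cz: float = 0.7
    F_max: float = 1.0
    R_p: float = np.inf
    v0: float = 0.3
    init_radius_factor: float = 1.0
    r_recede: float = -0.5
    r_intrude: float = -0.5
    hidden: int = 48
    updates: int = 300
    episodes_per_update: int = 6
    lr: float = 1e-3
    gamma: float = 0.9
    sigma_bias: float = -1.0
    shared_policy: bool = True

    def env_config(self) -> EnvConfig:
        return EnvConfig(
            T=self.T, dt=self.dt, d_t=self.d_t, d_cz=self.d_cz,
            F_max=self.F_max, R_p=self.R_p, N=self.N, gamma=self.gamma,
        )

    def constants(self) -> RewardConstants:
        return RewardConstants(r_recede=self.r_recede, r_intrude=self.r_intrude)

    def make_env(self, force_field: Optional[ExternalForceField] = None) -> SwarmEnv:
        return SwarmEnv(
            self.env_config(),
            constants=self.constants(),
            force_field=force_field,
            v0=self.v0,
            init_radius_factor=self.init_radius_factor,
        )


def untrained_policy(recipe: SwirlRecipe, seed: int) -> PolicyParams:
    """Freshly initialized (state-quasi-independent, broad) control policy."""
    from .perception import SWARM_DIM

    return init_params(SWARM_DIM, np.random.default_rng(seed), hidden=recipe.hidden)


def train_swirl_swarm(
    recipe: SwirlRecipe,
    seed: int,
    force_field: Optional[ExternalForceField] = None,
) -> tuple[Policies, "pd.DataFrame"]:
    """Train one swarm per the recipe; returns (policies, metrics)."""
    from .perception import SWARM_DIM

    env = recipe.make_env(force_field)
    rng = np.random.default_rng(seed)
    if recipe.shared_policy:
        p0 = init_params(SWARM_DIM, rng, hidden=recipe.hidden)
        p0.b3_sigma += recipe.sigma_bias
        initial: Policies = p0
    else:
        initial = []
        for _ in range(recipe.N):
            p = init_params(SWARM_DIM, rng, hidden=recipe.hidden)
            p.b3_sigma += recipe.sigma_bias
            initial.append(p)
    tcfg = TrainConfig(
        n=recipe.episodes_per_update,
        updates=recipe.updates,
        lr=recipe.lr,
        gamma=recipe.gamma,
        optimizer="adam",
        normalize_advantages=True,
        seed=seed,
    )
    return train_swarm(env, tcfg, shared_policy=recipe.shared_policy, initial=initial)


def train_until_swirling(
    recipe: SwirlRecipe,
    seed: int,
    force_field: Optional[ExternalForceField] = None,
    target_tail_omega: float = 0.08,
    max_updates: int = 600,
    chunk: int = 50,
    select: str = "best",
) -> tuple[Policies, list]:
    """Train until the training-time tail |Omega| holds a plateau, keeping
    the best checkpoint.

    Training proceeds in chunks (one Adam optimizer persists throughout).
    After each chunk the rolling tail-|Omega| metric is compared against the
    best seen; the best-scoring parameters are snapshotted.  Training stops
    once the metric clears ``target_tail_omega`` — several times the
    untrained noise floor — or at ``max_updates``, returning the best
    checkpoint.  Seeds that synchronize early stop cheaply; stragglers get
    more updates, and a seed whose rotation peaks mid-training is captured
    at its peak instead of a later degraded state.

    ``select='final'`` disables both the early stop and the checkpoint
    selection: the full ``max_updates`` budget is spent and the final
    parameters are returned (used by the resistance experiment, where
    longer training keeps improving the swarm's response to the external
    force beyond the point where swirling first stabilizes).
    """
    if select not in ("best", "final"):
        raise ValueError("select must be 'best' or 'final'")
    from .perception import SWARM_DIM
    from .reinforce import make_optimizer

    rng = np.random.default_rng(seed)
    p0 = init_params(SWARM_DIM, rng, hidden=recipe.hidden)
    p0.b3_sigma += recipe.sigma_bias
    if not recipe.shared_policy:
        raise NotImplementedError("adaptive training implemented for the shared-policy route")
    policies: Policies = p0
    opt = make_optimizer("adam", recipe.lr)
    history = []
    best_score = -np.inf
    best_policies = policies.copy()
    done = 0
    min_updates = recipe.updates
    while done < max_updates:
        n_updates = min(chunk, max_updates - done)
        env = recipe.make_env(force_field)
        tcfg = TrainConfig(
            n=recipe.episodes_per_update,
            updates=n_updates,
            lr=recipe.lr,
            gamma=recipe.gamma,
            optimizer="adam",
            normalize_advantages=True,
            seed=seed + done,
        )
        policies, metrics = train_swarm(
            env, tcfg, shared_policy=True, initial=policies, optimizer_state=opt
        )
        history.append(metrics)
        done += n_updates
        score = float(metrics.abs_omega_tail.tail(n_updates // 2 or 1).mean())
        if score > best_score:
            best_score = score
            best_policies = policies.copy()
        if select == "best" and done >= min_updates and best_score >= target_tail_omega:
            break
    return (best_policies if select == "best" else policies), history


def evaluate_swirl(
    policies: Policies,
    recipe: SwirlRecipe,
    seed: int,
    episodes: int = 3,
    T: Optional[int] = None,
) -> dict:
    """Roll out evaluation episodes; reports tail |Omega| and dispersal."""
    env = recipe.make_env()
    if T is not None:
        env.cfg = EnvConfig(**{**env.cfg.__dict__, "T": T})
        env.T = T
    tails, extents, omega_series = [], [], []
    for e in range(episodes):
        out = run_swarm_episode(policies, env, np.random.default_rng([seed, e]))
        tails.append(float(np.mean(np.abs(out["omega"][-env.T // 4 :]))))
        extents.append(float(swarm_extent(out["final_positions"])))
        omega_series.append(out["omega"])
    return {
        "tail_abs_omega": float(np.mean(tails)),
        "extent": float(np.mean(extents)),
        "omega": np.stack(omega_series),
    }


def resistance_experiment(
    recipe: SwirlRecipe,
    f0_grid: Sequence[float],
    seed: int,
    reps: int = 10,
    f0_train: Optional[float] = None,
    beta: float = 1.0,
    modulation_period: int = 50,
    max_updates: int = 800,
) -> tuple["pd.DataFrame", float]:
    """Trained-vs-untrained center-shift comparison under external forcing.

    Trains one swarm *with the force field active* (random direction per
    episode, stretched-exponential magnitudes), pairs it with a freshly
    initialized control, and measures mean shifts over ``reps`` paired
    episodes per f0.  Returns the results table and the maximum
    untrained/trained mean-shift ratio over the grid.
    """
    f0_train = f0_train if f0_train is not None else float(np.median(f0_grid))
    train_field = ExternalForceField(f0=f0_train, beta=beta, modulation_period=modulation_period)
    trained, _ = train_until_swirling(
        recipe, seed, force_field=train_field, max_updates=max_updates
    )
    control = untrained_policy(recipe, seed + 10_000)
    table = resistance_curve(
        trained,
        control,
        f0_grid,
        recipe.env_config(),
        reps=reps,
        seed=seed,
        beta=beta,
        modulation_period=modulation_period,
        constants=recipe.constants(),
    )
    untr = table[table.group == "untrained"].set_index("f0").mean_shift
    tr = table[table.group == "trained"].set_index("f0").mean_shift
    ratios = untr / tr.abs()
    valid = ratios[np.isfinite(ratios) & (untr > 0)]
    max_ratio = float(valid.max()) if len(valid) else float("nan")
    return table, max_ratio
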