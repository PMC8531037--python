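"""EPISODIC REINFORCE: discounted returns, gradient estimate, ascent update.

The training loop collects ``n`` episodes per update, computes discounted
reward-to-go returns, optionally subtracts the per-timestep batch-mean
baseline, forms the score-function gradient and takes a plain gradient
*ascent* step ``theta <- theta + lr * grad`` (an Adam variant is available
behind a config switch; the plain rule is the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import numpy as np

from .policy import PolicyParams, forward, sample_action, weighted_logprob_grad

__all__ = [
    "EpisodeBatch",
    "TrainConfig",
    "discounted_return",
    "returns_to_go",
    "policy_gradient",
    "update",
    "Adam",
    "train",
    "GaussianBanditEnv",
]


def discounted_return(rewards, gamma: float) -> float:
    """sum_k gamma^k r_k over one episode."""
    rewards = np.asarray(rewards, dtype=float)
    if rewards.size == 0:
        return 0.0
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    return float(np.polynomial.polynomial.polyval(gamma, rewards))


def returns_to_go(rewards: np.ndarray, gamma: float) -> np.ndarray:
    """G_t = sum_{k>=t} gamma^(k-t) r_k along the last axis (reverse scan)."""
    rewards = np.asarray(rewards, dtype=float)
    G = np.empty_like(rewards)
    acc = np.zeros(rewards.shape[:-1])
    for t in range(rewards.shape[-1] - 1, -1, -1):
        acc = rewards[..., t] + gamma * acc
        G[..., t] = acc
    return G


@dataclass
class EpisodeBatch:
    """n same-length trajectories of (state, raw action, reward).

    Shapes: states (n, T, d_s); actions (n, T, 2); rewards (n, T).
    """

    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        n, T, _ = self.states.shape
        if self.actions.shape[:2] != (n, T) or self.rewards.shape != (n, T):
            raise ValueError("inconsistent EpisodeBatch shapes")

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def T(self) -> int:
        return self.states.shape[1]


def policy_gradient(
    batch: EpisodeBatch,
    params: PolicyParams,
    gamma: float,
    baseline: bool = True,
) -> PolicyParams:
    """Score-function estimate of grad_theta of the mean discounted return.

    (1/n) sum_episodes sum_t grad log pi(a_t|s_t) * G_t, with G_t the
    discounted reward-to-go and, if ``baseline``, the across-episode mean of
    G_t at the same t subtracted.
    """
    G = returns_to_go(batch.rewards, gamma)  # (n, T)
    if not np.all(np.isfinite(G)):
        raise FloatingPointError("non-finite returns in batch")
    if baseline and batch.n > 1:
        G = G - G.mean(axis=0, keepdims=True)
    n, T, d_s = batch.states.shape
    S = batch.states.reshape(n * T, d_s)
    A = batch.actions.reshape(n * T, 2)
    w = G.reshape(n * T) / n
    return weighted_logprob_grad(params, S, A, w)


def update(params: PolicyParams, gradient: PolicyParams, lr: float) -> PolicyParams:
    """Plain gradient ascent theta_{k+1} = theta_k + lr * grad."""
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    gradient.check_finite()
    return params.map(gradient, lambda p, g: p + lr * g)


class Adam:
    """Adam ascent (maximization) as an optional drop-in for plain ascent."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: Optional[PolicyParams] = None
        self._v: Optional[PolicyParams] = None
        self._t = 0

    def step(self, params: PolicyParams, grad: PolicyParams) -> PolicyParams:
        grad.check_finite()
        if self._m is None:
            self._m = grad.map(grad, lambda a, b: np.zeros_like(a))
            self._v = self._m.copy()
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        self._m = self._m.map(grad, lambda m, g: b1 * m + (1 - b1) * g)
        self._v = self._v.map(grad, lambda v, g: b2 * v + (1 - b2) * g * g)
        c1 = 1 - b1**self._t
        c2 = 1 - b2**self._t
        mhat = self._m.map(self._m, lambda m, _: m / c1)
        vhat = self._v.map(self._v, lambda v, _: v / c2)
        step = mhat.map(vhat, lambda m, v: self.lr * m / (np.sqrt(v) + self.eps))
        return params.map(step, lambda p, s: p + s)


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: PolicyParams, grad: PolicyParams) -> PolicyParams:
        return update(params, grad, self.lr)


def make_optimizer(name: str, lr: float):
    if name == "sgd":
        return _SGD(lr)
    if name == "adam":
        return Adam(lr)
    raise ValueError(f"unknown optimizer {name!r}; expected 'sgd' or 'adam'")


class Env(Protocol):
    """Minimal single-agent episodic environment contract."""

    obs_dim: int
    action_bound: float
    T: int

    def reset(self, rng: np.random.Generator) -> np.ndarray: ...

    def step(self, action: np.ndarray) -> tuple[np.ndarray, float]: ...


@dataclass
class TrainConfig:
    n: int = 16
    updates: int = 2000
    lr: float = 1e-3
    gamma: float = 0.9
    baseline: bool = True
    normalize_advantages: bool = False
    optimizer: str = "sgd"
    seed: int = 0
    log_every: int = 0  # 0 disables printing


def collect_episodes(env: Env, params: PolicyParams, n: int, rng: np.random.Generator) -> EpisodeBatch:
    T, d = env.T, env.obs_dim
    states = np.empty((n, T, d))
    actions = np.empty((n, T, 2))
    rewards = np.empty((n, T))
    for e in range(n):
        obs = env.reset(rng)
        for t in range(T):
            dist = forward(params, obs)
            clipped, raw = sample_action(dist, env.action_bound, rng)
            states[e, t] = obs
            actions[e, t] = raw
            obs, r = env.step(clipped)
            rewards[e, t] = r
    return EpisodeBatch(states, actions, rewards)


def train(
    env: Env,
    params: PolicyParams,
    cfg: TrainConfig,
    callback: Optional[Callable[[int, float], None]] = None,
) -> tuple[PolicyParams, "pd.DataFrame"]:
    """Iterate collect -> gradient -> update; returns params and metrics."""
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    opt = make_optimizer(cfg.optimizer, cfg.lr)
    rows = []
    for k in range(cfg.updates):
        batch = collect_episodes(env, params, cfg.n, rng)
        mean_return = float(
            np.mean([discounted_return(batch.rewards[e], cfg.gamma) for e in range(cfg.n)])
        )
        if not np.isfinite(mean_return):
            raise FloatingPointError(f"training diverged at update {k}")
        grad = policy_gradient(batch, params, cfg.gamma, baseline=cfg.baseline)
        params = opt.step(params, grad)
        sig = forward(params, batch.states[0, 0]).sigma
        rows.append({"update": k, "mean_return": mean_return, "mean_sigma": float(np.mean(sig))})
        if callback is not None:
            callback(k, mean_return)
        if cfg.log_every and k % cfg.log_every == 0:
            print(f"update {k:5d}  mean_return {mean_return:+.4f}")
    return params, pd.DataFrame(rows)


class GaussianBanditEnv:
    """One-step continuous bandit with reward -||a||^2.

    The optimal policy mean is the origin; used as an analytic oracle for
    the gradient estimator and the training loop.
    """

    def __init__(self, obs_dim: int = 2, T: int = 1, action_bound: float = np.inf):
        self.obs_dim = obs_dim
        self.T = T
        self.action_bound = action_bound
        self._obs = np.zeros(obs_dim)

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        return self._obs.copy()

    def step(self, action: np.ndarray) -> tuple[np.ndarray, float]:
        return self._obs.copy(), -float(np.dot(action, action))
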