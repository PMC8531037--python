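"""Stochastic Gaussian action policy backed by a small fully connected net.

Architecture: two hidden layers of width 128 with ELU activations, then two
linear heads producing the action mean and (through an exponential) the
strictly positive per-component standard deviation.  The network is small
enough that forward and backward passes are written directly in numpy; the
analytic gradients are verified against finite differences in the tests.

Actions are drawn from the diagonal Gaussian and then norm-clipped to the
physical bound.  The log-density used by the policy-gradient estimator is
evaluated at the *raw* (pre-clip) Gaussian draw, which keeps the score
function exact for the distribution actually sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterator

import numpy as np

from .kinematics import clip_action

__all__ = [
    "PolicyParams",
    "ActionDistribution",
    "elu",
    "init_params",
    "forward",
    "sample_action",
    "log_density",
    "weighted_logprob_grad",
    "HIDDEN_WIDTH",
]

HIDDEN_WIDTH = 128

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PolicyParams:
    """Learnable parameters theta = (W1, b1, W2, b2, heads for mu and sigma)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3_mu: np.ndarray
    b3_mu: np.ndarray
    W3_sigma: np.ndarray
    b3_sigma: np.ndarray

    @property
    def d_s(self) -> int:
        return self.W1.shape[1]

    def arrays(self) -> Iterator[tuple[str, np.ndarray]]:
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    def copy(self) -> "PolicyParams":
        return PolicyParams(**{name: arr.copy() for name, arr in self.arrays()})

    def map(self, other: "PolicyParams", fn) -> "PolicyParams":
        """Elementwise combine with another parameter set (e.g. an update)."""
        return PolicyParams(
            **{name: fn(arr, getattr(other, name)) for name, arr in self.arrays()}
        )

    def check_finite(self) -> None:
        for name, arr in self.arrays():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in parameter {name}")


@dataclass
class ActionDistribution:
    """Diagonal Gaussian over 2D actions."""

    mu: np.ndarray  # (..., 2)
    sigma: np.ndarray  # (..., 2), strictly positive


def elu(x: np.ndarray) -> np.ndarray:
    """ELU(x) = x for x > 0, exp(x) - 1 otherwise (C^1 at zero)."""
    return np.maximum(x, 0.0) + np.expm1(np.minimum(x, 0.0))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    # exp(min(x, 0)) equals 1 for x > 0 and exp(x) otherwise
    return np.exp(np.minimum(x, 0.0))


def init_params(d_s: int, rng: np.random.Generator, hidden: int = HIDDEN_WIDTH) -> PolicyParams:
    """Uniform initialization on [-1/sqrt(fan_in), 1/sqrt(fan_in)] per layer."""
    if d_s < 1:
        raise ValueError("state dimension must be >= 1")

    def u(shape, fan_in):
        w = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-w, w, size=shape)

    return PolicyParams(
        W1=u((hidden, d_s), d_s),
        b1=u(hidden, d_s),
        W2=u((hidden, hidden), hidden),
        b2=u(hidden, hidden),
        W3_mu=u((2, hidden), hidden),
        b3_mu=u(2, hidden),
        W3_sigma=u((2, hidden), hidden),
        b3_sigma=u(2, hidden),
    )


def _forward_cached(params: PolicyParams, S: np.ndarray):
    Z1 = S @ params.W1.T + params.b1
    H1 = elu(Z1)
    Z2 = H1 @ params.W2.T + params.b2
    H2 = elu(Z2)
    mu = H2 @ params.W3_mu.T + params.b3_mu
    log_sigma = H2 @ params.W3_sigma.T + params.b3_sigma
    sigma = np.exp(log_sigma)
    return Z1, H1, Z2, H2, mu, sigma


def forward(params: PolicyParams, s: np.ndarray) -> ActionDistribution:
    """Evaluate mu(s) and sigma(s); accepts a single state or a batch."""
    S = np.asarray(s, dtype=float)
    single = S.ndim == 1
    if single:
        S = S[None, :]
    if S.shape[1] != params.d_s:
        raise ValueError(f"state dim {S.shape[1]} != network input dim {params.d_s}")
    *_, mu, sigma = _forward_cached(params, S)
    if single:
        return ActionDistribution(mu=mu[0], sigma=sigma[0])
    return ActionDistribution(mu=mu, sigma=sigma)


def sample_action(
    dist: ActionDistribution, bound: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a raw Gaussian action and its norm-clipped physical counterpart.

    Returns ``(clipped, raw)``; the raw draw is what the log-density and the
    gradient estimator see.
    """
    raw = dist.mu + dist.sigma * rng.standard_normal(np.shape(dist.mu))
    if raw.ndim == 1:
        return clip_action(raw, bound), raw
    norms = np.linalg.norm(raw, axis=-1, keepdims=True)
    scale = np.minimum(1.0, bound / np.maximum(norms, 1e-300))
    return raw * scale, raw


def log_density(dist: ActionDistribution, a: np.ndarray) -> np.ndarray:
    """Diagonal-Gaussian log pdf of the raw action(s), summed over components."""
    a = np.asarray(a, dtype=float)
    z = (a - dist.mu) / dist.sigma
    return -0.5 * np.sum(z * z + _LOG_2PI, axis=-1) - np.sum(np.log(dist.sigma), axis=-1)


def weighted_logprob_grad(
    params: PolicyParams, S: np.ndarray, A: np.ndarray, w: np.ndarray
) -> PolicyParams:
    """Gradient of sum_b w_b * log pi_theta(a_b | s_b) with respect to theta.

    This is the workhorse of the REINFORCE estimator: with w the per-sample
    (discounted, baseline-subtracted) returns divided by the episode count,
    the result is the policy-gradient estimate.  Backpropagation is written
    out explicitly layer by layer.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    A = np.atleast_2d(np.asarray(A, dtype=float))
    w = np.asarray(w, dtype=float).reshape(-1, 1)

    Z1, H1, Z2, H2, mu, sigma = _forward_cached(params, S)

    inv_var = 1.0 / (sigma * sigma)
    d_mu = (A - mu) * inv_var * w  # d logp / d mu, weighted
    d_logsig = ((A - mu) ** 2 * inv_var - 1.0) * w  # d logp / d log(sigma), weighted

    g_W3_mu = d_mu.T @ H2
    g_b3_mu = d_mu.sum(axis=0)
    g_W3_sigma = d_logsig.T @ H2
    g_b3_sigma = d_logsig.sum(axis=0)

    dH2 = d_mu @ params.W3_mu + d_logsig @ params.W3_sigma
    dZ2 = dH2 * _elu_grad(Z2)
    g_W2 = dZ2.T @ H1
    g_b2 = dZ2.sum(axis=0)

    dH1 = dZ2 @ params.W2
    dZ1 = dH1 * _elu_grad(Z1)
    g_W1 = dZ1.T @ S
    g_b1 = dZ1.sum(axis=0)

    return PolicyParams(
        W1=g_W1,
        b1=g_b1,
        W2=g_W2,
        b2=g_b2,
        W3_mu=g_W3_mu,
        b3_mu=g_b3_mu,
        W3_sigma=g_W3_sigma,
        b3_sigma=g_b3_sigma,
    )


# ---------------------------------------------------------------------------
# Serialization


def save_params(params: PolicyParams, path) -> None:
    """Write parameters as a JSON document (text-only artifact)."""
    import json

    doc = {name: arr.tolist() for name, arr in params.arrays()}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_params(path) -> PolicyParams:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    return PolicyParams(**{k: np.asarray(v, dtype=float) for k, v in doc.items()})
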