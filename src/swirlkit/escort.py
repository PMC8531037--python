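"""One-to-one escort task: a follower pursues an independently moving leader.

The leader traverses a predefined curve at constant speed; the follower
only perceives the 8-component limited state (in-band indicator, approach
indicator, the two velocity directions and its own last force) and acts
through one of the three control regimes A/B/C.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .kinematics import AgentKinematics, EnvConfig, LeaderPath, step
from .perception import ESCORT_DIM, encode_escort
from .rewards import RewardConstants, reward_escort

__all__ = ["EscortEnv"]


class EscortEnv:
    """Episodic escort environment usable with :func:`swirlkit.reinforce.train`."""

    obs_dim = ESCORT_DIM

    def __init__(
        self,
        cfg: EnvConfig,
        path: LeaderPath,
        mode: str = "C",
        constants: Optional[RewardConstants] = None,
        init_spread: float = 1.0,
    ):
        if mode not in ("A", "B", "C"):
            raise ValueError(f"unknown escort scenario {mode!r}")
        self.cfg = cfg
        self.path = path
        self.mode = mode
        self.k = constants or RewardConstants()
        self.init_spread = init_spread
        self.T = cfg.T
        self.action_bound = cfg.F_max if mode == "C" else cfg.v_max
        self._t = 0
        self._follower: Optional[AgentKinematics] = None
        self._prev_dist: Optional[float] = None

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        self._t = 0
        # follower starts near the band around the leader's initial position
        angle = rng.uniform(0, 2 * np.pi)
        radius = self.cfg.d_t + rng.uniform(-1, 1) * self.init_spread
        offset = radius * np.array([np.cos(angle), np.sin(angle)])
        self._follower = AgentKinematics(
            position=self.path.position(0.0) + offset,
            velocity=np.zeros(2),
        )
        obs, dist = encode_escort(
            self.path.position(0.0), self.path.velocity(0.0), self._follower, None, self.cfg
        )
        self._prev_dist = dist
        return obs.vector()

    def step(self, action: np.ndarray) -> tuple[np.ndarray, float]:
        self._t += 1
        t_now = self._t * self.cfg.dt
        self._follower = step(self._follower, action, self.mode, self.cfg)
        obs, dist = encode_escort(
            self.path.position(t_now),
            self.path.velocity(t_now),
            self._follower,
            self._prev_dist,
            self.cfg,
        )
        self._prev_dist = dist
        return obs.vector(), reward_escort(obs, self.k)

    # convenience for rollout inspection
    def follower_state(self) -> AgentKinematics:
        return self._follower
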