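# swirlkit

Reinforcement-learning models of collective animal motion in 2D:

* **Escort pursuit** — a follower with severely limited perception (binary
  distance-band and approach indicators, velocity directions, its own last
  force) learns to stay within a comfort zone around an independently moving
  leader, under three control regimes: unbounded velocity control (A),
  velocity control with an acceleration cap (B), and bounded force-only
  control (C).
* **Swirling swarms** — N identical agents learn the same escort behaviour
  with respect to their own group centre; collective rotation (milling)
  emerges and is quantified by the mean angular velocity order parameter Ω.
* **Perturbation resistance** — swarms trained for swirling are compared to
  untrained controls under a randomly directed external force with
  stretched-exponential magnitudes; the observable is the shift of the swarm
  centre along the force direction.
* **Energy-optimal group locomotion** — spherical agents in viscous fluid at
  low Reynolds number (Rotne–Prager mobility tensors): direct minimization of
  dissipated power over formations, and an RL environment in which followers
  learn to draft behind a leader.

Learning uses EPISODIC REINFORCE (score-function policy gradient over whole
episodes) on a Gaussian policy whose mean and standard deviation come from a
three-layer fully connected network (two ELU hidden layers of width 128, an
exponential head for the standard deviation).  The network and its
backpropagation are implemented directly in numpy; gradients are verified
against finite differences in the test suite.

## Command line

```bash
swirlkit demo                        # <2 min smoke run of every experiment
swirlkit escort --scenario C --leader circle --seed 0 --out out/escort
swirlkit swarm train --n-agents 20 --seed 0 --out out/swarm
swirlkit swarm rollout --config cfg.yaml --out out/rollout
swirlkit perturb --f0-grid 0.05,0.1,0.2 --reps 10 --out out/perturb
swirlkit hydro-opt --n 3 --restarts 64
swirlkit hydro-rl --n 2 --updates 300
```

Configuration files are YAML with strict validation (unknown keys rejected);
every output directory receives a JSON manifest with the seed and a config
hash sufficient to reproduce the run exactly.

## Observation layouts

| task | length | order |
|---|---|---|
| escort | 8 | S_d, S_a, leader dir (2), self dir (2), last force (2) |
| swarm | 12 | S_cz, S_ca, S_gc, S_ga, neighbour dir (2), self dir (2), last force (2), group-velocity dir (2) |
| locomotion | 9 + 4(N−1) | rel. leader pos (2), rel. positions (2(N−1)), self velocity (2), rel. velocities (2(N−1)), last force (2), S_cz, S_ca, S_d |

Indicator conventions: Heaviside boundary H(0)=1 (band edge counts as
inside); approach indicators compare distances across one time step and are
0 on the first step; zero-velocity directions encode as the (0, 0) sentinel.

## Package layout

| module | contents |
|---|---|
| `swirlkit.kinematics` | action clipping, Euler stepping (modes A/B/C), leader paths |
| `swirlkit.perception` | indicators, direction encodings, observation vectors |
| `swirlkit.rewards` | reward rules for escort / swarm / locomotion |
| `swirlkit.policy` | Gaussian MLP policy, sampling, log-density, backprop |
| `swirlkit.reinforce` | returns, REINFORCE gradient, optimizers, training loop |
| `swirlkit.escort` | one-to-one escort environment |
| `swirlkit.swirl` | swarm environment, Ω order parameter, swarm training |
| `swirlkit.perturbation` | stretched-exponential force field, resistance trials |
| `swirlkit.hydro` | Rotne–Prager mobilities, power minimization, locomotion RL |
| `swirlkit.experiments` | desk-scale recipes shared by tests and the acceptance report |
| `swirlkit.config` / `swirlkit.cli` | YAML configs, output writers, CLI |
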