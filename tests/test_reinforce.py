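import numpy as np
import pytest

from swirlkit.policy import (
    ActionDistribution,
    PolicyParams,
    forward,
    init_params,
    log_density,
    sample_action,
)
from swirlkit.reinforce import (
    Adam,
    EpisodeBatch,
    GaussianBanditEnv,
    TrainConfig,
    discounted_return,
    policy_gradient,
    returns_to_go,
    train,
    update,
)


def loop_discounted(rewards, gamma):
    acc, g = 0.0, 1.0
    for r in rewards:
        acc += g * r
        g *= gamma
    return acc


class TestDiscountedReturn:
    def test_printed_example(self):
        assert discounted_return([1, 1, 1], 0.9) == pytest.approx(2.71)

    def test_zeros(self):
        assert discounted_return(np.zeros(10), 0.9) == 0.0

    def test_empty(self):
        assert discounted_return([], 0.9) == 0.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            r = rng.normal(size=rng.integers(1, 30))
            g = rng.uniform(0.1, 0.99)
            assert discounted_return(r, g) == pytest.approx(loop_discounted(r, g), abs=1e-12)

    def test_bad_gamma(self):
        with pytest.raises(ValueError):
            discounted_return([1.0], 1.0)


class TestReturnsToGo:
    def test_matches_loop(self, rng):
        r = rng.normal(size=12)
        G = returns_to_go(r, 0.9)
        for t in range(12):
            assert G[t] == pytest.approx(loop_discounted(r[t:], 0.9), abs=1e-10)

    def test_batched(self, rng):
        R = rng.normal(size=(4, 9))
        G = returns_to_go(R, 0.8)
        for e in range(4):
            np.testing.assert_allclose(G[e], returns_to_go(R[e], 0.8))


class TestUpdate:
    def test_zero_gradient_noop(self, rng):
        p = init_params(4, rng, hidden=4)
        zero = p.map(p, lambda a, b: np.zeros_like(a))
        out = update(p, zero, lr=0.5)
        for (_, a), (_, b) in zip(p.arrays(), out.arrays()):
            np.testing.assert_array_equal(a, b)

    def test_unit_lr_exact_shift(self, rng):
        p = init_params(4, rng, hidden=4)
        g = init_params(4, np.random.default_rng(99), hidden=4)
        out = update(p, g, lr=1.0)
        for (_, a), (_, ga), (_, o) in zip(p.arrays(), g.arrays(), out.arrays()):
            np.testing.assert_allclose(o, a + ga)

    def test_two_half_steps_equal_one(self, rng):
        p = init_params(4, rng, hidden=4)
        g = init_params(4, np.random.default_rng(99), hidden=4)
        one = update(p, g, lr=0.2)
        two = update(update(p, g, lr=0.1), g, lr=0.1)
        for (_, a), (_, b) in zip(one.arrays(), two.arrays()):
            np.testing.assert_allclose(a, b, atol=1e-14)

    def test_nonfinite_gradient_aborts(self, rng):
        p = init_params(4, rng, hidden=4)
        g = p.copy()
        g.W1[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            update(p, g, lr=0.1)


def _bandit_batch(params, mu_offset, n, rng, sigma_override=None):
    """Collect one-step bandit episodes; reward -||a||^2."""
    S = np.zeros((n, 1, 2))
    A = np.empty((n, 1, 2))
    R = np.empty((n, 1))
    for e in range(n):
        d = forward(params, S[e, 0])
        if sigma_override is not None:
            d = ActionDistribution(mu=d.mu, sigma=np.full(2, sigma_override))
        _, raw = sample_action(d, np.inf, rng)
        A[e, 0] = raw
        R[e, 0] = -np.dot(raw, raw)
    return EpisodeBatch(S, A, R)


class TestPolicyGradientEstimator:
    def test_constant_reward_baseline_zeroes_gradient(self, rng):
        p = init_params(3, rng, hidden=6)
        n, T = 8, 5
        S = rng.normal(size=(n, T, 3))
        A = rng.normal(size=(n, T, 2))
        R = np.ones((n, T))
        g = policy_gradient(EpisodeBatch(S, A, R), p, gamma=0.9, baseline=True)
        # identical rewards for every episode -> advantages vanish exactly
        for name, arr in g.arrays():
            np.testing.assert_allclose(arr, 0.0, atol=1e-12)

    def test_bandit_gradient_closed_form(self):
        # E[R] = -(mu^2 + sigma^2); d/dmu at mu=(1,0) is (-2, 0)
        rng = np.random.default_rng(42)
        hidden = 4
        p = PolicyParams(
            W1=np.zeros((hidden, 2)),
            b1=np.zeros(hidden),
            W2=np.zeros((hidden, hidden)),
            b2=np.zeros(hidden),
            W3_mu=np.zeros((2, hidden)),
            b3_mu=np.array([1.0, 0.0]),
            W3_sigma=np.zeros((2, hidden)),
            b3_sigma=np.full(2, np.log(0.05)),
        )
        n = 10_000
        batch = _bandit_batch(p, 1.0, n, rng)
        g = policy_gradient(batch, p, gamma=0.9, baseline=False)
        # gradient w.r.t. b3_mu equals dE[R]/dmu = -2*mu; per-sample sd ~ mu^2/sigma
        # gives SE ~ 0.2 at n=1e4, so test at 3 SE
        assert g.b3_mu[0] == pytest.approx(-2.0, abs=0.6)
        assert g.b3_mu[1] == pytest.approx(0.0, abs=0.6)

    def test_estimator_unbiased_across_sample_sizes(self):
        p = PolicyParams(
            W1=np.zeros((2, 2)), b1=np.zeros(2), W2=np.zeros((2, 2)), b2=np.zeros(2),
            W3_mu=np.zeros((2, 2)), b3_mu=np.array([0.7, -0.3]),
            W3_sigma=np.zeros((2, 2)), b3_sigma=np.zeros(2),
        )
        # analytic: E[R] = -(||mu||^2 + 2); grad wrt mu = -2 mu
        for n in (100, 10_000):
            estimates = []
            for rep in range(20 if n == 100 else 3):
                rng = np.random.default_rng(1000 + rep + n)
                batch = _bandit_batch(p, 0.0, n, rng)
                g = policy_gradient(batch, p, gamma=0.9, baseline=False)
                estimates.append(g.b3_mu.copy())
            est = np.mean(estimates, axis=0)
            se = np.std(estimates, axis=0, ddof=1) / np.sqrt(len(estimates))
            target = -2 * np.array([0.7, -0.3])
            assert np.all(np.abs(est - target) < 3 * np.maximum(se, 0.05))

    def test_baseline_preserves_estimator_mean(self):
        p = PolicyParams(
            W1=np.zeros((2, 2)), b1=np.zeros(2), W2=np.zeros((2, 2)), b2=np.zeros(2),
            W3_mu=np.zeros((2, 2)), b3_mu=np.array([0.5, 0.0]),
            W3_sigma=np.zeros((2, 2)), b3_sigma=np.zeros(2),
        )
        with_b, without_b = [], []
        for rep in range(30):
            rng = np.random.default_rng(rep)
            batch = _bandit_batch(p, 0.0, 200, rng)
            with_b.append(policy_gradient(batch, p, 0.9, baseline=True).b3_mu)
            rng = np.random.default_rng(rep)
            batch = _bandit_batch(p, 0.0, 200, rng)
            without_b.append(policy_gradient(batch, p, 0.9, baseline=False).b3_mu)
        m1, m2 = np.mean(with_b, axis=0), np.mean(without_b, axis=0)
        se = np.std(without_b, axis=0, ddof=1) / np.sqrt(30)
        assert np.all(np.abs(m1 - m2) < 4 * np.maximum(se, 0.02))


class TestTwoStepMdpFiniteDifference:
    """Estimator mean vs central finite differences of Monte-Carlo <R>."""

    @staticmethod
    def _rollout_return(theta_mu, rng, n, gamma=0.9):
        # tiny 2-step MDP: s0 = 0, a0 ~ N(theta, sigma0); s1 = a0; r depends on both
        sigma = 0.4
        a0 = theta_mu + sigma * rng.standard_normal((n, 2))
        r0 = -np.sum(a0**2, axis=1)
        a1 = theta_mu + sigma * rng.standard_normal((n, 2))
        r1 = -np.sum((a1 - 1.0) ** 2, axis=1)
        return r0 + gamma * r1

    def test_gradient_matches_fd(self):
        gamma, sigma = 0.9, 0.4
        theta = np.array([0.3, -0.2])
        n = 40_000
        rng = np.random.default_rng(0)
        # REINFORCE estimate with reward-to-go
        a0 = theta + sigma * rng.standard_normal((n, 2))
        r0 = -np.sum(a0**2, axis=1)
        a1 = theta + sigma * rng.standard_normal((n, 2))
        r1 = -np.sum((a1 - 1.0) ** 2, axis=1)
        G0 = r0 + gamma * r1
        G1 = r1
        score0 = (a0 - theta) / sigma**2
        score1 = (a1 - theta) / sigma**2
        per_ep = score0 * G0[:, None] + gamma * score1 * G1[:, None]
        est = per_ep.mean(axis=0)
        se = per_ep.std(axis=0, ddof=1) / np.sqrt(n)

        # central finite differences of the Monte-Carlo average return
        h = 0.05
        fd = np.empty(2)
        for k in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            rp = self._rollout_return(tp, np.random.default_rng(123), 400_000).mean()
            rm = self._rollout_return(tm, np.random.default_rng(123), 400_000).mean()
            fd[k] = (rp - rm) / (2 * h)
        assert np.all(np.abs(est - fd) < 3 * np.maximum(se, 0.02))


class TestTraining:
    def test_bandit_converges_to_origin(self):
        env = GaussianBanditEnv()
        rng = np.random.default_rng(5)
        params = init_params(env.obs_dim, rng, hidden=16)
        cfg = TrainConfig(n=64, updates=200, lr=0.05, gamma=0.9, optimizer="adam", seed=5)
        params, metrics = train(env, params, cfg)
        d = forward(params, np.zeros(2))
        assert np.linalg.norm(d.mu) < 0.1
        assert metrics.mean_return.iloc[-20:].mean() > metrics.mean_return.iloc[:20].mean()

    def test_learning_curve_deterministic(self):
        env = GaussianBanditEnv()
        curves = []
        for _ in range(2):
            params = init_params(env.obs_dim, np.random.default_rng(3), hidden=8)
            _, m = train(env, params, TrainConfig(n=8, updates=10, lr=0.01, seed=3))
            curves.append(m.mean_return.to_numpy())
        np.testing.assert_array_equal(curves[0], curves[1])

    def test_moving_average_improves(self):
        env = GaussianBanditEnv()
        params = init_params(env.obs_dim, np.random.default_rng(11), hidden=16)
        _, m = train(env, params, TrainConfig(n=32, updates=120, lr=0.05, optimizer="adam", seed=11))
        smooth = m.mean_return.rolling(20).mean().dropna()
        assert smooth.iloc[-1] > smooth.iloc[0]


class TestAdam:
    def test_step_direction(self, rng):
        p = init_params(3, rng, hidden=4)
        g = p.map(p, lambda a, b: np.ones_like(a))
        opt = Adam(lr=0.1)
        out = opt.step(p, g)
        for (_, a), (_, b) in zip(p.arrays(), out.arrays()):
            assert np.all(b >= a)  # positive gradient -> ascent
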