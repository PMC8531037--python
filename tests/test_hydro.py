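import itertools
import math

import numpy as np
import pytest

from swirlkit.hydro import (
    HydroParams,
    LocomotionEnv,
    mobility_matrix,
    optimize_configuration,
    pair_block,
    solo_power,
    solve_common_velocity,
    specific_power,
    train_locomotion,
)
from swirlkit.kinematics import EnvConfig
from swirlkit.reinforce import TrainConfig

P = HydroParams()  # a=1, drag coefficient 6*pi*eta*a = 1


class TestPairBlock:
    def test_self_block_identity(self):
        blk = pair_block(np.zeros(2), P)
        np.testing.assert_allclose(blk, np.eye(2) / P.drag)
        assert P.drag == pytest.approx(1.0)

    def test_contact_parallel_coefficient(self):
        # symbolic substitution at x = 2a along the line of centres:
        # (3/4)(1/2)(1+1) + (1/2)(1/8)(1-3) = 3/4 - 1/8 = 5/8
        blk = pair_block(np.array([2.0, 0.0]), P)
        assert blk[0, 0] * P.drag == pytest.approx(5.0 / 8.0)
        # perpendicular coefficient: (3/8)(1) + (1/16)(1) = 7/16
        assert blk[1, 1] * P.drag == pytest.approx(7.0 / 16.0)
        assert blk[0, 1] == pytest.approx(0.0)

    def test_far_field_decay_like_1_over_x(self):
        b1 = pair_block(np.array([100.0, 0.0]), P)
        b2 = pair_block(np.array([200.0, 0.0]), P)
        assert b1[0, 0] / b2[0, 0] == pytest.approx(2.0, rel=1e-3)

    def test_below_contact_warns(self):
        with pytest.warns(RuntimeWarning):
            pair_block(np.array([1.0, 0.0]), P)

    def test_symmetry_in_separation_sign(self, rng):
        x = rng.normal(size=2) * 3 + 5
        np.testing.assert_allclose(pair_block(x, P), pair_block(-x, P))


class TestMobilityMatrix:
    def _random_config(self, rng, n):
        # rejection-sample a non-overlapping configuration
        while True:
            pos = rng.uniform(-10, 10, size=(n, 2))
            d = [np.linalg.norm(pos[i] - pos[j]) for i in range(n) for j in range(i + 1, n)]
            if min(d) > 2.05:
                return pos

    def test_symmetric_and_spd_on_100_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            pos = self._random_config(rng, n)
            M = mobility_matrix(pos, P)
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            np.linalg.cholesky(M)  # raises if not positive definite

    def test_coincident_agents_error(self):
        with pytest.raises(ValueError):
            mobility_matrix(np.zeros((2, 2)), P)


class TestSolveCommonVelocity:
    def test_single_agent_stokes(self):
        v = np.array([1.0, 0.0])
        F, Pw = solve_common_velocity(np.zeros((1, 2)), v, P)
        np.testing.assert_allclose(F, [[1.0, 0.0]])
        assert Pw == pytest.approx(solo_power(v, P)) == pytest.approx(1.0)

    def test_far_apart_pair_decouples(self):
        # analytic far field: P/N = 1/(1+c)^2 with c = 3a/(2x) for in-line motion
        pos = np.array([[0.0, 0.0], [100.0, 0.0]])
        sp = specific_power(pos, np.array([1.0, 0.0]), P)
        c = 3.0 / (2.0 * 100.0)
        assert sp == pytest.approx(1.0 / (1.0 + c) ** 2, abs=1e-4)
        # and decoupling is complete by 10^4 radii
        far = np.array([[0.0, 0.0], [10_000.0, 0.0]])
        assert specific_power(far, np.array([1.0, 0.0]), P) == pytest.approx(1.0, abs=3e-4)

    def test_in_line_beats_side_by_side(self):
        v = np.array([1.0, 0.0])
        inline = np.array([[0.0, 0.0], [3.0, 0.0]])
        side = np.array([[0.0, 0.0], [0.0, 3.0]])
        _, P_in = solve_common_velocity(inline, v, P)
        _, P_side = solve_common_velocity(side, v, P)
        assert P_in < P_side

    def test_matches_dense_solver_oracle(self, rng):
        """Independent oracle: build the matrix from pair_block directly and
        solve with scipy's LU factorization."""
        from scipy.linalg import lu_factor, lu_solve

        for _ in range(10):
            n = int(rng.integers(2, 6))
            pos = rng.uniform(-8, 8, size=(n, 2))
            d = [np.linalg.norm(pos[i] - pos[j]) for i in range(n) for j in range(i + 1, n)]
            if min(d) < 2.1:
                continue
            v = rng.normal(size=2)
            M = np.zeros((2 * n, 2 * n))
            for i in range(n):
                for j in range(n):
                    M[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = pair_block(pos[i] - pos[j], P)
            F_oracle = lu_solve(lu_factor(M), np.tile(v, n)).reshape(n, 2)
            P_oracle = np.sum(F_oracle**2) / P.drag
            F, Pw = solve_common_velocity(pos, v, P)
            np.testing.assert_allclose(F, F_oracle, atol=1e-10)
            assert Pw == pytest.approx(P_oracle, rel=1e-10)

    def test_translation_invariance(self, rng):
        pos = np.array([[0.0, 0.0], [3.0, 1.0], [-2.0, 4.0]])
        v = np.array([0.7, -0.4])
        _, P1 = solve_common_velocity(pos, v, P)
        _, P2 = solve_common_velocity(pos + rng.normal(size=2) * 50, v, P)
        assert P1 == pytest.approx(P2, rel=1e-12)

    def test_rotation_equivariance(self):
        theta = 0.8
        c, s = math.cos(theta), math.sin(theta)
        R = np.array([[c, -s], [s, c]])
        pos = np.array([[0.0, 0.0], [3.0, 1.0], [-2.0, 4.0]])
        v = np.array([0.7, -0.4])
        _, P1 = solve_common_velocity(pos, v, P)
        _, P2 = solve_common_velocity(pos @ R.T, R @ v, P)
        assert P1 == pytest.approx(P2, rel=1e-10)


class TestOptimizeConfiguration:
    def test_n2_matches_grid_search_oracle(self):
        """Brute-force grid over (separation, orientation) for the pair."""
        best = (np.inf, None)
        v = np.array([1.0, 0.0])
        for sep in np.linspace(2.0, 6.0, 60):
            for th in np.linspace(0, np.pi, 60):
                d = sep * np.array([np.cos(th), np.sin(th)]) / 2
                pos = np.array([-d, d])
                sp = specific_power(pos, v, P)
                if sp < best[0]:
                    best = (sp, (sep, th))
        res = optimize_configuration(2, restarts=12, rng=np.random.default_rng(0))
        # oracle optimum: contact separation, aligned with the motion axis
        assert best[1][0] == pytest.approx(2.0)
        assert best[1][1] == pytest.approx(0.0, abs=0.03) or best[1][1] == pytest.approx(
            np.pi, abs=0.03
        )
        assert res.best_specific_power == pytest.approx(best[0], rel=1e-3)
        d = res.best_positions[0] - res.best_positions[1]
        assert np.linalg.norm(d) == pytest.approx(2.0, abs=1e-4)
        assert abs(d[1] / d[0]) < 0.01  # in-line with v

    def test_specific_power_strictly_decreasing_to_n4(self):
        values = [1.0]
        for n, restarts in ((2, 8), (3, 16), (4, 24)):
            res = optimize_configuration(n, restarts=restarts, rng=np.random.default_rng(n))
            values.append(res.best_specific_power)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_n3_two_mirror_triangles_base_along_motion(self):
        res = optimize_configuration(3, restarts=40, rng=np.random.default_rng(1))
        assert len(res.minima) == 2
        for pos, _ in res.minima:
            d = sorted(
                np.linalg.norm(a - b)
                for a, b in itertools.combinations(pos, 2)
            )
            # isoceles triangle at contact separations
            assert d[0] == pytest.approx(2.0, abs=1e-3)
            assert d[1] == pytest.approx(2.0, abs=1e-3)
            # base along x: two agents share the same y coordinate
            yy = sorted(pos[:, 1])
            assert abs(yy[0] - yy[1]) < 1e-3 or abs(yy[1] - yy[2]) < 1e-3
        # the two realizations are mirror images in y
        a, b = res.minima[0][0], res.minima[1][0]
        mirrored = a * np.array([1.0, -1.0])
        from swirlkit.hydro import _config_distance

        assert _config_distance(np.array(sorted(map(tuple, mirrored))), np.array(sorted(map(tuple, b)))) < 0.05


class TestLocomotionEnv:
    def _env(self, n=2, overlap="clamp"):
        cfg = EnvConfig(N=n, T=30, d_t=6.0, d_cz=2.2, F_max=2.0)
        return LocomotionEnv(cfg, overlap=overlap)

    def test_decoupled_stokes_limit(self):
        env = self._env(n=2)
        env.reset(np.random.default_rng(0))
        env.positions = np.array([[500.0, 0.0], [-500.0, 300.0]])
        env.leader_pos = np.array([0.0, 1000.0])
        F = np.array([[1.0, 0.0], [0.0, 1.0]])
        _, _, info = env.step(F)
        np.testing.assert_allclose(info["velocities"][1], [1.0, 0.0], atol=1e-2)
        np.testing.assert_allclose(info["velocities"][2], [0.0, 1.0], atol=1e-2)

    def test_leader_moves_at_v_lead_exactly(self, rng):
        env = self._env(n=3)
        env.reset(np.random.default_rng(1))
        _, _, info = env.step(rng.normal(size=(3, 2)))
        np.testing.assert_allclose(info["velocities"][0], env.p.v_lead, atol=1e-12)

    def test_passive_followers_advected_by_leader_flow(self):
        """Zero follower forces near a moving leader: followers drift with the
        leader's flow field.  Oracle: velocity = zeta_(follower,leader) F_lead."""
        env = self._env(n=1)
        env.reset(np.random.default_rng(2))
        env.positions = np.array([[-3.0, 0.0]])
        env.leader_pos = np.zeros(2)
        _, _, info = env.step(np.zeros((1, 2)))
        F_lead = info["leader_force"]
        # oracle at the pre-step separation vector
        expected = pair_block(np.array([-3.0, 0.0]), env.p) @ F_lead
        np.testing.assert_allclose(info["velocities"][1], expected, atol=1e-10)
        assert np.linalg.norm(info["velocities"][1]) > 0.05

    def test_power_bookkeeping(self, rng):
        env = self._env(n=3)
        env.reset(np.random.default_rng(3))
        F = rng.normal(size=(3, 2))
        _, _, info = env.step(F)
        # definition check: P = sum ||F||^2 / drag over all agents incl. leader
        F_all = np.vstack([info["leader_force"], np.clip(F, -env.cfg.F_max, env.cfg.F_max)])
        # recompute clipping exactly as the env does
        norms = np.linalg.norm(F, axis=1, keepdims=True)
        Fc = F * np.minimum(1.0, env.cfg.F_max / norms)
        expected = (np.sum(info["leader_force"] ** 2) + np.sum(Fc**2)) / env.p.drag
        assert info["power"] == pytest.approx(expected, rel=1e-12)

    def test_overlap_error_mode(self):
        env = self._env(n=2, overlap="error")
        env.reset(np.random.default_rng(0))
        env.positions = np.array([[0.5, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            env.step(np.zeros((2, 2)))


class TestTrainLocomotion:
    def test_smoke_runs_and_metrics_finite(self):
        cfg = EnvConfig(N=2, T=25, d_t=6.0, d_cz=2.2, F_max=2.0)
        env = LocomotionEnv(cfg)
        _, m = train_locomotion(
            env, TrainConfig(n=2, updates=4, lr=1e-3, optimizer="adam", seed=0), hidden=16
        )
        assert np.isfinite(m.mean_return).all()
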