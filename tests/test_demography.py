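import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import crabipm as c
from crabipm.demography import (Season, expected_trajectory, initial_density,
                                overwinter_survival_prob,
                                overwinter_transition, recruit_density,
                                simulate_trajectory, step_within_season)
from crabipm.kernels import Kernel, growth_kernel
from crabipm.params import OverwinterParams, RecruitInitParams
from crabipm.size_structure import DensityVector


@pytest.fixture()
def rec_params():
    return RecruitInitParams(mu_A=np.log(35.0), sigma_A=0.25, lambda_A=438.0,
                             mu_R=5.4, sigma_R=2.0, mu_lambda=5.4,
                             sigma_lambda=1.2)


class TestSeason:
    def test_default_clock(self):
        s = Season()
        assert s.d(1) == 0.0
        assert s.d(s.t_max) == pytest.approx(0.53)
        assert s.dt_step == pytest.approx(0.53 / 14)
        assert s.dt_winter == pytest.approx(0.47)


class TestStepWithinSeason:
    def test_remove_everything_leaves_recruits(self, grid):
        state = DensityVector(grid, np.full(grid.m, 5.0))
        K = Kernel(grid, np.eye(grid.m))
        recruits = DensityVector(grid, np.full(grid.m, 2.0))
        out = step_within_season(state, state, K, recruits)
        np.testing.assert_allclose(out.values, 2.0)

    def test_identity_kernel_subtracts(self, grid):
        state = DensityVector(grid, np.full(grid.m, 5.0))
        removals = DensityVector(grid, np.full(grid.m, 1.0))
        K = Kernel(grid, np.eye(grid.m))
        out = step_within_season(state, removals, K)
        np.testing.assert_allclose(out.values, 4.0)

    def test_excess_removals_raise(self, grid):
        state = DensityVector(grid, np.ones(grid.m))
        removals = DensityVector(grid, np.full(grid.m, 2.0))
        with pytest.raises(ValueError):
            step_within_season(state, removals, Kernel(grid, np.eye(grid.m)))

    def test_conservation_without_mortality(self, grid, truth):
        K = growth_kernel(grid, 0.1, 0.14, 0.04, truth.growth)
        state = DensityVector(grid, np.full(grid.m, 3.0))
        out = step_within_season(state, DensityVector(grid, np.zeros(grid.m)), K)
        assert out.total == pytest.approx(state.total, rel=1e-12)


class TestOverwinterSurvival:
    def test_no_mortality(self):
        p = OverwinterParams(alpha_o=0.0, sigma_o=0.1)
        assert overwinter_survival_prob(50.0, 1000.0, p, 0.0) == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_density(self):
        p = OverwinterParams(alpha_o=2.0, sigma_o=0.1)
        assert overwinter_survival_prob(50.0, 0.0, p, -0.3) == \
            pytest.approx(np.exp(-0.3))

    def test_capped_below_one(self):
        p = OverwinterParams(alpha_o=0.0, sigma_o=0.1)
        assert overwinter_survival_prob(50.0, 0.0, p, 5.0) < 1.0

    @settings(deadline=None, max_examples=30)
    @given(alpha_o=st.floats(0.01, 10.0), x1=st.floats(5.0, 50.0),
           dx=st.floats(0.1, 50.0), n1=st.floats(0.0, 5e3),
           dn=st.floats(0.1, 5e3))
    def test_orderings(self, alpha_o, x1, dx, n1, dn):
        p = OverwinterParams(alpha_o=alpha_o, sigma_o=0.1)
        s_small = overwinter_survival_prob(x1, n1, p, 0.0)
        s_big = overwinter_survival_prob(x1 + dx, n1, p, 0.0)
        s_dense = overwinter_survival_prob(x1, n1 + dn, p, 0.0)
        assert s_big >= s_small
        assert s_dense <= s_small

    def test_alternative_forms(self):
        p = OverwinterParams(alpha_o=1.0, sigma_o=0.1)
        assert overwinter_survival_prob(10.0, 5.0, p, 0.0, "size") == \
            pytest.approx(np.exp(-1 / 100))
        assert overwinter_survival_prob(10.0, 5.0, p, 0.0, "density") == \
            pytest.approx(np.exp(-5.0))
        assert overwinter_survival_prob(10.0, 5.0, p, 0.0, "constant") == \
            pytest.approx(np.exp(-1.0))
        with pytest.raises(ValueError):
            overwinter_survival_prob(10.0, 5.0, p, 0.0, "nope")


class TestOverwinterTransition:
    def test_full_survival(self, grid, truth, rng):
        p = OverwinterParams(alpha_o=0.0, sigma_o=0.1)
        G = Kernel(grid, np.eye(grid.m))
        state = DensityVector(grid, np.full(grid.m, 20.0))
        zero = DensityVector(grid, np.zeros(grid.m))
        out, m_tilde = overwinter_transition(state, zero, G, p, 0.0, rng)
        np.testing.assert_array_equal(out.values, m_tilde)

    def test_no_survival(self, grid, rng):
        p = OverwinterParams(alpha_o=0.0, sigma_o=0.1)
        G = Kernel(grid, np.eye(grid.m))
        state = DensityVector(grid, np.full(grid.m, 20.0))
        zero = DensityVector(grid, np.zeros(grid.m))
        out, _ = overwinter_transition(state, zero, G, p, -50.0, rng)
        assert out.total == 0.0

    def test_binomial_oracle_mean(self, grid):
        # MC mean of survivors matches m_tilde * s within 3 MC s.e.
        rng = np.random.default_rng(42)
        p = OverwinterParams(alpha_o=1.8, sigma_o=0.1)
        G = Kernel(grid, np.eye(grid.m))
        state = DensityVector(grid, np.full(grid.m, 50.0))
        zero = DensityVector(grid, np.zeros(grid.m))
        n_total = state.total
        s = overwinter_survival_prob(grid.midpoints, n_total, p, 0.0)
        j = grid.m - 1  # largest bin: appreciable survival
        draws = np.array([overwinter_transition(state, zero, G, p, 0.0,
                                                rng)[0].values[j]
                          for _ in range(10_000)])
        expect = 50.0 * s[j]
        se = np.sqrt(50.0 * s[j] * (1 - s[j]) / 10_000)
        assert abs(draws.mean() - expect) < 3 * se


class TestInitialAndRecruitDensity:
    def test_initial_total(self, grid, rec_params):
        dv = initial_density(rec_params, grid)
        assert dv.total == pytest.approx(438.0, rel=1e-9)

    def test_initial_concentrates_small_sigma(self, grid):
        p = RecruitInitParams(mu_A=np.log(37.0), sigma_A=1e-5, lambda_A=100.0,
                              mu_R=5.4, sigma_R=2.0, mu_lambda=5.0,
                              sigma_lambda=1.0)
        dv = initial_density(p, grid)
        assert dv.values[grid.locate(37.0)] == pytest.approx(100.0)

    def test_initial_matches_cdf_oracle(self, grid, rec_params):
        dv = initial_density(rec_params, grid)
        dist = stats.lognorm(s=rec_params.sigma_A,
                             scale=np.exp(rec_params.mu_A))
        oracle = np.diff(dist.cdf(grid.edges))
        oracle = 438.0 * oracle / oracle.sum()
        np.testing.assert_allclose(dv.values, oracle, rtol=1e-7, atol=1e-9)

    def test_recruit_total_and_shape(self, grid, rec_params):
        dv = recruit_density(700.0, rec_params, grid)
        assert dv.total == pytest.approx(700.0, rel=1e-9)
        # >= 95% of recruit mass sits in the first three bins
        assert dv.values[:3].sum() / dv.total > 0.95

    def test_recruit_zero(self, grid, rec_params):
        assert recruit_density(0.0, rec_params, grid).total == 0.0
        with pytest.raises(ValueError):
            recruit_density(-1.0, rec_params, grid)


class TestSimulateTrajectory:
    def test_conservation_under_identity_dynamics(self, grid, truth):
        import dataclasses

        params = c.ParameterSet(
            growth=truth.growth,
            mortality=c.MortalityParams(beta=0.0, alpha=0.0),
            overwinter=OverwinterParams(alpha_o=0.0, sigma_o=0.0,
                                        eps_y=np.zeros(1)),
            traps=truth.traps,
            recruit=dataclasses.replace(truth.recruit,
                                        lambda_R_y=np.zeros(2)))
        rng = np.random.default_rng(5)
        traj = simulate_trajectory(params, None, 2, grid, Season(), rng)
        totals = traj.totals()
        np.testing.assert_allclose(totals[:, 0], totals[0, 0], rtol=1e-9)
        np.testing.assert_allclose(totals[:, 1], totals[0, 1], rtol=1e-9)

    def test_zero_effort_no_removals(self, grid, truth, rng):
        traj = simulate_trajectory(truth, None, 2, grid, Season(), rng)
        assert traj.removals.sum() == 0.0

    def test_recruit_pulse_moments(self, grid, truth):
        rng = np.random.default_rng(9)
        traj = simulate_trajectory(truth, None, 200, grid, Season(), rng)
        loglam = np.log(traj.lambda_R)
        mu, sig = truth.recruit.mu_lambda, truth.recruit.sigma_lambda
        assert abs(loglam.mean() - mu) < 3 * sig / np.sqrt(200)
        assert loglam.std() == pytest.approx(sig, rel=0.25)

    def test_recruits_enter_at_t_R(self, grid, truth):
        import dataclasses

        params = c.ParameterSet(
            growth=truth.growth, mortality=c.MortalityParams(0.0, 0.0),
            overwinter=truth.overwinter, traps=truth.traps,
            recruit=dataclasses.replace(truth.recruit, lambda_A=0.0,
                                        lambda_R_y=np.array([100.0])))
        rng = np.random.default_rng(1)
        traj = simulate_trajectory(params, None, 1, grid, Season(), rng)
        t_R = params.recruit.t_R
        assert traj.totals()[t_R - 1, 0] == 0.0
        assert traj.totals()[t_R, 0] == pytest.approx(100.0)

    def test_seeded_determinism(self, grid, truth):
        effort = lambda y, t: [("fukui", 1.0)] * 3
        t1 = simulate_trajectory(truth, effort, 3, grid, Season(),
                                 np.random.default_rng(33))
        t2 = simulate_trajectory(truth, effort, 3, grid, Season(),
                                 np.random.default_rng(33))
        np.testing.assert_array_equal(t1.n, t2.n)
        np.testing.assert_array_equal(t1.removals, t2.removals)


class TestExpectedTrajectory:
    def test_matches_simulation_first_year(self, grid, truth):
        # before any stochastic node fires, expectation == simulation
        rng = np.random.default_rng(2)
        lam = np.array([300.0, 250.0])
        eps = np.zeros(1)
        import dataclasses
        params = c.ParameterSet(
            growth=truth.growth, mortality=truth.mortality,
            overwinter=dataclasses.replace(truth.overwinter,
                                           eps_y=np.zeros(1)),
            traps=truth.traps,
            recruit=dataclasses.replace(truth.recruit, lambda_R_y=lam))
        traj = simulate_trajectory(params, None, 2, grid, Season(), rng)
        removals = np.zeros_like(traj.removals)
        n_exp = expected_trajectory(params, lam, eps, removals, grid, Season())
        np.testing.assert_allclose(n_exp[:, 0], traj.n[:, 0], rtol=1e-9)
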