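import numpy as np
import pytest
from scipy import stats

from crabipm.observation import (RemovalRecord, TrapParams, binom_logpmf,
                                 capture_probability, conditional_trap_probs,
                                 dirichlet_multinomial_logpmf, hazard,
                                 removal_loglik, sample_removals)
from crabipm.size_structure import DensityVector


@pytest.fixture()
def tp():
    return TrapParams(h_max={"fukui": 0.02, "shrimp": 0.06, "minnow": 0.02},
                      h_k={"fukui": 0.25, "shrimp": 0.20},
                      h_0={"fukui": 45.0, "shrimp": 40.0},
                      h_A=45.0, h_sigma=120.0, rho=50.0)


class TestHazard:
    def test_logistic_midpoint(self, tp):
        assert hazard(45.0, "fukui", tp) == pytest.approx(0.01)
        assert hazard(40.0, "shrimp", tp) == pytest.approx(0.03)

    def test_logistic_saturates(self, tp):
        assert hazard(1e4, "fukui", tp) == pytest.approx(0.02)

    def test_minnow_mode(self, tp):
        assert hazard(45.0, "minnow", tp) == pytest.approx(0.02)
        assert hazard(30.0, "minnow", tp) < 0.02
        assert hazard(60.0, "minnow", tp) < 0.02

    def test_unknown_gear(self, tp):
        with pytest.raises(ValueError):
            hazard(50.0, "crab_pot", tp)

    def test_negligible_below_30mm(self, tp):
        # all gears barely catch small crabs with realistic parameters
        for gear in ("fukui", "shrimp", "minnow"):
            p1 = 1 - np.exp(-hazard(25.0, gear, tp) * 1.0)
            assert p1 < 0.02


class TestCaptureProbability:
    def test_no_traps(self, tp):
        assert capture_probability(50.0, [], tp) == 0.0

    def test_two_identical_traps_complement(self, tp):
        p1 = capture_probability(55.0, [("fukui", 1.0)], tp)
        p2 = capture_probability(55.0, [("fukui", 1.0)] * 2, tp)
        assert p2 == pytest.approx(1 - (1 - p1) ** 2, rel=1e-12)

    def test_direct_evaluation(self, tp):
        # H = h_max/2 = 0.01 at the midpoint; soak 5 days
        assert capture_probability(45.0, [("fukui", 5.0)], tp) == \
            pytest.approx(1 - np.exp(-0.05), rel=1e-12)

    def test_monotone_in_soak_and_count(self, tp):
        p_short = capture_probability(60.0, [("fukui", 1.0)], tp)
        p_long = capture_probability(60.0, [("fukui", 2.0)], tp)
        p_two = capture_probability(60.0, [("fukui", 1.0)] * 2, tp)
        assert p_short < p_long
        assert p_short < p_two


class TestConditionalTrapProbs:
    def test_single_trap(self, tp):
        np.testing.assert_allclose(conditional_trap_probs(50.0, [("fukui", 1.0)],
                                                          tp), [1.0])

    def test_symmetry(self, tp):
        pc = conditional_trap_probs(50.0, [("shrimp", 1.0), ("shrimp", 1.0)], tp)
        np.testing.assert_allclose(pc, [0.5, 0.5])

    def test_fukui_dominates_minnow_at_large_size(self, tp):
        pc = conditional_trap_probs(90.0, [("fukui", 1.0), ("minnow", 1.0)], tp)
        # oracle: hazard ratio (minnow hazard vanishes far from its mode)
        hf, hm = hazard(90.0, "fukui", tp), hazard(90.0, "minnow", tp)
        np.testing.assert_allclose(pc, [hf / (hf + hm), hm / (hf + hm)])
        assert pc[0] > 0.999

    def test_all_zero_hazards_warns_uniform(self, tp):
        tp0 = TrapParams(h_max={"fukui": 0.0, "shrimp": 0.0, "minnow": 0.0},
                         h_k=tp.h_k, h_0=tp.h_0, h_A=tp.h_A,
                         h_sigma=tp.h_sigma, rho=tp.rho)
        with pytest.warns(RuntimeWarning):
            pc = conditional_trap_probs(50.0, [("fukui", 1.0), ("shrimp", 1.0)],
                                        tp0)
        np.testing.assert_allclose(pc, [0.5, 0.5])


class TestLogpmfHelpers:
    def test_binom_matches_scipy(self):
        ks = np.arange(0, 11)
        ll = binom_logpmf(ks, 10, 0.3)
        np.testing.assert_allclose(ll, stats.binom.logpmf(ks, 10, 0.3),
                                   rtol=1e-10)

    def test_binom_k_exceeds_n(self):
        assert binom_logpmf(5, 4.5, 0.5) == -np.inf

    def test_dm_matches_scipy(self):
        counts = np.array([3.0, 1.0, 2.0])
        alpha = np.array([2.0, 1.0, 4.0])
        mine = dirichlet_multinomial_logpmf(counts, alpha)
        ref = stats.dirichlet_multinomial(alpha, 6).logpmf(counts)
        assert mine == pytest.approx(float(ref), rel=1e-10)

    def test_dm_zero_total_is_zero(self):
        assert dirichlet_multinomial_logpmf(np.zeros(3), np.ones(3)) == 0.0


class TestRemovalLoglik:
    def test_certain_outcome(self, grid, tp):
        # p ~ 1 everywhere catchable and totals equal latent -> loglik ~ 0
        tp_hot = TrapParams(h_max={"fukui": 1e3, "shrimp": 0.0, "minnow": 0.0},
                            h_k={"fukui": 1e-9, "shrimp": 0.2},
                            h_0={"fukui": 0.0, "shrimp": 40.0},
                            h_A=45.0, h_sigma=120.0, rho=50.0)
        latent = DensityVector(grid, np.full(grid.m, 4.0))
        rec = RemovalRecord(year=0, t=1, trap_id="a", gear="fukui",
                            soak_days=5.0, counts=np.full(grid.m, 4))
        ll = removal_loglik([rec], latent, tp_hot)
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_impossible_observation(self, grid, tp):
        latent = DensityVector(grid, np.ones(grid.m))
        rec = RemovalRecord(year=0, t=1, trap_id="a", gear="fukui",
                            soak_days=1.0, counts=np.full(grid.m, 5))
        assert removal_loglik([rec], latent, tp) == -np.inf

    def test_dm_limits_to_multinomial(self, grid):
        # rho -> inf: trap split converges to multinomial
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, size=(3, grid.m))
        tot = counts.sum(axis=0)
        pc = np.full((3, grid.m), 1 / 3)
        dm = dirichlet_multinomial_logpmf(counts.astype(float), 1e6 * pc)
        ref = np.array([stats.multinomial(int(tot[i]), pc[:, i]).logpmf(
            counts[:, i]) for i in range(grid.m)])
        np.testing.assert_allclose(dm, ref, atol=1e-4)

    def test_likelihood_peaks_near_truth(self, grid, tp, rng):
        # average loglik over simulated data is higher at the generating
        # parameters than at perturbed ones
        latent = DensityVector(grid, np.full(grid.m, 50.0))
        traps = [("fukui", 1.0), ("shrimp", 1.0)]
        tp_pert = TrapParams(h_max={"fukui": 0.08, "shrimp": 0.2,
                                    "minnow": 0.02},
                             h_k=tp.h_k, h_0=tp.h_0, h_A=tp.h_A,
                             h_sigma=tp.h_sigma, rho=tp.rho)
        ll_true = ll_pert = 0.0
        for _ in range(40):
            totals, split = sample_removals(latent, traps, tp, rng)
            recs = [RemovalRecord(year=0, t=1, trap_id=str(j), gear=g,
                                  soak_days=s, counts=split[j])
                    for j, (g, s) in enumerate(traps)]
            ll_true += removal_loglik(recs, latent, tp)
            ll_pert += removal_loglik(recs, latent, tp_pert)
        assert ll_true > ll_pert


class TestSampleRemovals:
    def test_zero_probability(self, grid, tp, rng):
        tp0 = TrapParams(h_max={"fukui": 0.0, "shrimp": 0.0, "minnow": 0.0},
                         h_k=tp.h_k, h_0=tp.h_0, h_A=tp.h_A,
                         h_sigma=tp.h_sigma, rho=tp.rho)
        latent = DensityVector(grid, np.full(grid.m, 100.0))
        totals, split = sample_removals(latent, [("fukui", 1.0)], tp0, rng)
        assert totals.sum() == 0
        assert split.sum() == 0

    def test_mc_mean_matches_binomial(self, grid, tp):
        rng = np.random.default_rng(7)
        latent = DensityVector(grid, np.full(grid.m, 40.0))
        traps = [("fukui", 1.0)] * 3
        p = capture_probability(grid.midpoints, traps, tp)
        n_draws = 10_000
        j = 12  # a well-captured bin
        tot = np.empty(n_draws)
        for i in range(n_draws):
            totals, _ = sample_removals(latent, traps, tp, rng)
            tot[i] = totals[j]
        expect = 40 * p[j]
        se = np.sqrt(40 * p[j] * (1 - p[j]) / n_draws)
        assert abs(tot.mean() - expect) < 3 * se

    def test_split_sums_to_totals(self, grid, tp, rng):
        latent = DensityVector(grid, np.full(grid.m, 200.0))
        traps = [("fukui", 1.0), ("shrimp", 1.0), ("minnow", 1.0)]
        for _ in range(20):
            totals, split = sample_removals(latent, traps, tp, rng)
            np.testing.assert_array_equal(split.sum(axis=0), totals)
            assert np.all(totals <= latent.values)

    def test_dm_overdispersion_exceeds_multinomial(self, grid):
        # small rho inflates the per-trap variance above multinomial
        tp_lo = TrapParams(h_max={"fukui": 0.05, "shrimp": 0.05,
                                  "minnow": 0.0},
                           h_k={"fukui": 0.25, "shrimp": 0.25},
                           h_0={"fukui": 45.0, "shrimp": 45.0},
                           h_A=45.0, h_sigma=120.0, rho=0.5)
        n, pc = 200, 0.5
        rng = np.random.default_rng(11)
        draws_dm = np.array([
            rng.multinomial(n, rng.dirichlet([tp_lo.rho * pc, tp_lo.rho * pc]))[0]
            for _ in range(3000)])
        var_multi = n * pc * (1 - pc)
        assert draws_dm.var() > 1.5 * var_multi


class TestRemovalRecord:
    def test_rejects_bad_gear(self, grid):
        with pytest.raises(ValueError):
            RemovalRecord(year=0, t=1, trap_id="x", gear="net", soak_days=1,
                          counts=np.zeros(grid.m))

    def test_rejects_negative_counts(self, grid):
        with pytest.raises(ValueError):
            RemovalRecord(year=0, t=1, trap_id="x", gear="fukui", soak_days=1,
                          counts=np.full(grid.m, -1))
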