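import numpy as np
import pytest
from scipy import stats as sps

from pupilwave import StatsConfig
from pupilwave.waveform import (GroupWaveforms, PointwiseTest, RunThreshold,
                                cohens_d, compare_groups, estimate_phi,
                                exact_max_run_tail, find_windows,
                                null_max_run, pointwise_welch, run_threshold,
                                stack_waveforms)
from pupilwave.preprocess import CleanTimecourse

nan = np.nan


def gw(label, data, dt=0.1):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return GroupWaveforms(label, data, np.arange(data.shape[1]) * dt)


def ar1_matrix(rng, n, T, phi, sd=1.0):
    x = rng.standard_normal((n, T)) * sd
    for t in range(1, T):
        x[:, t] = phi * x[:, t - 1] + np.sqrt(1 - phi ** 2) * x[:, t]
    return x


class TestPointwiseWelch:
    def test_against_scipy_oracle(self):
        a = np.array([[0.1], [0.2], [0.3]])
        b = np.array([[0.4], [0.5], [0.6]])
        res = pointwise_welch(gw("A", a), gw("B", b),
                              StatsConfig(tail="two_sided"))[0]
        t_ref, p_ref = sps.ttest_ind(a[:, 0], b[:, 0], equal_var=False)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.df == pytest.approx(4.0, abs=1e-10)
        assert res.t == pytest.approx(-3.6742346141747673, abs=1e-9)

    def test_one_tailed_directions(self):
        a = np.array([[0.1], [0.2], [0.3]])
        b = np.array([[0.4], [0.5], [0.6]])
        less = pointwise_welch(gw("A", a), gw("B", b),
                               StatsConfig(tail="A_less"))[0]
        greater = pointwise_welch(gw("A", a), gw("B", b),
                                  StatsConfig(tail="A_greater"))[0]
        assert less.p == pytest.approx(1.0 - greater.p, abs=1e-12)
        assert less.p < 0.05 < greater.p

    def test_identical_groups_t0_p_half(self):
        a = np.array([[0.1, 0.4], [0.2, 0.5], [0.3, 0.6]])
        for tp in pointwise_welch(gw("A", a), gw("B", a.copy()),
                                  StatsConfig(tail="A_less")):
            assert tp.t == 0.0
            assert tp.p == pytest.approx(0.5)

    def test_untestable_timepoint_marked(self):
        a = np.array([[0.1, 0.1], [0.2, nan], [0.3, nan]])
        b = np.array([[0.4, 0.4], [0.5, 0.5]])
        res = pointwise_welch(gw("A", a), gw("B", b), StatsConfig())
        assert res[0].testable
        assert not res[1].testable
        assert np.isnan(res[1].p)

    def test_pairwise_deletion_counts(self):
        a = np.array([[1.0, nan], [2.0, 3.0], [3.0, 4.0]])
        b = np.array([[1.0, 2.0], [2.0, 3.0], [0.5, 1.0]])
        res = pointwise_welch(gw("A", a), gw("B", b), StatsConfig())
        assert res[0].n_A == 3 and res[1].n_A == 2

    def test_welch_matches_scipy_on_random_matrices(self, rng):
        a = rng.normal(0, 1, (8, 40))
        b = rng.normal(0, 2, (12, 40))
        res = pointwise_welch(gw("A", a), gw("B", b),
                              StatsConfig(tail="two_sided"))
        t_ref, p_ref = sps.ttest_ind(a, b, axis=0, equal_var=False)
        for i, tp in enumerate(res):
            assert tp.t == pytest.approx(t_ref[i], abs=1e-10)
            assert tp.p == pytest.approx(p_ref[i], abs=1e-10)

    def test_no_testable_timepoint_raises(self):
        a = np.array([[1.0], [nan]])
        b = np.array([[1.0], [2.0]])
        with pytest.raises(ValueError, match="testable"):
            pointwise_welch(gw("A", a), gw("B", b), StatsConfig())


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # pooled variance = 4/3, d = -1 / sqrt(4/3) = -0.8660
        assert cohens_d([0, 0, 2, 2], [1, 1, 3, 3]) == pytest.approx(
            -np.sqrt(3) / 2, abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning, match="pooled"):
            assert np.isnan(cohens_d([1, 1], [2, 2]))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1, 2])


class TestEstimatePhi:
    def test_white_noise_near_zero(self, rng):
        a = gw("A", rng.standard_normal((12, 600)))
        b = gw("B", rng.standard_normal((12, 600)))
        assert abs(estimate_phi(a, b)) < 0.05

    def test_ar1_recovery(self, rng):
        a = gw("A", ar1_matrix(rng, 12, 600, 0.9))
        b = gw("B", ar1_matrix(rng, 12, 600, 0.9))
        assert estimate_phi(a, b) == pytest.approx(0.9, abs=0.05)

    def test_constant_residuals_error(self):
        a = gw("A", np.ones((3, 10)))
        b = gw("B", np.ones((3, 10)))
        with pytest.raises(ValueError, match="degenerate"):
            estimate_phi(a, b)

    def test_clipped_to_nonnegative(self, rng):
        # per-row amplitudes keep the alternation in the residual, whose
        # lag-1 autocorrelation is then strongly negative -> clipped to 0
        base = np.tile([1.0, -1.0], 50)
        amps = rng.uniform(0.5, 2.0, size=(6, 1))
        data = amps * base
        phi = estimate_phi(gw("A", data), gw("B", data.copy()))
        assert phi == 0.0


class TestExactMaxRunTail:
    @pytest.mark.parametrize("T, alpha", [(10, 0.1), (50, 0.3), (5, 0.9)])
    def test_k1_closed_form(self, T, alpha):
        assert exact_max_run_tail(T, 1, alpha) == pytest.approx(
            1 - (1 - alpha) ** T, abs=1e-12)

    def test_enumeration_t3_k2(self):
        # of the 8 equiprobable outcomes, {011, 110, 111} contain a run >= 2
        assert exact_max_run_tail(3, 2, 0.5) == pytest.approx(0.375, abs=1e-12)

    @pytest.mark.parametrize("T, alpha", [(5, 0.1), (8, 0.5)])
    def test_k_equals_T(self, T, alpha):
        assert exact_max_run_tail(T, T, alpha) == pytest.approx(
            alpha ** T, abs=1e-12)

    def test_k_above_T_is_zero(self):
        assert exact_max_run_tail(5, 6, 0.5) == 0.0

    def test_k_zero_is_one(self):
        assert exact_max_run_tail(5, 0, 0.1) == 1.0

    def test_monotone_in_k(self):
        tails = [exact_max_run_tail(30, k, 0.3) for k in range(1, 10)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_brute_force_enumeration_T6(self):
        # full enumeration over all 2^6 outcomes, alpha = 0.3
        import itertools
        alpha, T, k = 0.3, 6, 3
        total = 0.0
        for bits in itertools.product([0, 1], repeat=T):
            run = best = 0
            prob = 1.0
            for b in bits:
                run = run + 1 if b else 0
                best = max(best, run)
                prob *= alpha if b else 1 - alpha
            if best >= k:
                total += prob
        assert exact_max_run_tail(T, k, alpha) == pytest.approx(total, abs=1e-12)


class TestNullMaxRun:
    def test_alpha_one_forces_full_run(self):
        cfg = StatsConfig(alpha_point=0.999999, n_sim=20, seed=0)
        dist = null_max_run(15, 4, 4, 0.0, cfg)
        assert (dist == 15).all()

    def test_tiny_alpha_gives_zero_runs(self):
        cfg = StatsConfig(alpha_point=1e-9, n_sim=50, seed=0)
        dist = null_max_run(20, 4, 4, 0.0, cfg)
        assert (dist == 0).all()

    def test_phi0_matches_dp_oracle_small(self):
        cfg = StatsConfig(alpha_point=0.1, tail="two_sided", n_sim=2000,
                          seed=3)
        dist = null_max_run(50, 15, 15, 0.0, cfg)
        for k in (1, 2, 3, 5):
            mc = np.mean(dist >= k)
            exact = exact_max_run_tail(50, k, 0.1)
            se = np.sqrt(exact * (1 - exact) / cfg.n_sim)
            assert abs(mc - exact) < 4 * se + 1e-9

    def test_determinism(self):
        cfg = StatsConfig(n_sim=100, seed=5)
        d1 = null_max_run(30, 5, 5, 0.5, cfg)
        d2 = null_max_run(30, 5, 5, 0.5, cfg)
        assert np.array_equal(d1, d2)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            null_max_run(10, 1, 5, 0.0, StatsConfig(n_sim=10))


class TestRunThreshold:
    def test_degenerate_at_zero(self):
        thr = run_threshold(np.zeros(1000, dtype=int), StatsConfig())
        assert thr.k_samples == 1
        assert thr.k_seconds == pytest.approx(0.1)

    def test_uniform_1_to_20(self):
        dist = np.repeat(np.arange(1, 21), 50)   # P(>= 20) = 0.05 exactly
        thr = run_threshold(dist, StatsConfig(alpha_fw=0.05))
        assert thr.k_samples == 20
        assert thr.null_tail == pytest.approx(0.05)

    def test_resolution_error(self):
        with pytest.raises(ValueError, match="n_sim"):
            run_threshold(np.zeros(10, dtype=int),
                          StatsConfig(alpha_fw=0.01))

    def test_null_tail_leq_alpha(self, rng):
        dist = rng.integers(0, 30, size=5000)
        thr = run_threshold(dist, StatsConfig(alpha_fw=0.05))
        assert thr.null_tail <= 0.05
        assert np.mean(dist >= thr.k_samples - 1) > 0.05 or thr.k_samples == 1


def make_tests(pvals, testable=None, dt=0.1):
    testable = [True] * len(pvals) if testable is None else testable
    return [PointwiseTest(time_s=i * dt, t=(1.0 if p < 0.5 else 0.0) + i * 1e-3,
                          df=10.0, p=p, n_A=5, n_B=5,
                          mean_A=0.0, mean_B=0.0, testable=ok)
            for i, (p, ok) in enumerate(zip(pvals, testable))]


def thr(k):
    return RunThreshold(k_samples=k, k_seconds=k * 0.1, phi_hat=0.5,
                        null_tail=0.04, n_sim=1000)


class TestFindWindows:
    a = gw("A", np.random.default_rng(0).normal(0, 1, (5, 12)))
    b = gw("B", np.random.default_rng(1).normal(1, 1, (5, 12)))
    cfg = StatsConfig()

    def test_all_nonsignificant_empty(self):
        out = find_windows(make_tests([0.5] * 12), thr(2), self.a, self.b, self.cfg)
        assert out == []

    def test_run_length_boundary(self):
        p = [0.5] * 12
        p[3:6] = [0.01] * 3
        assert find_windows(make_tests(p), thr(4), self.a, self.b, self.cfg) == []
        wins = find_windows(make_tests(p), thr(3), self.a, self.b, self.cfg)
        assert len(wins) == 1
        w = wins[0]
        assert w.start_s == pytest.approx(0.3)
        assert w.end_s == pytest.approx(0.5)
        assert w.length_samples == 3

    def test_untestable_breaks_runs(self):
        p = [0.01] * 6
        ok = [True, True, True, False, True, True]
        wins = find_windows(make_tests(p, ok), thr(3), self.a, self.b, self.cfg)
        assert len(wins) == 1
        assert wins[0].start_s == pytest.approx(0.0)
        assert wins[0].length_samples == 3

    def test_peak_summary_at_max_abs_t(self):
        p = [0.5] * 12
        p[2:7] = [0.02] * 5
        tests = make_tests(p)
        tests[4].t = -9.0   # largest |t| inside the run
        wins = find_windows(tests, thr(3), self.a, self.b, self.cfg)
        assert wins[0].peak_time_s == pytest.approx(0.4)
        assert wins[0].t == -9.0


class TestCompareGroups:
    def test_identical_groups_no_windows(self, rng):
        data = ar1_matrix(rng, 8, 100, 0.5)
        cfg = StatsConfig(n_sim=400, seed=1)
        rep = compare_groups(gw("A", data), gw("B", data.copy()), cfg)
        assert rep.windows == []
        assert rep.phi_hat > 0.3

    def test_determinism(self, rng):
        a = ar1_matrix(rng, 6, 80, 0.5)
        b = ar1_matrix(rng, 6, 80, 0.5)
        cfg = StatsConfig(n_sim=300, seed=9)
        r1 = compare_groups(gw("A", a), gw("B", b), cfg)
        r2 = compare_groups(gw("A", a), gw("B", b), cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_injected_effect_detected_in_effect_region(self, rng):
        T = 300
        a = ar1_matrix(rng, 12, T, 0.8, sd=0.2)
        b = ar1_matrix(rng, 12, T, 0.8, sd=0.2)
        a[:, 100:200] -= 0.35   # A lower on [10 s, 20 s]
        cfg = StatsConfig(tail="A_less", n_sim=1000, seed=2)
        rep = compare_groups(gw("A", a), gw("B", b), cfg)
        assert rep.windows, "expected at least one window"
        assert any(w.start_s < 20.0 and w.end_s > 10.0 for w in rep.windows)

    def test_opposite_sign_effect_yields_no_effect_window(self, rng):
        T = 300
        a = ar1_matrix(rng, 12, T, 0.8, sd=0.2)
        b = ar1_matrix(rng, 12, T, 0.8, sd=0.2)
        a[:, 100:200] += 0.35   # A higher: wrong direction for A_less
        cfg = StatsConfig(tail="A_less", n_sim=1000, seed=2)
        rep = compare_groups(gw("A", a), gw("B", b), cfg)
        assert not any(10.0 <= w.peak_time_s <= 20.0 for w in rep.windows)

    def test_stack_waveforms_pads_short_rows(self):
        c1 = CleanTimecourse("p1", "g", 0, np.arange(5) * 0.1,
                             np.arange(5.0), 0.0)
        c2 = CleanTimecourse("p2", "g", 0, np.arange(3) * 0.1,
                             np.arange(3.0), 0.0)
        w = stack_waveforms([c1, c2])
        assert w.data.shape == (2, 5)
        assert np.isnan(w.data[1, 3:]).all()
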