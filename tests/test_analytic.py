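"""Closed-form means, extinction theory, asymptotics and MS-G closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import erlangcell as ec
from erlangcell.analytic import DegenerateRatesError, UnsupportedParameterisationError


def ms_matrix(N, lam, mu):
    """Coefficient matrix of the stage-cycling model: the division flux
    returns two cells to stage 1 (independent oracle for the closed forms)."""
    A = np.diag(np.full(N, -(lam + mu)))
    for j in range(N - 1):
        A[j + 1, j] = lam
    A[0, N - 1] += 2 * lam
    return A


class TestMsMeans:
    def test_initial_condition(self):
        ch = ec.StageChain.erlang(4, 0.3, 0.05, C0=77.0)
        assert ec.ms_mean_stages(ch, 0.0) == pytest.approx([77, 0, 0, 0])
        assert ec.ms_mean_total(ch, 0.0) == pytest.approx(77.0)

    def test_single_stage_is_birth_death(self):
        ch = ec.StageChain.erlang(1, 0.4, 0.1, C0=10.0)
        t = np.array([0.0, 2.0, 10.0])
        expected = 10.0 * np.exp((0.4 - 0.1) * t)
        assert ec.ms_mean_stages(ch, t)[0] == pytest.approx(expected)
        assert ec.ms_mean_total(ch, t) == pytest.approx(expected)

    def test_two_stage_hyperbolic_forms(self):
        lam, mu, C0, t = 0.3, 0.05, 100.0, 7.0
        ch = ec.StageChain.erlang(2, lam, mu, C0)
        M = ec.ms_mean_stages(ch, t)
        assert M[0] == pytest.approx(C0 * np.exp(-(lam + mu) * t) * np.cosh(np.sqrt(2) * lam * t))
        assert M[1] == pytest.approx(C0 / np.sqrt(2) * np.exp(-(lam + mu) * t) * np.sinh(np.sqrt(2) * lam * t))

    def test_late_time_stage_ratio(self):
        # five stages, growing regime: M1/M5 approaches 2^{4/5}
        ch = ec.StageChain.erlang(5, 0.8, 0.1, C0=100.0)
        M = ec.ms_mean_stages(ch, 100.0)
        assert M[0] / M[4] == pytest.approx(2 ** 0.8, rel=5e-5)

    def test_total_is_stage_sum_and_satisfies_flux_balance(self):
        ch = ec.StageChain.erlang(3, 0.5, 0.1, C0=20.0)
        t = np.linspace(0, 30, 301)
        M = ec.ms_mean_stages(ch, t)
        tot = ec.ms_mean_total(ch, t)
        assert tot == pytest.approx(M.sum(axis=0), rel=1e-12)
        # dM/dt = lam * M_N - mu * M  (central finite difference)
        dM = np.gradient(tot, t)
        rhs = 0.5 * M[-1] - 0.1 * tot
        assert np.max(np.abs(dM[1:-1] - rhs[1:-1]) / tot[1:-1]) < 1e-3

    def test_unequal_rates_rejected(self):
        ch = ec.StageChain(2, np.array([0.1, 0.2]), 0.0)
        with pytest.raises(UnsupportedParameterisationError):
            ec.ms_mean_stages(ch, 1.0)

    def test_critical_regime_levels_out(self):
        # mu at the extinction boundary: stage j levels out to 2^{(1-j)/N} C0/N
        N, lam, C0 = 5, 0.6, 100.0
        mu = (2 ** (1 / N) - 1) * lam
        ch = ec.StageChain.erlang(N, lam, mu, C0)
        M = ec.ms_mean_stages(ch, 50.0 / lam)
        j = np.arange(1, N + 1)
        plateau = 2.0 ** ((1 - j) / N) * C0 / N
        assert np.max(np.abs(M - plateau) / plateau) < 0.01


class TestGrowthExponent:
    @pytest.mark.parametrize("N,expected", [(1, 1.0), (2, np.sqrt(2) - 1)])
    def test_small_N(self, N, expected):
        assert ec.growth_exponent(N) == pytest.approx(expected)

    def test_large_N_limit(self):
        assert 1_000_000 * ec.growth_exponent(1_000_000) == pytest.approx(np.log(2), abs=1e-5)

    def test_invalid_N(self):
        with pytest.raises(Exception):
            ec.growth_exponent(0)

    def test_late_time_slope_of_log_total(self):
        # log M(t) slope over [200, 400] h equals sigma_N * lam - mu
        for N, lam, mu in [(5, 0.8, 0.1), (2, 0.3, 0.05), (8, 1.0, 0.0)]:
            ch = ec.StageChain.erlang(N, lam, mu, C0=100.0)
            t = np.linspace(200, 400, 21)
            logM = np.log(ec.ms_mean_total(ch, t))
            slope = np.polyfit(t, logM, 1)[0]
            assert slope == pytest.approx(ec.growth_exponent(N) * lam - mu, abs=1e-3)


class TestExtinction:
    def test_single_stage_closed_form(self):
        res = ec.extinction_probabilities(ec.StageChain.erlang(1, 0.5, 0.2))
        assert res.p1 == pytest.approx(0.4)
        assert ec.extinction_probabilities(ec.StageChain.erlang(1, 0.5, 0.9)).p1 == 1.0

    def test_two_stage_closed_form(self):
        lam, mu = 1.0, 0.2
        res = ec.extinction_probabilities(ec.StageChain.erlang(2, lam, mu))
        assert res.p1 == pytest.approx((mu**2 + 2 * mu * lam) / lam**2)

    def test_certain_extinction_branch(self):
        res = ec.extinction_probabilities(ec.StageChain.erlang(5, 0.5, 0.1))
        assert res.certain and np.all(res.p == 1.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(N=st.integers(1, 12), lam=st.floats(0.01, 5.0), mu=st.floats(0.0, 5.0))
    def test_probabilities_and_recursion(self, N, lam, mu):
        res = ec.extinction_probabilities(ec.StageChain.erlang(N, lam, mu))
        assert np.all((res.p >= 0) & (res.p <= 1))
        assert res.certain == (mu >= (2 ** (1 / N) - 1) * lam)
        # first-step fixed point
        a, b = mu / (lam + mu), lam / (lam + mu)
        assert res.p[:-1] == pytest.approx(a + b * res.p[1:], abs=1e-9)
        assert res.p[-1] == pytest.approx(a + b * res.p[0] ** 2, abs=1e-9)

    def test_monte_carlo_corroboration(self):
        # supercritical chain: closed form vs 1e4-replicate Gillespie frequency
        ch = ec.StageChain.erlang(3, 1.0, 0.1)
        exact = ec.extinction_probabilities(ch).p1
        est = ec.estimate_extinction(ch, n_replicates=10_000, t_end=400.0, seed=2024)
        assert abs(est.frequency - exact) < 3 * max(est.std_error, 1e-3)


class TestStationaryFractions:
    def test_single_stage(self):
        assert ec.stationary_stage_fractions(1) == pytest.approx([1.0])

    def test_two_stage_values(self):
        assert ec.stationary_stage_fractions(2) == pytest.approx([2 - np.sqrt(2), np.sqrt(2) - 1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(N=st.integers(1, 200))
    def test_normalised_and_decreasing(self, N):
        frac = ec.stationary_stage_fractions(N)
        assert frac.sum() == pytest.approx(1.0)
        assert np.all(np.diff(frac) < 0) or N == 1


class TestMsgUniform:
    def test_generation_zero_first_stage(self):
        # the founder compartment decays at the total event rate
        vals = ec.msg_uniform_mean(3, 0.2, 0.05, C0=50.0, t=10.0, G=4)
        assert vals[0, 0] == pytest.approx(50.0 * np.exp(-0.25 * 10.0))
        assert vals[1, 0] >= 0

    def test_initial_condition(self):
        vals = ec.msg_uniform_mean(3, 0.2, 0.05, C0=50.0, t=0.0, G=4)
        expected = np.zeros((5, 3))
        expected[0, 0] = 50.0
        assert vals == pytest.approx(expected)

    def test_generation_sum_recovers_stage_means(self):
        # summing the generation ladder at fixed stage reproduces the
        # stage-cycling closed form (the two models share stage marginals)
        N, lam, mu, C0 = 4, 0.3, 0.05, 60.0
        for t in (5.0, 20.0, 60.0):
            ladder = ec.msg_uniform_mean(N, lam, mu, C0, t)   # adaptive cutoff
            stage_sum = ladder.sum(axis=0)
            direct = ec.ms_mean_stages(ec.StageChain.erlang(N, lam, mu, C0), t)
            assert np.max(np.abs(stage_sum - direct) / direct.max()) < 1e-8

    def test_matches_matrix_exponential(self):
        N, lam, mu, C0, G = 3, 0.2, 0.05, 50.0, 10
        sch = ec.build_schedule(C0=C0, N0=N, lambda0=lam, N=N, lam=lam,
                                alpha=0.0, G_max=G, mu_constant=mu)
        t = np.array([6.0, 24.0])
        traj = ec.solve_mean(sch, t)
        ref = np.transpose(ec.msg_uniform_mean(N, lam, mu, C0, t, G=G), (2, 0, 1))
        ref = ref.reshape(t.size, -1)
        assert np.max(np.abs(traj.values - ref)) / ref.max() < 1e-6


class TestMsgExponential:
    def test_generation_zero_and_empty_start(self):
        lams, mus = [0.1, 0.12, 0.14], [0.0, 0.01, 0.02]
        M = ec.msg_exponential_mean(lams, mus, C0=100.0, t=0.0)
        assert M == pytest.approx([100.0, 0.0, 0.0])
        M8 = ec.msg_exponential_mean(lams, mus, C0=100.0, t=8.0)
        assert M8[0] == pytest.approx(100.0 * np.exp(-0.1 * 8.0))

    def test_matches_matrix_exponential(self):
        lams = 0.1 + 0.01 * np.arange(5)
        mus = 0.01 * np.arange(5)
        sch = ec.GenerationSchedule(np.ones(5, int), lams, mus, 100.0)
        t = np.array([48.0])
        ref = ec.msg_exponential_mean(lams, mus, 100.0, t).T
        traj = ec.solve_mean(sch, t)
        assert np.max(np.abs(traj.values - ref) / np.abs(ref)) < 1e-8

    def test_coincident_rate_sums_rejected(self):
        with pytest.raises(DegenerateRatesError):
            ec.msg_exponential_mean([0.1, 0.1], [0.0, 0.0], 10.0, 5.0)


class TestThreeWayAgreement:
    def test_closed_form_matrix_and_ensemble(self):
        """Closed form, matrix exponential and Gillespie ensemble agree."""
        N, lam, mu, C0 = 3, 0.4, 0.08, 30.0
        ch = ec.StageChain.erlang(N, lam, mu, C0)
        t = np.array([4.0, 12.0])
        closed = ec.ms_mean_stages(ch, t).T                       # (T, N)
        oracle = np.stack([expm(ms_matrix(N, lam, mu) * tt) @ [C0, 0, 0] for tt in t])
        assert closed == pytest.approx(oracle, rel=1e-9)
        sch = ec.build_schedule(C0=C0, N0=N, lambda0=lam, N=N, lam=lam,
                                alpha=0.0, G_max=8, mu_constant=mu)
        reps = ec.simulate_ensemble(sch, t, 2000, seed=5)
        stage = np.stack([r.counts.sum(axis=1).astype(float)[:, :N] for r in reps])
        mean = stage.mean(axis=0)
        se = stage.std(axis=0, ddof=1) / np.sqrt(stage.shape[0])
        assert np.all(np.abs(mean - closed) <= 3 * np.maximum(se, 1e-9))
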