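"""MBAR/BAR, TI-Gaussian-quadrature, finite differences, block analysis."""

import inspect
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from abfekit.constants import rt
from abfekit.estimators import (LambdaSchedule, WindowEnergyTable, bar,
                                block_uncertainty, fd_dudl, gq_schedule, mbar,
                                mbar_block_uncertainty, read_table,
                                replica_stats, ti_gq, write_table)
from abfekit.toysampler import exact_gaussian_windows


class TestGQSchedule:
    def test_midpoint_rule_for_n_1(self):
        s = gq_schedule(1)
        assert s.lambdas == (0.5,)
        assert s.weights == (1.0,)

    def test_two_point_nodes_are_legendre_roots(self):
        s = gq_schedule(2)
        expected = (0.5 - 1.0 / (2.0 * math.sqrt(3.0)), 0.5 + 1.0 / (2.0 * math.sqrt(3.0)))
        np.testing.assert_allclose(s.lambdas, expected, atol=1e-14)
        np.testing.assert_allclose(s.weights, (0.5, 0.5), atol=1e-14)

    @pytest.mark.parametrize("n", [1, 2, 3, 7, 12, 32, 64])
    def test_weights_integrate_degree_one_exactly(self, n):
        s = gq_schedule(n)
        assert sum(s.weights) == pytest.approx(1.0, abs=1e-12)
        assert np.dot(s.weights, s.lambdas) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("n", [0, 65])
    def test_window_count_bounds(self, n):
        with pytest.raises(ValueError):
            gq_schedule(n)


class TestTIGQ:
    def test_constant_derivative_returns_it(self):
        s = gq_schedule(5)
        assert ti_gq([3.25] * 5, s) == pytest.approx(3.25)

    def test_zero_derivatives_give_zero(self):
        assert ti_gq([0.0] * 4, gq_schedule(4)) == 0.0

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_polynomial_of_degree_2n_minus_1_integrated_exactly(self, n):
        rng = np.random.default_rng(n)
        coeffs = rng.uniform(-5, 5, size=2 * n)  # degree 2n-1
        poly = np.polynomial.Polynomial(coeffs)
        s = gq_schedule(n)
        means = poly(np.asarray(s.lambdas))
        exact = poly.integ()(1.0) - poly.integ()(0.0)
        assert ti_gq(means, s) == pytest.approx(exact, abs=1e-10)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="node means"):
            ti_gq([1.0, 2.0], gq_schedule(3))

    def test_explicit_schedule_rejected(self):
        s = LambdaSchedule(mode="explicit", lambdas=(0.0, 1.0))
        with pytest.raises(ValueError, match="gauss_quadrature"):
            ti_gq([1.0, 2.0], s)


class TestMBAR:
    def test_identical_windows_give_zero(self):
        table = exact_gaussian_windows([8.0, 8.0], None, 2000, seed=0)
        assert abs(mbar(table).delta_g(0, 1)) < 1e-10

    def test_recovers_harmonic_partition_ratio(self):
        # k vs 4k: ΔG = (RT/2) ln 4, samples drawn exactly
        table = exact_gaussian_windows([10.0, 40.0], None, 10000, seed=1)
        dg = mbar(table).delta_g(0, 1)
        se = mbar_block_uncertainty(table, 10)
        analytic = 0.5 * rt() * math.log(4.0)
        assert abs(dg - analytic) < 3.0 * se

    def test_three_window_ladder_matches_quadrature_oracle(self):
        ks = [5.0, 15.0, 45.0]
        cs = [0.0, 0.3, 0.6]
        table = exact_gaussian_windows(ks, cs, 12000, seed=2)
        result = mbar(table)
        RT = rt()
        z = [quad(lambda x, k=k, c=c: math.exp(-0.5 * k * (x - c) ** 2 / RT),
                  -10, 10)[0] for k, c in zip(ks, cs)]
        for i in range(3):
            for j in range(3):
                oracle = -RT * math.log(z[j] / z[i])
                se = max(mbar_block_uncertainty(table, 10, i, j), 1e-6)
                assert abs(result.delta_g(i, j) - oracle) < 3.0 * se

    def test_translation_invariance_per_sample_column(self):
        table = exact_gaussian_windows([10.0, 25.0], None, 3000, seed=3)
        shifted = WindowEnergyTable(
            u_kn=table.u_kn + np.random.default_rng(0).normal(size=table.n_total),
            N_k=table.N_k, temperature=table.temperature)
        assert mbar(shifted).delta_g(0, 1) == pytest.approx(
            mbar(table).delta_g(0, 1), abs=1e-9)

    def test_antisymmetry_and_cycle_closure(self):
        table = exact_gaussian_windows([5.0, 12.0, 30.0], [0.0, 0.2, 0.5], 2000, seed=4)
        r = mbar(table)
        assert r.delta_g(0, 1) == -r.delta_g(1, 0)
        closure = r.delta_g(0, 1) + r.delta_g(1, 2) + r.delta_g(2, 0)
        assert abs(closure) < 1e-12

    def test_nonconvergence_carries_residual(self):
        from abfekit.estimators import ConvergenceError
        table = exact_gaussian_windows([10.0, 40.0], None, 500, seed=5)
        with pytest.raises(ConvergenceError) as err:
            mbar(table, tol=1e-15, max_iter=3)
        assert err.value.residual > 0


class TestBAR:
    def test_identical_windows_zero(self):
        table = exact_gaussian_windows([6.0, 6.0], None, 1000, seed=6)
        assert abs(bar(table)) < 1e-10

    def test_harmonic_large_n_limit(self):
        table = exact_gaussian_windows([10.0, 40.0], None, 10000, seed=7)
        se = mbar_block_uncertainty(table, 10)
        assert abs(bar(table) - 0.5 * rt() * math.log(4.0)) < 3.0 * se

    def test_equivalent_to_mbar_on_two_windows(self):
        table = exact_gaussian_windows([4.0, 9.0], [0.0, 0.4], 4000, seed=8)
        assert abs(bar(table) - mbar(table).delta_g(0, 1)) < 1e-8

    def test_requires_exactly_two_windows(self):
        table = exact_gaussian_windows([4.0, 9.0, 16.0], None, 100, seed=9)
        with pytest.raises(ValueError, match="two windows"):
            bar(table)


class TestFdDudl:
    def test_potential_linear_in_lambda_is_exact(self):
        c = 7.5
        RT = rt()

        def sampler(lo, hi):
            n = 500
            u_kn = np.vstack([np.full(2 * n, lo * c / RT),
                              np.full(2 * n, hi * c / RT)])
            return WindowEnergyTable(u_kn=u_kn, N_k=np.array([n, n]))

        for delta in (0.001, 0.01, 0.1):
            assert fd_dudl(sampler, 0.5, delta) == pytest.approx(c, abs=1e-8)

    def test_default_delta_lambda_is_0_001(self):
        sig = inspect.signature(fd_dudl)
        assert sig.parameters["delta_lambda"].default == 0.001

    def test_quadratic_coupling_matches_analytic_derivative(self):
        # U(x, λ) = ½k0 x² + λ²·½c x²  →  <∂U/∂λ> = λ c RT/(k0 + λ²c)
        from abfekit.toysampler import LambdaCoupled, sample_windows
        pot = LambdaCoupled(k0=10.0, c=30.0, exponent=2.0)
        lam = 0.6

        tables = {}

        def sampler(lo, hi):
            schedule = LambdaSchedule(mode="explicit", lambdas=(lo, hi))
            table = sample_windows(pot, schedule, 4000, seed=10)
            tables["t"] = table
            return table

        estimate = fd_dudl(sampler, lam)
        analytic = pot.analytic_dudl_mean(lam)
        se = mbar_block_uncertainty(tables["t"], 5) / 0.001
        assert abs(estimate - analytic) < 3.0 * se


class TestBlockUncertainty:
    def test_constant_series_has_zero_uncertainty(self):
        assert block_uncertainty(np.ones(100), 10) == 0.0

    def test_iid_noise_matches_standard_error_formula(self):
        # mean SE of unit-variance noise at length 1e4 is 0.01
        rng = np.random.default_rng(12)
        estimates = [block_uncertainty(rng.standard_normal(10_000), 10)
                     for _ in range(100)]
        assert np.mean(estimates) == pytest.approx(0.01, rel=0.3)

    def test_doubling_length_halves_variance_in_expectation(self):
        rng = np.random.default_rng(13)
        short = np.mean([block_uncertainty(rng.standard_normal(4000), 8) ** 2
                         for _ in range(60)])
        long = np.mean([block_uncertainty(rng.standard_normal(8000), 8) ** 2
                        for _ in range(60)])
        assert short / long == pytest.approx(2.0, rel=0.35)

    def test_remainder_dropped_from_front(self):
        series = np.concatenate([[1000.0], np.zeros(10)])  # remainder holds the spike
        assert block_uncertainty(series, 5) == 0.0

    def test_series_shorter_than_blocks_errors(self):
        with pytest.raises(ValueError, match="blocks"):
            block_uncertainty(np.ones(3), 5)


class TestReplicaStats:
    def test_published_short_protocol_averages_reproduce(self):
        from abfekit.cli import round_half_away
        s = replica_stats([-7.2, -7.4, -7.4, -7.6, -7.0, -7.4])
        assert round_half_away(s.mean) == -7.3
        assert round_half_away(s.spread) == 0.2
        s = replica_stats([-6.9, -7.2, -4.5, -8.6, -8.1, -6.0])
        assert round_half_away(s.mean) == -6.9

    def test_identical_replicas_have_zero_spread(self):
        s = replica_stats([-5.0, -5.0, -5.0])
        assert s.spread == 0.0

    def test_population_convention(self):
        s = replica_stats([1.0, 3.0])
        assert s.spread == pytest.approx(1.0)  # population SD, not sample SD √2

    def test_fewer_than_two_replicas_error(self):
        with pytest.raises(ValueError, match="2 replicas"):
            replica_stats([-5.0])


class TestTableIO:
    def test_roundtrip_with_schedule_and_dudl(self, tmp_path):
        schedule = gq_schedule(3)
        rng = np.random.default_rng(14)
        table = WindowEnergyTable(
            u_kn=rng.normal(size=(3, 30)),
            N_k=np.array([10, 10, 10]),
            schedule=schedule,
            dudl_k=[rng.normal(size=10) for _ in range(3)],
            temperature=300.0)
        path = tmp_path / "windows.tsv"
        write_table(table, path)
        back = read_table(path)
        np.testing.assert_allclose(back.u_kn, table.u_kn, atol=1e-10)
        np.testing.assert_array_equal(back.N_k, table.N_k)
        assert back.temperature == 300.0
        assert back.schedule.lambdas == schedule.lambdas
        for a, b in zip(back.dudl_k, table.dudl_k):
            np.testing.assert_allclose(a, b, atol=1e-12)


@given(st.lists(st.floats(min_value=-30, max_value=30), min_size=2, max_size=6))
def test_mbar_shift_of_one_window_row_shifts_its_free_energy(offsets):
    """Adding a constant to window k's row shifts f_k by that constant."""
    table = exact_gaussian_windows([10.0] * len(offsets), None, 200, seed=15)
    shifted = WindowEnergyTable(
        u_kn=table.u_kn + np.asarray(offsets)[:, None],
        N_k=table.N_k, temperature=table.temperature)
    f0 = mbar(table).f
    f1 = mbar(shifted).f
    expected = np.asarray(offsets) - offsets[0]
    np.testing.assert_allclose(f1 - f0, expected, atol=1e-6)
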