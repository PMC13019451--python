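"""Population-balance tests: analytic oracles, conservation, trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biosos.pbm import (
    GrowthParams,
    KernelParams,
    NumberDensity,
    SizeGrid,
    aggregation_kernel,
    default_grid,
    default_growth,
    default_kernel,
    diameter_to_volume,
    diameters_to_density,
    gompertz_growth_rate,
    simulate_pbm,
    summarize_distribution,
    volume_to_diameter,
)
from biosos.pbm import gompertz_characteristic


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------


class TestAggregationKernel:
    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(1.0, 1e9),
        xp=st.floats(1.0, 1e9),
    )
    def test_symmetric_and_nonnegative(self, x, xp):
        p = KernelParams(k=1e-10, k1=0.8, a=1e7)
        kxy = aggregation_kernel(x, xp, p)
        kyx = aggregation_kernel(xp, x, p)
        assert kxy == pytest.approx(kyx, rel=1e-12)
        assert kxy >= 0

    def test_zero_rate_constant(self):
        p = KernelParams(k=0.0, k1=1.0, a=1e7)
        assert aggregation_kernel(123.0, 456.0, p) == 0.0

    def test_hand_substitution_at_x_eq_a(self):
        k, k1, a = 2.0, 0.7, 1e6
        p = KernelParams(k=k, k1=k1, a=a)
        expected = k * np.exp(-k1) * (2 * a ** (1 / 3)) ** (7 / 3)
        assert aggregation_kernel(a, a, p) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_at_large_sizes(self):
        p = KernelParams(k=1.0, k1=1.0, a=1e6)
        assert aggregation_kernel(1e9, 1e9, p) < aggregation_kernel(1e6, 1e6, p)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            aggregation_kernel(-1.0, 1.0, KernelParams(k=1, k1=1, a=1))

    def test_alternative_parenthesization_available(self):
        p = KernelParams(k=1.0, k1=0.01, a=0.5, form="power")
        x = 1e4
        expected = np.exp(-0.01 * x**0.5) * (2 * x ** (1 / 3)) ** (7 / 3)
        assert aggregation_kernel(x, x, p) == pytest.approx(expected, rel=1e-12)


class TestGompertzGrowth:
    def test_zero_at_maximum_size(self):
        p = GrowthParams(alpha_g=0.01, m_max=1e8)
        assert gompertz_growth_rate(1e8, p) == pytest.approx(0.0)

    def test_value_at_m_over_e(self):
        p = GrowthParams(alpha_g=0.01, m_max=1e8)
        assert gompertz_growth_rate(1e8 / np.e, p) == pytest.approx(
            0.01 * 1e8 / np.e, rel=1e-12
        )

    def test_negative_above_m(self):
        p = GrowthParams(alpha_g=0.01, m_max=1e8)
        assert gompertz_growth_rate(2e8, p) < 0

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            gompertz_growth_rate(0.0, GrowthParams(alpha_g=0.01, m_max=1e8))


# ---------------------------------------------------------------------------
# PBM solver vs analytic oracles
# ---------------------------------------------------------------------------


class TestSimulatePbm:
    def test_frozen_when_both_mechanisms_off(self):
        grid = default_grid()
        counts = np.zeros(grid.n_bins)
        counts[40] = 100.0
        init = NumberDensity.from_counts(grid, counts)
        res = simulate_pbm(init, KernelParams(k=0, k1=1, a=1e7), None, [0, 24, 48])
        for nd in res:
            np.testing.assert_allclose(nd.values, init.values)

    def test_smoluchowski_constant_kernel_count(self):
        """Monodisperse constant-kernel count follows N0/(1 + k N0 t / 2)."""
        grid = SizeGrid.geometric(1.0, 1e7, 100)
        counts = np.zeros(grid.n_bins)
        counts[3] = 1.0
        init = NumberDensity.from_counts(grid, counts)
        ts = np.linspace(0, 10, 11)  # k N0 t in [0, 10]
        res = simulate_pbm(
            init, None, None, ts,
            kernel_fn=lambda x, xp: np.ones(np.broadcast(x, xp).shape),
        )
        for nd, t in zip(res, ts):
            exact = 1.0 / (1.0 + t / 2.0)
            assert nd.total_count() == pytest.approx(exact, rel=0.02)

    def test_mass_conserved_under_pure_coalescence(self):
        """Total aggregate volume drifts < 0.5% over a 5-day horizon."""
        grid = default_grid()
        rng = np.random.default_rng(0)
        init = diameters_to_density(
            rng.lognormal(np.log(260), 0.15, 5000), grid, per_ml=2000.0
        )
        res = simulate_pbm(init, default_kernel(), None, np.linspace(0, 120, 6))
        m0 = res[0].total_mass()
        for nd in res:
            assert abs(nd.total_mass() - m0) / m0 < 0.005

    def test_count_nonincreasing_under_pure_coalescence(self):
        grid = default_grid()
        rng = np.random.default_rng(1)
        init = diameters_to_density(
            rng.lognormal(np.log(260), 0.2, 3000), grid, per_ml=2000.0
        )
        res = simulate_pbm(init, default_kernel(), None, np.linspace(0, 120, 7))
        counts = [nd.total_count() for nd in res]
        assert all(a >= b - 1e-9 for a, b in zip(counts, counts[1:]))

    def test_mean_size_follows_gompertz_characteristic(self):
        """Advection-only pulse mean matches the closed form within 1e-4."""
        grid = default_grid()
        growth = GrowthParams(alpha_g=0.02, m_max=1e8)
        counts = np.zeros(grid.n_bins)
        counts[30] = 5.0
        init = NumberDensity.from_counts(grid, counts)
        ts = np.linspace(0, 120, 6)
        res = simulate_pbm(init, None, growth, ts)
        for nd, t in zip(res, ts):
            mean_x = nd.total_mass() / nd.total_count()
            exact = gompertz_characteristic(grid.pivots[30], t, growth)
            assert abs(mean_x - exact) / exact < 1e-4

    def test_five_day_trend_mean_up_count_down(self):
        """Coalescence + growth: size rises while aggregate number falls."""
        rng = np.random.default_rng(2)
        init = diameters_to_density(
            rng.lognormal(np.log(260), 0.15, 10000), default_grid(), per_ml=2000.0
        )
        res = simulate_pbm(
            init, default_kernel(), default_growth(), np.linspace(0, 96, 5), dt=2.0
        )
        means = [summarize_distribution(nd).mean_diameter for nd in res]
        counts = [nd.total_count() for nd in res]
        assert all(a < b for a, b in zip(means, means[1:]))
        assert all(a > b for a, b in zip(counts, counts[1:]))
        assert means[-1] > 1.5 * means[0]

    def test_gillespie_oracle_count_trajectory(self):
        """Sectional count matches discrete-event coalescence within 5%."""
        n0 = 2000
        k_hat = 1.0 / n0  # pairwise rate so k * N0 = 1 per unit time
        rng = np.random.default_rng(7)

        def gillespie_counts(t_grid):
            n = n0
            t = 0.0
            out = []
            i = 0
            while i < len(t_grid):
                rate = k_hat * n * (n - 1) / 2.0
                dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                while i < len(t_grid) and t + dt > t_grid[i]:
                    out.append(n)
                    i += 1
                t += dt
                n -= 1
            return np.array(out, dtype=float)

        t_grid = np.linspace(0, 8, 9)
        mc = np.mean([gillespie_counts(t_grid) for _ in range(30)], axis=0)

        grid = SizeGrid.geometric(1.0, 1e7, 90)
        counts = np.zeros(grid.n_bins)
        counts[3] = float(n0)
        init = NumberDensity.from_counts(grid, counts)
        res = simulate_pbm(
            init, None, None, t_grid,
            kernel_fn=lambda x, xp: k_hat * np.ones(np.broadcast(x, xp).shape),
        )
        sect = np.array([nd.total_count() for nd in res])
        np.testing.assert_allclose(sect, mc, rtol=0.05)


# ---------------------------------------------------------------------------
# summaries and binning
# ---------------------------------------------------------------------------


class TestSummarizeDistribution:
    def test_delta_distribution_mean_diameter(self):
        grid = default_grid()
        counts = np.zeros(grid.n_bins)
        counts[50] = 10.0
        nd = NumberDensity.from_counts(grid, counts)
        s = summarize_distribution(nd)
        x0 = grid.pivots[50]
        assert s.mean_diameter == pytest.approx((6 * x0 / np.pi) ** (1 / 3))
        assert s.std_diameter == pytest.approx(0.0)
        assert s.total_count == pytest.approx(10.0)

    def test_doubling_density_scales_count_not_mean(self):
        grid = default_grid()
        rng = np.random.default_rng(3)
        nd = diameters_to_density(rng.lognormal(np.log(250), 0.2, 2000), grid)
        nd2 = NumberDensity(grid, 2 * nd.values)
        s1, s2 = summarize_distribution(nd), summarize_distribution(nd2)
        assert s2.total_count == pytest.approx(2 * s1.total_count)
        assert s2.mean_diameter == pytest.approx(s1.mean_diameter)

    def test_lognormal_sample_matches_analytic_moments(self):
        mu, sig, n = np.log(300.0), 0.25, 200_000
        rng = np.random.default_rng(4)
        d = rng.lognormal(mu, sig, n)
        nd = diameters_to_density(d, default_grid(n_bins=160))
        s = summarize_distribution(nd)
        mean_true = np.exp(mu + sig**2 / 2)
        std_true = mean_true * np.sqrt(np.exp(sig**2) - 1)
        assert s.mean_diameter == pytest.approx(mean_true, rel=0.01)
        assert s.std_diameter == pytest.approx(std_true, rel=0.03)
        assert s.median_diameter == pytest.approx(np.exp(mu), rel=0.02)

    def test_all_zero_density_undefined(self):
        nd = NumberDensity(default_grid(), np.zeros(90))
        with pytest.raises(ValueError):
            summarize_distribution(nd)


class TestDiametersToDensity:
    def test_single_diameter_lands_at_its_volume(self):
        grid = default_grid()
        d0 = 300.0
        nd = diameters_to_density([d0], grid)
        v0 = diameter_to_volume(d0)
        occupied = np.nonzero(nd.counts)[0]
        assert len(occupied) in (1, 2)
        lo = grid.pivots[occupied[0]]
        hi = grid.pivots[occupied[-1]]
        assert lo <= v0 <= hi
        # two-point split preserves the sample's volume exactly
        assert nd.total_mass() == pytest.approx(v0, rel=1e-12)

    def test_round_trip_mean_within_2_percent(self):
        rng = np.random.default_rng(5)
        d = rng.lognormal(np.log(280.0), 0.3, 10_000)
        nd = diameters_to_density(d, default_grid())
        s = summarize_distribution(nd)
        assert s.mean_diameter == pytest.approx(d.mean(), rel=0.02)

    def test_nonpositive_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="rejected 2"):
            nd = diameters_to_density([250.0, -1.0, 0.0], default_grid())
        # remaining valid samples still carry the full per-mL normalization
        assert nd.total_count() == pytest.approx(1.0)

    def test_empty_after_filtering_errors(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                diameters_to_density([-5.0], default_grid())

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            diameters_to_density([], default_grid())


class TestSizeGridInvariants:
    def test_rejects_too_few_bins(self):
        with pytest.raises(ValueError):
            SizeGrid.geometric(1.0, 1e5, 10)

    def test_rejects_narrow_span(self):
        with pytest.raises(ValueError):
            SizeGrid.geometric(1.0, 100.0, 30)

    def test_volume_diameter_round_trip(self):
        d = np.array([10.0, 265.4, 481.4])
        np.testing.assert_allclose(volume_to_diameter(diameter_to_volume(d)), d)
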