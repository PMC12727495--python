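"""Conversion-factor estimation from inversion ensembles."""

import numpy as np
import pytest

from carbonledger import FluxSeries
from carbonledger.convfactor import (
    InversionMember,
    annual_growth_ppm,
    bim_band,
    ensemble_factor_stats,
    gatm_uncertainty,
    member_conversion_factor,
)


def monthly_axis(first, last):
    return np.arange(first - 0.5, last + 1.5 + 1e-9, 1 / 12)


def record_from_growth(years, growth, seasonal_amp=3.0, start=350.0):
    """Piecewise-linear mole-fraction record with known annual boundary
    growth plus a two-harmonic seasonal cycle."""
    t = monthly_axis(years[0], years[-1])
    boundaries = np.concatenate([[start], start + np.cumsum(growth)])
    bt = np.arange(years[0], years[-1] + 2, dtype=float)
    base = np.interp(t, bt, boundaries)
    seasonal = seasonal_amp * (
        np.cos(2 * np.pi * t) + 0.3 * np.sin(4 * np.pi * t)
    )
    return t, base + seasonal


class TestAnnualGrowth:
    def test_exact_linear_no_seasonality(self):
        years = np.arange(2000, 2020)
        t = monthly_axis(2000, 2019)
        rec = 300.0 + 2.0 * (t - 2000.0)
        growth = annual_growth_ppm(t, rec, years)
        np.testing.assert_allclose(growth, 2.0, atol=1e-9)

    def test_sinusoid_removed(self):
        years = np.arange(2000, 2020)
        t = monthly_axis(2000, 2019)
        rec = 300.0 + 2.0 * (t - 2000.0) + 2.5 * np.sin(2 * np.pi * t)
        growth = annual_growth_ppm(t, rec, years)
        np.testing.assert_allclose(growth, 2.0, atol=1e-6)

    def test_stepwise_growth_recovered(self):
        years = np.arange(2000, 2003)
        truth = np.array([1.5, 2.5, 2.0])
        t, rec = record_from_growth(years, truth)
        growth = annual_growth_ppm(t, rec, years)
        np.testing.assert_allclose(growth, truth, atol=0.01)

    def test_offset_invariance(self):
        """Adding a constant to all mole fractions leaves growth unchanged."""
        years = np.arange(2000, 2010)
        truth = np.linspace(1.5, 2.5, years.size)
        t, rec = record_from_growth(years, truth)
        g1 = annual_growth_ppm(t, rec, years)
        g2 = annual_growth_ppm(t, rec + 123.4, years)
        np.testing.assert_allclose(g1, g2, atol=1e-9)

    def test_insufficient_coverage_rejected(self):
        t = monthly_axis(2000, 2005)
        with pytest.raises(ValueError):
            annual_growth_ppm(t, np.ones(t.size), np.arange(2000, 2010))


class TestMemberFactor:
    def test_reference_factor_recovered(self):
        years = np.arange(2001, 2011)
        growth = np.full(10, 2.0)
        m = InversionMember("m", years, net_input=2.124 * growth,
                            growth_ppm=growth)
        np.testing.assert_allclose(member_conversion_factor(m), 2.124,
                                   atol=1e-15)

    def test_near_zero_growth_flagged(self):
        years = np.arange(2001, 2006)
        growth = np.array([2.0, 0.01, 2.0, -0.02, 2.0])
        m = InversionMember("m", years, net_input=np.full(5, 4.0),
                            growth_ppm=growth)
        with pytest.warns(UserWarning, match="near-zero"):
            f = member_conversion_factor(m)
        assert np.isnan(f[[1, 3]]).all()
        assert np.isfinite(f[[0, 2, 4]]).all()


class TestEnsembleStats:
    def years(self):
        return np.arange(2001, 2024)

    def test_identical_members_zero_sigma(self):
        years = self.years()
        growth = np.full(years.size, 2.0)
        members = [
            InversionMember(f"m{i}", years, 2.124 * growth, growth_ppm=growth)
            for i in range(5)
        ]
        stats = ensemble_factor_stats(members, (2001, 2023))
        np.testing.assert_allclose(stats.mean, 2.124, atol=1e-15)
        np.testing.assert_allclose(stats.sigma, 0.0, atol=1e-15)

    def test_two_member_year(self):
        years = np.arange(2001, 2004)
        growth = np.ones(3)
        members = [
            InversionMember("a", years, 2.0 * growth, growth_ppm=growth),
            InversionMember("b", years, 2.2 * growth, growth_ppm=growth),
        ]
        stats = ensemble_factor_stats(members, (2001, 2003))
        assert stats.mean == pytest.approx(2.1)
        assert stats.sigma == pytest.approx(0.1414, abs=5e-5)

    def test_direct_statistics_oracle(self):
        rng = np.random.default_rng(23)
        years = self.years()
        growth = rng.uniform(1.5, 3.0, years.size)
        factors = 2.124 + rng.normal(0, 0.05, (14, years.size))
        members = [
            InversionMember(f"m{i}", years, factors[i] * growth,
                            growth_ppm=growth)
            for i in range(14)
        ]
        stats = ensemble_factor_stats(members, (2001, 2023))
        np.testing.assert_allclose(stats.mean, factors.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(stats.sigma, factors.std(axis=0, ddof=1),
                                   atol=1e-12)
        assert stats.interannual_sigma == pytest.approx(
            np.std(factors.mean(axis=0), ddof=1), abs=1e-12
        )

    def test_sparse_years_dropped(self):
        growth = np.ones(23)
        full = InversionMember("full", self.years(), 2.124 * growth,
                               growth_ppm=growth)
        short_years = np.arange(2010, 2024)
        short = InversionMember("short", short_years,
                                2.124 * np.ones(14), growth_ppm=np.ones(14))
        with pytest.warns(UserWarning, match="dropped"):
            stats = ensemble_factor_stats([full, short], (2001, 2023))
        assert stats.years[0] == 2010


class TestGatmUncertainty:
    def make_cf(self, sigma=0.0, interannual=0.0):
        years = np.arange(2001, 2024)
        from carbonledger.convfactor import ConversionFactorSeries

        return ConversionFactorSeries(
            years=years,
            mean=np.full(years.size, 2.124),
            sigma=np.full(years.size, sigma),
            n_members=np.full(years.size, 14),
            interannual_sigma=interannual,
            window=(2001, 2023),
        )

    def test_all_sources_zero(self, series_factory):
        gatm = series_factory(np.full(23, 5.0), "G_ATM", 2001)
        out = gatm_uncertainty(gatm, 0.0, self.make_cf())
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_growth_source_alone(self, series_factory):
        """sigma_growth = 0.1 ppm with an exact 2.124 factor gives
        0.2124 GtC/yr regardless of the G_ATM level."""
        gatm = series_factory(np.linspace(4, 6, 23), "G_ATM", 2001)
        out = gatm_uncertainty(gatm, 0.1, self.make_cf())
        np.testing.assert_allclose(out.values, 0.2124, atol=1e-12)

    def test_three_relative_sources_quadrature(self, series_factory):
        """1%, 2%, 2% relative sources on G_ATM = 5.2 combine to 0.156."""
        gatm = series_factory(np.full(23, 5.2), "G_ATM", 2001)
        cf = self.make_cf(sigma=0.02 * 2.124, interannual=0.02 * 2.124)
        # source (1): sigma_ppm×2.124/G_ATM = 1% ⇒ sigma_ppm = 0.052/2.124
        out = gatm_uncertainty(gatm, 0.01 * 5.2 / 2.124, cf)
        np.testing.assert_allclose(out.values, 5.2 * 0.03, atol=1e-12)

    def test_consistent_members_reduce_to_growth_source(self):
        """Members whose net input is exactly 2.124 × their growth leave
        only the observational growth source."""
        years = np.arange(2001, 2024)
        growth = np.linspace(1.8, 2.6, years.size)
        members = [
            InversionMember(f"m{i}", years, 2.124 * growth, growth_ppm=growth)
            for i in range(5)
        ]
        stats = ensemble_factor_stats(members, (2001, 2023))
        gatm = FluxSeries("G_ATM", years, 2.124 * growth)
        out = gatm_uncertainty(gatm, 0.1, stats)
        np.testing.assert_allclose(out.values, 0.2124, atol=1e-9)


class TestBimBand:
    def test_flagging(self, series_factory):
        bim = series_factory([0.5, 0.5], "B_IM", 2000)
        sig_wide = series_factory([0.6, 0.6], "sigma", 2000)
        sig_narrow = series_factory([0.3, 0.3], "sigma", 2000)
        assert not bim_band(bim, sig_wide)["significant"].any()
        assert bim_band(bim, sig_narrow)["significant"].all()

    def test_halved_sigma_matches_brute_force(self, series_factory):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 0.5, 30)
        sig = np.abs(rng.normal(0.4, 0.1, 30))
        bim = series_factory(vals, "B_IM", 1990)
        for scale in (1.0, 0.5):
            band = bim_band(bim, series_factory(sig * scale, "s", 1990))
            brute = np.abs(vals) > sig * scale
            np.testing.assert_array_equal(band["significant"].to_numpy(), brute)
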