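"""Lee-Carter fit, gap-tolerant drift estimation, and bounded forecasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from u5mort.lc import (
    ForecastConfig,
    _drift_and_variance,
    fit_lc,
    forecast_k,
    forecast_rates,
    mortality_from_fit,
)
from u5mort.lifetable import N_AGES
from u5mort.synthetic import TrueSurfaceParams, make_true_surface


def _rank1_surface(years, a=None, b=None, k=None):
    rng = np.random.default_rng(0)
    a = a if a is not None else np.log(0.2 * np.exp(-0.2 * np.arange(N_AGES)) + 0.01)
    b = b if b is not None else (lambda v: v / v.sum())(rng.uniform(0.5, 2.0, N_AGES))
    k = k if k is not None else (lambda v: v - v.mean())(np.linspace(20, -20, len(years)))
    logm = a[:, None] + np.outer(b, k)
    return (
        pd.DataFrame(logm, index=pd.Index(range(N_AGES), name="age_month"), columns=pd.Index(years, name="year")),
        a,
        b,
        k,
    )


class TestFitLC:
    def test_rank1_identity(self):
        logm, a, b, k = _rank1_surface(np.arange(1995, 2018))
        fit = fit_lc(logm)
        assert fit.ve == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.a_x, a, atol=1e-10)
        assert np.allclose(fit.b_x, b, atol=1e-10)
        assert np.allclose(fit.k_t.to_numpy(), k, atol=1e-8)
        recon = fit.a_x[:, None] + np.outer(fit.b_x, fit.k_t.to_numpy())
        assert np.max(np.abs(recon - logm.to_numpy())) < 1e-10
        assert fit.e_sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_normalization(self):
        logm, *_ = _rank1_surface(np.arange(2000, 2010))
        fit = fit_lc(logm)
        assert fit.b_x.sum() == pytest.approx(1.0, abs=1e-10)
        assert fit.k_t.sum() == pytest.approx(0.0, abs=1e-10)

    def test_identifiability_under_rescaling(self):
        years = np.arange(2000, 2012)
        logm1, a, b, k = _rank1_surface(years)
        c = 3.7
        logm2, *_ = _rank1_surface(years, a=a, b=b / c, k=c * k)
        f1, f2 = fit_lc(logm1), fit_lc(logm2)
        assert np.allclose(f1.b_x, f2.b_x, atol=1e-10)
        assert np.allclose(f1.k_t.to_numpy(), f2.k_t.to_numpy(), atol=1e-8)

    def test_constant_surface_degenerate_flagged(self):
        years = np.arange(2000, 2006)
        logm = pd.DataFrame(
            np.tile(np.linspace(-2, -5, N_AGES)[:, None], (1, len(years))),
            index=range(N_AGES),
            columns=years,
        )
        fit = fit_lc(logm)
        assert fit.degenerate
        assert fit.ve == 1.0
        assert np.allclose(fit.b_x, 1.0 / N_AGES)
        assert np.allclose(fit.k_t.to_numpy(), 0.0)

    def test_fewer_than_three_years_rejected(self):
        logm, *_ = _rank1_surface(np.arange(2000, 2002))
        with pytest.raises(ValueError, match="3 observed years"):
            fit_lc(logm)

    def test_missing_years_dropped_complete_case(self):
        logm, a, b, k = _rank1_surface(np.arange(2000, 2010))
        logm[2004] = np.nan
        fit = fit_lc(logm)
        assert 2004 not in fit.k_t.index
        assert len(fit.k_t) == 9

    def test_variance_explained_with_noise(self):
        rng = np.random.default_rng(8)
        logm, a, b, k = _rank1_surface(np.arange(1993, 2018))
        noisy = logm + rng.normal(0, 0.05, logm.shape)
        fit = fit_lc(noisy)
        assert 0.9 < fit.ve < 1.0
        assert np.corrcoef(fit.b_x, b)[0, 1] > 0.9

    def test_drift_recovery_across_seeded_surfaces(self):
        """Median absolute drift error over 50 simulated 25-year surfaces
        is below 10% of the true drift."""
        errors = []
        for seed in range(50):
            surf = make_true_surface(TrueSurfaceParams(seed=seed))
            fit = fit_lc(np.log(surf.m))
            drift, _, _ = _drift_and_variance(fit)
            errors.append(abs(drift - surf.params.k_drift))
        assert np.median(errors) < 0.1 * abs(TrueSurfaceParams().k_drift)


class TestForecastK:
    def test_linear_k_forecast_continues_line(self):
        years = np.arange(2000, 2011)
        logm, a, b, k = _rank1_surface(years, k=np.linspace(10, -10, 11))
        fit = fit_lc(logm)
        fc, flags = forecast_k(fit, ForecastConfig(horizons=(2015, 2020), bound_type="narrow"))
        slope = (k[-1] - k[0]) / (years[-1] - years[0])
        assert fc.loc[2015, "k"] == pytest.approx(k[-1] + 5 * slope, abs=1e-8)
        assert fc.loc[2020, "k"] == pytest.approx(k[-1] + 10 * slope, abs=1e-8)
        assert flags  # zero innovation variance flagged

    def test_gapped_series_matches_brute_force_ml(self):
        """Drift and innovation variance on unequally spaced observations
        agree with direct numerical ML for the RW-with-drift model."""
        rng = np.random.default_rng(4)
        t = np.array([2000, 2001, 2003, 2006, 2007, 2011, 2013])
        c_true, s_true = -1.2, 0.4
        k = np.concatenate([[0.0], np.cumsum(c_true * np.diff(t) + s_true * np.sqrt(np.diff(t)) * rng.standard_normal(len(t) - 1))])
        b = np.full(N_AGES, 1.0 / N_AGES)
        a = np.full(N_AGES, -3.0)
        logm = pd.DataFrame(a[:, None] + np.outer(b, k - k.mean()), index=range(N_AGES), columns=t)
        fit = fit_lc(logm)
        drift, sigma2, degen = _drift_and_variance(fit)

        dk, dt = np.diff(fit.k_t.to_numpy()), np.diff(t).astype(float)

        def nll(theta):
            c, log_s2 = theta
            s2 = np.exp(log_s2)
            return 0.5 * np.sum(np.log(2 * np.pi * s2 * dt) + (dk - c * dt) ** 2 / (s2 * dt))

        res = minimize(nll, x0=[-1.0, np.log(0.2)], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        c_ml, s2_ml = res.x[0], np.exp(res.x[1])
        assert drift == pytest.approx(c_ml, abs=1e-5)
        assert sigma2 == pytest.approx(s2_ml, rel=1e-3)
        assert not degen

    def test_forecast_invariant_to_reindexing_years(self):
        t1 = np.array([2000, 2002, 2006, 2010, 2012])
        t2 = t1 + 7  # same spacings, shifted labels
        k = np.array([5.0, 3.1, -0.4, -3.9, -5.2])
        b = np.full(N_AGES, 1.0 / N_AGES)
        a = np.full(N_AGES, -3.0)
        f1 = fit_lc(pd.DataFrame(a[:, None] + np.outer(b, k - k.mean()), index=range(N_AGES), columns=t1))
        f2 = fit_lc(pd.DataFrame(a[:, None] + np.outer(b, k - k.mean()), index=range(N_AGES), columns=t2))
        fc1, _ = forecast_k(f1, ForecastConfig(horizons=(2020,)))
        fc2, _ = forecast_k(f2, ForecastConfig(horizons=(2027,)))
        assert fc1.loc[2020, "k"] == pytest.approx(fc2.loc[2027, "k"], abs=1e-10)
        assert fc1.loc[2020, "hi"] - fc1.loc[2020, "lo"] == pytest.approx(
            fc2.loc[2027, "hi"] - fc2.loc[2027, "lo"], abs=1e-10
        )

    def test_bound_widths_nested_and_growing(self):
        rng = np.random.default_rng(6)
        surf = make_true_surface(TrueSurfaceParams(seed=12))
        fit = fit_lc(np.log(surf.m))
        fc, _ = forecast_k(fit, ForecastConfig(horizons=(2020, 2030, 2050)))
        widths = {}
        for name in ("narrow", "unbiased", "wide"):
            w = (fc[f"hi_{name}"] - fc[f"lo_{name}"]).to_numpy()
            widths[name] = w
            assert np.all(np.diff(w) >= -1e-12)  # non-decreasing in horizon
        assert np.all(widths["narrow"] <= widths["unbiased"] + 1e-12)
        assert np.all(widths["unbiased"] <= widths["wide"] + 1e-12)

    def test_narrow_interval_collapses_at_horizon_zero(self):
        surf = make_true_surface(TrueSurfaceParams(seed=2))
        fit = fit_lc(np.log(surf.m))
        last = int(fit.years[-1])
        fc, _ = forecast_k(fit, ForecastConfig(horizons=(last,), bound_type="narrow"))
        assert fc.loc[last, "k"] == pytest.approx(fit.k_t.iloc[-1])
        assert fc.loc[last, "hi_narrow"] - fc.loc[last, "lo_narrow"] == pytest.approx(0.0, abs=1e-12)

    def test_horizon_before_last_year_rejected(self):
        surf = make_true_surface(TrueSurfaceParams(seed=2))
        fit = fit_lc(np.log(surf.m))
        with pytest.raises(ValueError):
            forecast_k(fit, ForecastConfig(horizons=(2000,)))


class TestMortalityFromFit:
    def test_k_zero_returns_baseline(self):
        logm, a, b, k = _rank1_surface(np.arange(2000, 2010))
        fit = fit_lc(logm)
        m, sr = mortality_from_fit(fit, 0.0)
        assert np.allclose(m, np.exp(fit.a_x))
        assert 0 < sr.nmr <= sr.imr <= sr.u5mr < 1

    def test_lower_k_lowers_all_positive_loading_rates(self):
        logm, *_ = _rank1_surface(np.arange(2000, 2010))
        fit = fit_lc(logm)
        m_hi, _ = mortality_from_fit(fit, 1.0)
        m_lo, _ = mortality_from_fit(fit, -1.0)
        assert np.all(m_lo[fit.b_x > 0] < m_hi[fit.b_x > 0])

    def test_round_trip_reproduces_rank1_surface(self):
        logm, *_ = _rank1_surface(np.arange(2000, 2012))
        fit = fit_lc(logm)
        assert fit.ve == pytest.approx(1.0, abs=1e-12)
        for year in logm.columns:
            m, _ = mortality_from_fit(fit, float(fit.k_t[year]))
            assert np.max(np.abs(np.log(m) - logm[year].to_numpy())) < 1e-10

    def test_forecast_rates_intervals_contain_median(self):
        surf = make_true_surface(TrueSurfaceParams(seed=5))
        fit = fit_lc(np.log(surf.m))
        fc = forecast_rates(fit, ForecastConfig(horizons=(2030, 2050)))
        for ind in ("nmr", "imr", "u5mr"):
            assert (fc.rates[f"{ind}_lo"] <= fc.rates[ind]).all()
            assert (fc.rates[ind] <= fc.rates[f"{ind}_hi"]).all()
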