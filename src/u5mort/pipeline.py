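"""End-to-end orchestration: simulate -> estimate -> calibrate -> smooth
-> fit -> forecast -> assess, plus a coverage diagnostic.

Each stage reads and writes plain CSV artifacts in an output directory so
stages can be re-run individually; all randomness flows from one root
seed through named per-stage substreams (``default_rng([seed, stage])``),
making every run reproducible and every stage independently replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from u5mort import calibration as cal
from u5mort import lifetable as lt
from u5mort import synthetic as syn
from u5mort.lc import Forecast, ForecastConfig, LCFit, fit_lc, forecast_rates, mortality_from_fit
from u5mort.pspline import BasisConfig, select_lambda
from u5mort.sdg import assess_sdg, assessment_table

log = logging.getLogger("u5mort.pipeline")

# per-stage substream labels (second word of the rng seed sequence)
_STAGE_STREAMS = {"surface": 0, "birth_histories": 1}


@dataclass
class PipelineConfig:
    country: str = "SYNTH"
    seed: int = 0
    surface: syn.TrueSurfaceParams = field(default_factory=syn.TrueSurfaceParams)
    survey: syn.SurveyDesign = field(default_factory=syn.SurveyDesign)
    bias: syn.BiasConfig = field(default_factory=syn.BiasConfig)
    estimation_window: tuple[int, int] | None = None  # default: surface years
    use_weights: bool = False
    targets_csv: str | None = None   # None -> calibrate to the true surface; "skip" -> no calibration
    basis_age: BasisConfig = field(default_factory=lambda: BasisConfig(knot_spacing=2.0, lambda_grid=(1e-1, 1e1, 1e3)))
    basis_year: BasisConfig = field(default_factory=lambda: BasisConfig(knot_spacing=2.0, lambda_grid=(1e-1, 1e1, 1e3)))
    forecast: ForecastConfig = field(default_factory=ForecastConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        cfg.country = raw.get("country", cfg.country)
        cfg.seed = int(raw.get("seed", cfg.seed))
        if "surface" in raw:
            s = raw["surface"]
            cfg.surface = syn.TrueSurfaceParams(
                years=tuple(s.get("years", cfg.surface.years)),
                k_drift=float(s.get("k_drift", cfg.surface.k_drift)),
                k_sigma=float(s.get("k_sigma", cfg.surface.k_sigma)),
                e_sigma=float(s.get("e_sigma", cfg.surface.e_sigma)),
                seed=cfg.seed,
            )
        if "survey" in raw:
            cfg.survey = syn.SurveyDesign(**raw["survey"])
        if "bias" in raw:
            cfg.bias = syn.BiasConfig(**raw["bias"])
        if "estimation_window" in raw and raw["estimation_window"]:
            cfg.estimation_window = tuple(raw["estimation_window"])
        cfg.use_weights = bool(raw.get("use_weights", cfg.use_weights))
        cfg.targets_csv = raw.get("targets_csv", cfg.targets_csv)
        if "forecast" in raw:
            f = raw["forecast"]
            cfg.forecast = ForecastConfig(
                horizons=tuple(f.get("horizons", cfg.forecast.horizons)),
                bound_type=f.get("bound_type", cfg.forecast.bound_type),
                coverage=float(f.get("coverage", cfg.forecast.coverage)),
            )
        if "smoothing" in raw:
            s = raw["smoothing"]
            grid = tuple(s.get("lambda_grid", cfg.basis_age.lambda_grid))
            cfg.basis_age = BasisConfig(knot_spacing=float(s.get("knot_spacing_age", 2.0)), lambda_grid=grid)
            cfg.basis_year = BasisConfig(knot_spacing=float(s.get("knot_spacing_year", 2.0)), lambda_grid=grid)
        return cfg

    def window(self) -> tuple[int, int]:
        return self.estimation_window or self.surface.years


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGE_STREAMS[stage]])


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> tuple[syn.TrueSurface, pd.DataFrame]:
    params = cfg.surface
    params.seed = cfg.seed  # surface substream is the root seed itself
    surface = syn.make_true_surface(params)
    records = syn.simulate_birth_histories(
        surface, cfg.survey, cfg.bias, rng=_stage_rng(cfg.seed, "birth_histories")
    )
    syn.write_true_surface(surface, outdir / "true_surface.csv")
    surface.k.to_csv(outdir / "true_k.csv")
    syn.write_birth_records(records, outdir / "records.csv")
    log.info("simulate: %d records from %d women", len(records), cfg.survey.n_women)
    return surface, records


def stage_estimate(cfg: PipelineConfig, records: pd.DataFrame, outdir: Path) -> tuple[lt.EventMatrices, pd.DataFrame]:
    ev = lt.tabulate_events(records, cfg.window(), use_weights=cfg.use_weights)
    if ev.n_rejected:
        log.warning("estimate: rejected %d records with impossible death dates", ev.n_rejected)
    m = lt.death_rates(ev)
    lt.write_grid_csv(ev.D, outdir / "D.csv", "deaths")
    lt.write_grid_csv(ev.E, outdir / "E.csv", "exposure_months")
    lt.write_grid_csv(m, outdir / "m_raw.csv", "m")
    log.info("estimate: %d deaths, %.0f person-months", ev.D.to_numpy().sum(), ev.E.to_numpy().sum())
    return ev, m


def _truth_targets(surface: syn.TrueSurface, years) -> pd.DataFrame:
    rows = []
    for y in years:
        sr = surface.summary(int(y))
        rows.append({"country": "TRUTH", "year": int(y), **{k: 1000 * v for k, v in
                     [("nmr", sr.nmr), ("imr", sr.imr), ("u5mr", sr.u5mr)]}})
    return pd.DataFrame(rows)


def stage_calibrate(
    cfg: PipelineConfig,
    m_raw: pd.DataFrame,
    outdir: Path,
    surface: syn.TrueSurface | None = None,
) -> pd.DataFrame:
    """Calibrate each year's monthly schedule to its target summary rates.

    Returns the calibrated m grid.  Years with incomplete raw schedules
    or no target are left uncalibrated and flagged in the log.
    """
    if cfg.targets_csv == "skip":
        log.warning("calibrate: skipped by configuration; downstream stages use raw rates")
        lt.write_grid_csv(m_raw, outdir / "m_calibrated.csv", "m")
        return m_raw
    if cfg.targets_csv:
        targets = cal.read_targets_csv(cfg.targets_csv)
        country = cfg.country
    elif surface is not None:
        targets = _truth_targets(surface, m_raw.columns)
        targets[["nmr", "imr", "u5mr"]] /= 1000.0
        country = "TRUTH"
    else:
        log.warning("calibrate: no targets available; downstream stages use raw rates")
        lt.write_grid_csv(m_raw, outdir / "m_calibrated.csv", "m")
        return m_raw

    m_cal = m_raw.copy()
    fac_rows = []
    for year in m_raw.columns:
        col = m_raw[year].to_numpy()
        tgt = cal.targets_for_year(targets, country, int(year))
        if tgt is None:
            log.warning("calibrate: no target for %s %s; year left uncalibrated", country, year)
            continue
        if np.any(~np.isfinite(col)):
            log.warning("calibrate: year %s has empty cells; year left uncalibrated", year)
            continue
        res = cal.calibrate_to_targets(lt.lifetable_from_m(col), tgt)
        if res.capped_bands:
            log.warning("calibrate: year %s capped survival in bands %s", year, res.capped_bands)
        m_cal[year] = lt.q_to_m(res.lifetable.q)
        fac_rows.append({"country": cfg.country, "year": int(year),
                         **{f"f_{b}": res.f[b] for b in res.f},
                         **{f"d_{b}": res.d[b] for b in res.d}})
    pd.DataFrame(fac_rows).to_csv(outdir / "calibration_factors.csv", index=False)
    lt.write_grid_csv(m_cal, outdir / "m_calibrated.csv", "m")
    log.info("calibrate: %d/%d years calibrated", len(fac_rows), m_raw.shape[1])
    return m_cal


def stage_smooth(cfg: PipelineConfig, ev: lt.EventMatrices, m_cal: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    """Smooth the calibrated surface with the 2-D penalized Poisson model.

    Calibration rescales rates, not counts, so the smoother consumes
    calibrated expected counts D' = (E/12) * m_cal on the original
    exposure; empty cells keep zero weight.
    """
    E = ev.E.to_numpy()
    m = m_cal.to_numpy()
    D_eff = np.where((E > 0) & np.isfinite(m), E / 12.0 * np.where(np.isfinite(m), m, 0.0), 0.0)
    fit = select_lambda(D_eff, E, config=cfg.basis_age, config_year=cfg.basis_year)
    if not fit.converged:
        log.warning("smooth: IRWLS did not fully converge (%d iterations)", fit.n_iter)
    log.info("smooth: lambda=%s, ED=%.1f, BIC=%.1f", fit.lambdas, fit.ed, fit.bic)
    m_smooth = pd.DataFrame(np.exp(fit.log_mu), index=m_cal.index, columns=m_cal.columns)
    lt.write_grid_csv(m_smooth, outdir / "m_smoothed.csv", "m")
    return m_smooth


def stage_fit(cfg: PipelineConfig, m_smooth: pd.DataFrame, outdir: Path) -> LCFit:
    fit = fit_lc(np.log(m_smooth))
    if fit.degenerate:
        log.warning("fit: degenerate constant surface")
    log.info("fit: variance explained %.3f, residual sd %.4f", fit.ve, np.sqrt(fit.e_sigma2))
    pd.DataFrame({"age_month": np.arange(lt.N_AGES), "a_x": fit.a_x, "b_x": fit.b_x}).to_csv(
        outdir / "lc_ages.csv", index=False
    )
    ktab = fit.k_t.rename("k").reset_index()
    ktab["ve"] = fit.ve
    ktab["e_sigma2"] = fit.e_sigma2
    ktab.to_csv(outdir / "lc_k.csv", index=False)
    return fit


def stage_forecast(cfg: PipelineConfig, fit: LCFit, outdir: Path) -> Forecast:
    fc = forecast_rates(fit, cfg.forecast)
    for flag in fc.flags:
        log.warning("forecast: %s", flag)
    fc.k.to_csv(outdir / "forecast_k.csv")
    fc.rates.to_csv(outdir / "forecast_rates.csv")
    prof = pd.concat({y: df for y, df in fc.m.items()}, names=["year"]).reset_index()
    prof.to_csv(outdir / "forecast_age_profiles.csv", index=False)
    return fc


def stage_assess(cfg: PipelineConfig, fc: Forecast, outdir: Path) -> pd.DataFrame:
    r = fc.rates

    def _get(year, colname):
        if year in r.index:
            return float(r.loc[year, colname])
        return None

    a = assess_sdg(
        cfg.country,
        nmr_2030=_get(2030, "nmr"),
        u5mr_2030=_get(2030, "u5mr"),
        nmr_2050=_get(2050, "nmr"),
        u5mr_2050=_get(2050, "u5mr"),
    )
    table = assessment_table([a])
    table.to_csv(outdir / "assessment.csv", index=False)
    log.info("assess: %s -> %s", cfg.country, a.category.value)
    return table


def fitted_rates_by_year(fit: LCFit) -> pd.DataFrame:
    """Fitted NMR/IMR/U5MR (per 1,000) at each observed year's k_t."""
    rows = []
    for year, k in fit.k_t.items():
        _, sr = mortality_from_fit(fit, k)
        rows.append({"year": int(year), **sr.per_1000()})
    return pd.DataFrame(rows)


def coverage_check(estimates: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Share of point estimates inside external interval bounds.

    ``estimates``: columns year + nmr/imr/u5mr (per 1,000);
    ``intervals``: columns year + {nmr,imr,u5mr}_lo/_hi, same scale.
    Bounds are inclusive.  Years present in both tables are compared; an
    all-NaN result signals no overlap.
    """
    merged = estimates.merge(intervals, on="year", how="inner")
    out = {}
    for ind in ("nmr", "imr", "u5mr"):
        lo, hi = f"{ind}_lo", f"{ind}_hi"
        if lo not in merged.columns or hi not in merged.columns or merged.empty:
            out[ind] = np.nan
            continue
        ok = (merged[ind] >= merged[lo]) & (merged[ind] <= merged[hi])
        out[ind] = float(ok.mean())
    if merged.empty:
        log.warning("coverage: no matched country-years")
    return pd.Series(out, name="coverage")


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages in order, writing artifacts and a run log to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("u5mort")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        surface, records = stage_simulate(cfg, outdir)
        ev, m_raw = stage_estimate(cfg, records, outdir)
        m_cal = stage_calibrate(cfg, m_raw, outdir, surface=surface)
        m_smooth = stage_smooth(cfg, ev, m_cal, outdir)
        fit = stage_fit(cfg, m_smooth, outdir)
        fc = stage_forecast(cfg, fit, outdir)
        assessment = stage_assess(cfg, fc, outdir)

        fitted = fitted_rates_by_year(fit)
        fitted.to_csv(outdir / "fitted_rates.csv", index=False)
        cov = None
        if cfg.targets_csv and cfg.targets_csv != "skip":
            tgt = pd.read_csv(cfg.targets_csv)
            if {"nmr_lo", "nmr_hi"} <= set(tgt.columns):
                cov = coverage_check(fitted, tgt[tgt["country"] == cfg.country])
                cov.to_csv(outdir / "coverage.csv")
                log.info("coverage: %s", cov.to_dict())
    except Exception as exc:  # partial outputs stay on disk for debugging
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return {
        "surface": surface,
        "records": records,
        "events": ev,
        "m_raw": m_raw,
        "m_calibrated": m_cal,
        "m_smoothed": m_smooth,
        "lc_fit": fit,
        "forecast": fc,
        "assessment": assessment,
        "coverage": cov,
    }
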