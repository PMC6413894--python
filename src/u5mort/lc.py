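"""Lee-Carter decomposition and random-walk-with-drift forecasting.

The model is the log-bilinear decomposition

    log m[x,t] = a[x] + b[x] k_t + e[x,t],

estimated by SVD of the row-centered log-rate surface, with the usual
normalization sum_x b[x] = 1 and sum_t k_t = 0.  The variant implemented
here targets sparse series: observed years may be irregularly spaced
(gapped), at least three are required, the drift of k_t is the endpoint
slope (the maximum-likelihood estimator of a random walk with drift
observed at unequal intervals), and forecast uncertainty comes in three
nested widths:

    narrow   - process (innovation) variance only,
    unbiased - process + drift-estimation variance,
    wide     - process + drift + model fitting error.

Intervals are Gaussian on the k scale and mapped monotonically to rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from u5mort.lifetable import N_AGES, SummaryRates, m_to_q, summary_rates

BOUND_TYPES = ("narrow", "unbiased", "wide")


@dataclass
class LCFit:
    a_x: np.ndarray            # age means of log m
    b_x: np.ndarray            # age loadings, sum 1
    k_t: pd.Series             # period index at observed years, sum 0
    e_sigma2: float            # residual variance of e[x,t]
    ve: float                  # variance explained by the first singular component
    degenerate: bool = False   # constant surface: b uniform, k = 0 by convention

    @property
    def years(self) -> np.ndarray:
        return self.k_t.index.to_numpy()


@dataclass
class ForecastConfig:
    horizons: tuple[int, ...] = (2030, 2050)
    bound_type: str = "unbiased"
    coverage: float = 0.95
    all_bounds: bool = True     # also report the other two widths

    def validate(self, last_year: int) -> None:
        if self.bound_type not in BOUND_TYPES:
            raise ValueError(f"bound_type must be one of {BOUND_TYPES}")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        if any(h < last_year for h in self.horizons):
            # h == last_year is allowed: it reproduces the last fitted value
            raise ValueError(f"forecast horizons must not precede the last observed year {last_year}")


@dataclass
class Forecast:
    """Forecast k paths and derived rates at the requested horizon years."""

    k: pd.DataFrame            # index: year; columns: k, lo, hi (chosen bound) + per-bound widths
    rates: pd.DataFrame        # index: year; columns nmr/imr/u5mr medians + _lo/_hi, per 1,000
    m: dict[int, pd.DataFrame] # per year: age profile with median/lo/hi columns
    bound_type: str
    flags: list[str] = field(default_factory=list)


def fit_lc(logm: pd.DataFrame) -> LCFit:
    """Fit the decomposition by SVD of the row-centered surface.

    ``logm`` is a (60 ages x years) table of log annual death rates;
    columns (years) containing any missing value are dropped
    (complete-case in time).  At least three observed years are required.
    """
    if logm.shape[0] != N_AGES:
        raise ValueError(f"log-rate surface must have {N_AGES} age rows, got {logm.shape[0]}")
    observed = logm.dropna(axis=1)
    if observed.shape[1] < 3:
        raise ValueError(
            f"need at least 3 observed years to fit the model, got {observed.shape[1]}"
        )
    years = observed.columns.to_numpy(dtype=int)
    A = observed.to_numpy(dtype=float)
    a = A.mean(axis=1)
    C = A - a[:, None]

    if np.linalg.norm(C) < 1e-12 * max(1.0, np.linalg.norm(A)):
        # constant surface: no time signal to decompose
        return LCFit(
            a_x=a,
            b_x=np.full(N_AGES, 1.0 / N_AGES),
            k_t=pd.Series(np.zeros(len(years)), index=pd.Index(years, name="year")),
            e_sigma2=0.0,
            ve=1.0,
            degenerate=True,
        )

    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    b_raw = U[:, 0]
    k_raw = s[0] * Vt[0]
    scale = b_raw.sum()
    if abs(scale) < 1e-12:
        raise ValueError("age loadings sum to zero; the surface has no common direction to normalize")
    b = b_raw / scale
    k = k_raw * scale
    # re-anchor exactly: sum k = 0 (absorb any numerical mean into a)
    kbar = k.mean()
    a = a + b * kbar
    k = k - kbar

    resid = C - np.outer(b, k)
    ve = float(s[0] ** 2 / np.sum(s**2))
    return LCFit(
        a_x=a,
        b_x=b,
        k_t=pd.Series(k, index=pd.Index(years, name="year")),
        e_sigma2=float(np.mean(resid**2)),
        ve=ve,
    )


def _drift_and_variance(fit: LCFit) -> tuple[float, float, bool]:
    """Endpoint drift and innovation variance of k_t on unequal spacing.

    For a random walk with drift c and innovation variance s2 observed at
    times t_1 < ... < t_n, the ML drift is (k_n - k_1)/(t_n - t_1) and the
    ML innovation variance is mean over increments of
    (dk_i - c dt_i)^2 / dt_i.
    """
    t = fit.years.astype(float)
    k = fit.k_t.to_numpy()
    span = t[-1] - t[0]
    drift = (k[-1] - k[0]) / span
    dk = np.diff(k)
    dt = np.diff(t)
    resid2 = (dk - drift * dt) ** 2 / dt
    sigma2 = float(resid2.mean())
    degenerate = sigma2 < 1e-14
    return float(drift), sigma2, degenerate


def forecast_k(fit: LCFit, config: ForecastConfig) -> tuple[pd.DataFrame, list[str]]:
    """Forecast k_t by random walk with drift, with nested error bounds.

    Point forecast at horizon h years past the last observed year is
    k_last + c*h.  Variance components:

    - process:  sigma_k^2 * h
    - drift:    sigma_k^2 * h^2 / (t_last - t_first)
    - fitting:  e_sigma2 / sum_x b_x^2  (error of reading k off one
      year's age profile; included in the wide bound only)

    narrow = process; unbiased = process + drift; wide = all three.
    """
    last = int(fit.years[-1])
    config.validate(last)
    drift, sigma2, degen = _drift_and_variance(fit)
    flags = []
    if degen:
        flags.append("degenerate k series: zero innovation variance, bounds collapse")
    if fit.degenerate:
        flags.append("degenerate (constant) surface fit")
    span = float(fit.years[-1] - fit.years[0])
    fit_var = fit.e_sigma2 / float(np.sum(fit.b_x**2)) if np.sum(fit.b_x**2) > 0 else 0.0
    z = stats.norm.ppf(0.5 + config.coverage / 2.0)

    rows = []
    for year in config.horizons:
        h = float(year - last)
        point = fit.k_t.iloc[-1] + drift * h
        var = {
            "narrow": sigma2 * h,
            "unbiased": sigma2 * h + sigma2 * h**2 / span,
            "wide": sigma2 * h + sigma2 * h**2 / span + fit_var,
        }
        row = {"year": year, "k": point}
        for name, v in var.items():
            half = z * np.sqrt(v)
            row[f"lo_{name}"] = point - half
            row[f"hi_{name}"] = point + half
        row["lo"] = row[f"lo_{config.bound_type}"]
        row["hi"] = row[f"hi_{config.bound_type}"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("year"), flags


def mortality_from_fit(fit: LCFit, k: float) -> tuple[np.ndarray, SummaryRates]:
    """Age profile m[x] = exp(a_x + b_x k) and its summary rates."""
    m = np.exp(fit.a_x + fit.b_x * float(k))
    q = np.asarray(m_to_q(m))
    return m, summary_rates(q)


def forecast_rates(fit: LCFit, config: ForecastConfig | None = None) -> Forecast:
    """Full forecast: k intervals mapped to age profiles and summary rates.

    The map k -> rates is monotone age-by-age when b_x >= 0, so rate
    intervals are the (sorted) images of the k interval endpoints;
    summary-rate output is on the per-1,000 scale.
    """
    config = config or ForecastConfig()
    k_df, flags = forecast_k(fit, config)

    rate_rows = []
    m_profiles: dict[int, pd.DataFrame] = {}
    for year, row in k_df.iterrows():
        m_med, sr_med = mortality_from_fit(fit, row["k"])
        m_lo, sr_lo = mortality_from_fit(fit, row["lo"])
        m_hi, sr_hi = mortality_from_fit(fit, row["hi"])
        m_profiles[int(year)] = pd.DataFrame(
            {
                "age_month": np.arange(N_AGES),
                "m": m_med,
                "m_lo": np.minimum(m_lo, m_hi),
                "m_hi": np.maximum(m_lo, m_hi),
            }
        ).set_index("age_month")
        rrow = {"year": int(year)}
        for name in ("nmr", "imr", "u5mr"):
            vals = sorted([1000 * getattr(sr_lo, name), 1000 * getattr(sr_hi, name)])
            rrow[name] = 1000 * getattr(sr_med, name)
            rrow[f"{name}_lo"], rrow[f"{name}_hi"] = vals
        rate_rows.append(rrow)

    return Forecast(
        k=k_df,
        rates=pd.DataFrame(rate_rows).set_index("year"),
        m=m_profiles,
        bound_type=config.bound_type,
        flags=flags,
    )
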