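"""Proportional calibration of monthly survival to external summary rates.

Direct birth-history estimates of NMR/IMR/U5MR are noisy and biased;
external country-year estimates (UN IGME style) are taken as the truth
for three aggregate survival bands,

    neonatal      [1]p[0]  = p[0]            (ages [0, 1) months)
    postneonatal  [11]p[1] = prod p[1..11]   (ages [1, 12))
    child         [48]p[12]= prod p[12..59]  (ages [12, 60))

Each band's survival is rescaled by a single factor f_M so the band
matches its target exactly; the factor is spread uniformly on the
log-survival scale across the band's months, preserving the within-band
age shape.  The measurement error is reported as d_M = 1 - f_M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from u5mort.lifetable import LifeTable, SummaryRates, summary_rates

#: band name -> slice of age months
BANDS: dict[str, slice] = {
    "nmr": slice(0, 1),
    "pmr": slice(1, 12),
    "cmr": slice(12, 60),
}

_P_CAP = 1.0 - 1e-9


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationResult:
    f: dict[str, float]            # band adjustment factors
    d: dict[str, float]            # measurement errors d_M = 1 - f_M
    lifetable: LifeTable           # calibrated monthly schedule
    capped_bands: list[str] = field(default_factory=list)

    @property
    def rates(self) -> SummaryRates:
        return summary_rates(self.lifetable)


def band_survival(lt: LifeTable, band: str) -> float:
    """Probability of surviving a named age band, prod of monthly p."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    return float(np.prod(lt.p[BANDS[band]]))


def target_band_survivals(targets: SummaryRates) -> dict[str, float]:
    """Band survival probabilities implied by target NMR/IMR/U5MR."""
    s = {
        "nmr": 1.0 - targets.nmr,
        "pmr": (1.0 - targets.imr) / (1.0 - targets.nmr),
        "cmr": (1.0 - targets.u5mr) / (1.0 - targets.imr),
    }
    for band, v in s.items():
        if not 0.0 < v <= 1.0:
            raise CalibrationError(f"target band survival for {band!r} outside (0, 1]: {v}")
    return s


def calibrate_to_targets(lt: LifeTable, targets: SummaryRates) -> CalibrationResult:
    """Rescale band survivals so summary rates match ``targets`` exactly.

    For each band M with observed survival S_M and target survival S*_M,
    the factor is f_M = S*_M / S_M, applied as p -> p * f_M^(1/w) to each
    of the band's w months (a constant shift of log p).  If an adjusted p
    would reach 1 it is capped just below 1 and the remaining factor is
    redistributed over the band's other months (the band is flagged).

    Raises CalibrationError when a band has zero observed survival.
    """
    star = target_band_survivals(targets)
    p_new = lt.p.astype(float).copy()
    f: dict[str, float] = {}
    capped: list[str] = []

    for band, sl in BANDS.items():
        p_band = p_new[sl]
        S_obs = float(np.prod(p_band))
        if S_obs == 0.0:
            raise CalibrationError(f"cannot calibrate band {band!r}: observed band survival is 0")
        f_band = star[band] / S_obs
        f[band] = f_band
        p_new[sl] = _spread_factor(p_band, star[band], band, capped)

    result = CalibrationResult(
        f=f,
        d={band: 1.0 - fb for band, fb in f.items()},
        lifetable=LifeTable(q=1.0 - p_new),
        capped_bands=capped,
    )
    return result


def _spread_factor(p_band: np.ndarray, target_product: float, band: str, capped: list[str]) -> np.ndarray:
    """Rescale p_band so its product equals target_product, spreading the
    factor uniformly in log p and capping entries just below 1."""
    logp = np.log(p_band)
    log_target = np.log(target_product)
    cap = np.log(_P_CAP)
    fixed = np.zeros(len(logp), dtype=bool)
    logp_new = logp.copy()
    for _ in range(len(logp)):
        free = ~fixed
        if not free.any():  # every month at the cap; target unreachable
            if band not in capped:
                capped.append(band)
            break
        shift = (log_target - cap * fixed.sum() - logp[free].sum()) / free.sum()
        logp_new[free] = logp[free] + shift
        over = free & (logp_new > 0.0)  # adjusted p would exceed 1
        if not over.any():
            break
        logp_new[over] = cap
        fixed |= over
        if band not in capped:
            capped.append(band)
    return np.exp(logp_new)


# ---------------------------------------------------------------------------
# target table I/O

def read_targets_csv(path) -> pd.DataFrame:
    """Read per country-year calibration targets.

    Expects columns country, year, nmr, imr, u5mr on the per-1,000 scale
    (optionally *_lo / *_hi 90% bounds); returns proportions.
    """
    df = pd.read_csv(path)
    required = {"country", "year", "nmr", "imr", "u5mr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"targets CSV missing columns: {sorted(missing)}")
    out = df.copy()
    for col in out.columns:
        if col in ("country", "year"):
            continue
        out[col] = out[col] / 1000.0
    return out


def targets_for_year(df: pd.DataFrame, country: str, year: int) -> SummaryRates | None:
    row = df[(df["country"] == country) & (df["year"] == year)]
    if row.empty:
        return None
    r = row.iloc[0]
    return SummaryRates(nmr=float(r["nmr"]), imr=float(r["imr"]), u5mr=float(r["u5mr"]))
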