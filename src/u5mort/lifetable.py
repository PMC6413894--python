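"""Direct estimation of monthly under-5 death rates from birth histories.

Children contribute person-months of exposure to a 60-month-age x
calendar-year grid; deaths are counted in the cell of the age-month in
which they occur.  Annualized central death rates m[x,t] are converted to
monthly probabilities of dying q[x] under the assumption that deaths are
distributed uniformly within each month of age,

    q[x] = (m[x]/12) / (1 + m[x]/24),

and aggregated into the three conventional summary indicators:

    NMR  = q[0]
    IMR  = 1 - prod_{x=0..11} (1 - q[x])
    U5MR = 1 - prod_{x=0..59} (1 - q[x])

All probabilities are proportions internally; the per-1,000 scale is used
only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from u5mort._cmc import cmc, cmc_year

N_AGES = 60

REQUIRED_COLUMNS = (
    "woman_id",
    "child_id",
    "dob_cmc",
    "died",
    "death_age_months",
    "interview_cmc",
    "weight",
)


@dataclass
class EventMatrices:
    """Death counts D and person-month exposure E on the age x year grid.

    Both are (60, n_years) DataFrames indexed by age_month 0..59 with
    calendar-year columns.  ``n_rejected`` counts records dropped because
    their reported death would postdate the interview.
    """

    D: pd.DataFrame
    E: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if not self.D.index.equals(self.E.index) or not self.D.columns.equals(self.E.columns):
            raise ValueError("D and E must share the same age x year grid")


@dataclass
class LifeTable:
    """Monthly probabilities of dying q[x] for x = 0..59."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (N_AGES,):
            raise ValueError(f"life table needs exactly {N_AGES} monthly q values, got {self.q.shape}")
        if np.any(self.q < 0) or np.any(self.q >= 1) or not np.all(np.isfinite(self.q)):
            raise ValueError("q values must be finite and in [0, 1)")

    @property
    def p(self) -> np.ndarray:
        return 1.0 - self.q

    @property
    def l(self) -> np.ndarray:
        """Survivorship l[x] = P(alive at exact age-month x), l[0] = 1."""
        return np.concatenate([[1.0], np.cumprod(self.p)])[:N_AGES]


@dataclass(frozen=True)
class SummaryRates:
    """NMR, IMR, U5MR as proportions (probabilities of dying)."""

    nmr: float
    imr: float
    u5mr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.nmr <= self.imr <= self.u5mr < 1.0:
            raise ValueError(f"summary rates must nest: 0 <= nmr <= imr <= u5mr < 1, got {self}")

    def per_1000(self) -> dict[str, float]:
        return {"nmr": 1000 * self.nmr, "imr": 1000 * self.imr, "u5mr": 1000 * self.u5mr}


def tabulate_events(
    records: pd.DataFrame,
    window: tuple[int, int],
    use_weights: bool = False,
) -> EventMatrices:
    """Tabulate deaths and exposure by age-month and calendar year.

    Each child contributes one person-month to cell (x, t) for every
    completed month x it lived with the age-month falling in calendar
    year t inside ``window``; the month of death contributes half a
    person-month plus one death; the interview month contributes nothing.
    A month straddling two years belongs to the year containing its first
    day.  Ages >= 60 months are ignored.

    Records whose reported death age places the death at or after the
    interview month are rejected and counted in ``n_rejected``.
    """
    year_lo, year_hi = int(window[0]), int(window[1])
    if year_hi < year_lo:
        raise ValueError("window must be (first_year, last_year) with first <= last")
    years = np.arange(year_lo, year_hi + 1)

    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"birth-record table missing columns: {missing}")

    dob = records["dob_cmc"].to_numpy(dtype=np.int64)
    interview = records["interview_cmc"].to_numpy(dtype=np.int64)
    if np.any(dob > interview):
        raise ValueError("dob_cmc after interview_cmc")
    died = records["died"].to_numpy(dtype=bool)
    death_age = pd.to_numeric(records["death_age_months"], errors="coerce").to_numpy(dtype=float)
    weight = records["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(records))

    months_observed = interview - dob  # completed months lived before interview month

    # a death month starting after the interview month is impossible; a death
    # in the interview month itself is merely unobserved (censored)
    bad = died & (death_age > months_observed)
    n_rejected = int(bad.sum())
    keep = ~bad
    dob, interview, died, death_age, weight, months_observed = (
        a[keep] for a in (dob, interview, died, death_age, weight, months_observed)
    )

    n = len(dob)
    D = np.zeros((N_AGES, len(years)))
    E = np.zeros((N_AGES, len(years)))
    if n == 0:
        return EventMatrices(_grid_frame(D, years), _grid_frame(E, years), n_rejected)

    death_x = np.where(died, death_age, np.inf)

    # chunk over children to bound the (chunk, 60) work arrays
    ages = np.arange(N_AGES)
    for lo in range(0, n, 200_000):
        hi = min(lo + 200_000, n)
        dob_c = dob[lo:hi, None]
        obs_c = months_observed[lo:hi, None]
        dx_c = death_x[lo:hi, None]
        w_c = weight[lo:hi, None]

        observed = ages[None, :] < obs_c          # month lies fully before interview
        alive_through = ages[None, :] < dx_c      # survived the whole age-month
        dies_here = ages[None, :] == dx_c

        expo = np.where(observed & alive_through, 1.0, 0.0)
        expo += np.where(observed & dies_here, 0.5, 0.0)
        dths = np.where(observed & dies_here, 1.0, 0.0)

        year = cmc_year(dob_c + ages[None, :])
        in_window = (year >= year_lo) & (year <= year_hi)
        year_idx = np.clip(year - year_lo, 0, len(years) - 1)

        flat = (ages[None, :] * len(years) + year_idx).ravel()
        mask = in_window.ravel()
        np.add.at(E.ravel(), flat[mask], (expo * w_c).ravel()[mask])
        np.add.at(D.ravel(), flat[mask], (dths * w_c).ravel()[mask])

    return EventMatrices(_grid_frame(D, years), _grid_frame(E, years), n_rejected)


def _grid_frame(a: np.ndarray, years: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(a, index=pd.Index(np.arange(N_AGES), name="age_month"), columns=pd.Index(years, name="year"))


def death_rates(ev: EventMatrices) -> pd.DataFrame:
    """Annualized central death rates m[x,t] = D / (E/12).

    Cells with zero exposure are missing (NaN), not zero: downstream
    smoothing carries them with zero weight.
    """
    E = ev.E.to_numpy(dtype=float)
    D = ev.D.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(E > 0, D / (E / 12.0), np.nan)
    return pd.DataFrame(m, index=ev.D.index, columns=ev.D.columns)


def m_to_q(m):
    """Monthly probability of dying from an annualized central rate.

    q = (m/12) / (1 + m/24), the Greville/Chiang conversion with n = 1/12
    year and deaths uniform within the month.  Valid (q < 1) for m < 24
    deaths per person-year; larger rates are clipped just below 1.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m[np.isfinite(m)] < 0):
        raise ValueError("central death rate m must be non-negative")
    q = (m / 12.0) / (1.0 + m / 24.0)
    return np.minimum(q, 1.0 - 1e-12) if q.ndim else float(min(q, 1.0 - 1e-12))


def q_to_m(q):
    """Inverse conversion: m = 12 q / (1 - q/2)."""
    q = np.asarray(q, dtype=float)
    if np.any(q[np.isfinite(q)] < 0) or np.any(q[np.isfinite(q)] >= 1):
        raise ValueError("monthly probability q must lie in [0, 1)")
    m = 12.0 * q / (1.0 - q / 2.0)
    return m if m.ndim else float(m)


def summary_rates(lt: LifeTable | np.ndarray) -> SummaryRates:
    """NMR, IMR and U5MR from 60 monthly probabilities of dying."""
    q = lt.q if isinstance(lt, LifeTable) else np.asarray(lt, dtype=float)
    if q.shape != (N_AGES,):
        raise ValueError(f"need {N_AGES} monthly q values, got shape {q.shape}")
    p = 1.0 - q
    return SummaryRates(
        nmr=float(q[0]),
        imr=float(1.0 - np.prod(p[:12])),
        u5mr=float(1.0 - np.prod(p[:N_AGES])),
    )


def lifetable_from_m(m: np.ndarray) -> LifeTable:
    """Life table from a 60-vector of annualized rates (NaN -> rejected)."""
    m = np.asarray(m, dtype=float)
    if np.any(~np.isfinite(m)):
        raise ValueError("cannot build a life table from missing rates")
    return LifeTable(q=np.atleast_1d(m_to_q(m)))


# ---------------------------------------------------------------------------
# CSV I/O (long format: age_month, year, value)

def write_grid_csv(grid: pd.DataFrame, path, value_name: str = "value") -> None:
    long = grid.stack().rename(value_name).reset_index()
    long.to_csv(path, index=False)


def read_grid_csv(path, value_name: str = "value") -> pd.DataFrame:
    long = pd.read_csv(path)
    return long.pivot(index="age_month", columns="year", values=value_name)


def read_birth_records(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in rec.columns]
    if missing:
        raise ValueError(f"birth-record CSV missing columns: {missing}")
    rec["died"] = rec["died"].astype(bool)
    return rec
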