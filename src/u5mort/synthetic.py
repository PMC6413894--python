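"""Synthetic full-birth-history surveys with a known mortality surface.

The ground truth is a log-bilinear age-period surface,

    log m[x,t] = a[x] + b[x] * k_t + e[x,t],

with ``k_t`` a random walk with drift anchored to sum to zero — the
generative twin of the Lee-Carter decomposition the pipeline later fits.
Children then draw monthly death indicators from the surface's monthly
probabilities q[x,t], are right-censored at the interview month, and can
be distorted by two classic birth-history artefacts: survivor bias
(mothers whose children died are more likely to be missing from the
sample) and age heaping at 12 months.

Default parameter values sketch a high-mortality setting declining at
roughly 3% per year across ages: U5MR near 120 per 1,000 at the
anchored mid-period, a steeply decreasing age profile concentrated in the
first year of life, and faster proportional decline at child than at
neonatal ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from u5mort._cmc import cmc, cmc_year
from u5mort.lifetable import N_AGES, m_to_q, summary_rates


def default_baseline_log_rates() -> np.ndarray:
    """Baseline log annual death rates a[x]: steep decline over 0-59 months.

    m[x] = 0.25 exp(-0.25 x) + 0.006 deaths per person-year gives
    NMR ~ 21, IMR ~ 90, U5MR ~ 115 per 1,000 at k = 0.
    """
    x = np.arange(N_AGES)
    return np.log(0.25 * np.exp(-0.25 * x) + 0.006)


def default_age_loadings() -> np.ndarray:
    """Age loadings b[x] >= 0 summing to 1, mildly tilted toward older ages
    (post-neonatal and child mortality decline faster than neonatal)."""
    x = np.arange(N_AGES)
    b = 1.0 + x / (N_AGES - 1.0)
    return b / b.sum()


@dataclass
class TrueSurfaceParams:
    """Parameters of the generative log-bilinear mortality surface."""

    years: tuple[int, int] = (1993, 2017)
    a_x: np.ndarray = field(default_factory=default_baseline_log_rates)
    b_x: np.ndarray = field(default_factory=default_age_loadings)
    k_drift: float = -1.8   # per-year drift of k_t; with mean b ~ 1/60 this is ~3%/yr rate decline
    k_sigma: float = 0.3    # innovation SD of the k_t random walk
    e_sigma: float = 0.05   # SD of age-period log-rate noise
    seed: int = 0

    def validate(self) -> None:
        for name in ("k_drift", "k_sigma", "e_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter: {name}")
        if self.k_sigma < 0 or self.e_sigma < 0:
            raise ValueError("k_sigma and e_sigma must be non-negative")
        a = np.asarray(self.a_x, dtype=float)
        b = np.asarray(self.b_x, dtype=float)
        if a.shape != (N_AGES,) or not np.all(np.isfinite(a)):
            raise ValueError(f"a_x must be {N_AGES} finite values")
        if b.shape != (N_AGES,) or not np.all(np.isfinite(b)):
            raise ValueError(f"b_x must be {N_AGES} finite values")
        if np.any(b < 0) or abs(b.sum() - 1.0) > 1e-8:
            raise ValueError("b_x must be non-negative and sum to 1")
        if self.years[1] < self.years[0]:
            raise ValueError("years must be an inclusive (first, last) range")


@dataclass
class TrueSurface:
    """True annual death rates m[x,t] plus the latent components."""

    m: pd.DataFrame          # (60 ages x years), deaths per person-year
    k: pd.Series             # period index per year, sums to 0
    params: TrueSurfaceParams

    @property
    def years(self) -> np.ndarray:
        return self.m.columns.to_numpy()

    def q_grid(self) -> pd.DataFrame:
        """Monthly death probabilities q[x,t] via the uniform-deaths conversion."""
        return pd.DataFrame(m_to_q(self.m.to_numpy()), index=self.m.index, columns=self.m.columns)

    def summary(self, year: int):
        """True NMR/IMR/U5MR of a calendar year's period life table."""
        return summary_rates(np.asarray(m_to_q(self.m[year].to_numpy())))


@dataclass
class SurveyDesign:
    """Survey layout: who is interviewed, when, and how far back we look."""

    n_women: int = 5000
    interview_cmc: int = int(cmc(2018, 1))
    fertility_mean: float = 3.0      # Poisson mean births per woman in the window
    window_years: int = 25           # retrospective window before interview
    weight_dispersion: float = 0.0   # SD of sampling weights around 1 (0 = unweighted)

    def validate(self) -> None:
        if self.n_women <= 0:
            raise ValueError("n_women must be positive")
        if not 1 <= self.window_years <= 25:
            raise ValueError("window_years must be in [1, 25]")
        if self.fertility_mean <= 0:
            raise ValueError("fertility_mean must be positive")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be non-negative")


@dataclass
class BiasConfig:
    """Reporting distortions, both off by default.

    survivor_bias: per child death, the probability that the death removes
    the mother (and all her births) from the sample — a simple model of
    mortality clustering between mothers and children.
    heaping_at_12m: probability that a death at age 10-14 months is
    reported as exactly 12 months.
    """

    survivor_bias: float = 0.0
    heaping_at_12m: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.survivor_bias <= 1:
            raise ValueError("survivor_bias must be in [0, 1]")
        if not 0 <= self.heaping_at_12m <= 1:
            raise ValueError("heaping_at_12m must be in [0, 1]")


def make_true_surface(params: TrueSurfaceParams) -> TrueSurface:
    """Generate the true m[x,t] surface from the log-bilinear model.

    k_t is a Gaussian random walk with drift ``k_drift`` and innovation SD
    ``k_sigma``, anchored so that sum_t k_t = 0; age-period noise e[x,t]
    is iid N(0, e_sigma^2).  Reproducible under a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    years = np.arange(params.years[0], params.years[1] + 1)
    T = len(years)

    steps = params.k_drift + params.k_sigma * rng.standard_normal(T - 1)
    k = np.concatenate([[0.0], np.cumsum(steps)])
    k -= k.mean()  # anchor: sum_t k_t = 0

    a = np.asarray(params.a_x, dtype=float)
    b = np.asarray(params.b_x, dtype=float)
    e = params.e_sigma * rng.standard_normal((N_AGES, T))
    logm = a[:, None] + b[:, None] * k[None, :] + e
    m = pd.DataFrame(
        np.exp(logm),
        index=pd.Index(np.arange(N_AGES), name="age_month"),
        columns=pd.Index(years, name="year"),
    )
    return TrueSurface(m=m, k=pd.Series(k, index=m.columns, name="k"), params=params)


def simulate_birth_histories(
    surface: TrueSurface,
    design: SurveyDesign,
    bias: BiasConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate one full-birth-history survey from a true surface.

    Each woman has a Poisson number of births with birth months uniform
    over her retrospective window; each child then walks through age
    months 0..59 drawing a death indicator with probability q[x, t(month)]
    from the surface, and is censored at the interview month.  Biases
    (survivor removal, 12-month heaping) are applied last.

    Returns a BirthRecordTable DataFrame with columns woman_id, child_id,
    dob_cmc, died, death_age_months, interview_cmc, weight.
    """
    design.validate()
    bias = bias or BiasConfig()
    bias.validate()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    interview = int(design.interview_cmc)
    first_birth_cmc = interview - 12 * design.window_years
    # every month a child may live through must be covered by the surface
    need_first_year = int(cmc_year(first_birth_cmc))
    need_last_year = int(cmc_year(interview - 1))
    years = surface.years
    if need_first_year < years[0] or need_last_year > years[-1]:
        raise ValueError(
            f"retrospective window needs surface years {need_first_year}-{need_last_year}, "
            f"surface covers {years[0]}-{years[-1]}"
        )

    n_births = rng.poisson(design.fertility_mean, size=design.n_women)
    woman_id = np.repeat(np.arange(design.n_women), n_births)
    n = len(woman_id)
    dob = rng.integers(first_birth_cmc, interview, size=n)  # uniform birth months

    # monthly survival walk, vectorized over children
    ages = np.arange(N_AGES)
    month_cmc = dob[:, None] + ages[None, :]
    year_idx = np.clip(cmc_year(month_cmc) - years[0], 0, len(years) - 1)
    q_grid = m_to_q(surface.m.to_numpy())          # (60, T)
    q_child = q_grid[ages[None, :], year_idx]      # (n, 60)
    observed = month_cmc < interview               # month fully before interview
    dies = (rng.random((n, N_AGES)) < q_child) & observed
    any_death = dies.any(axis=1)
    first_death = np.where(any_death, dies.argmax(axis=1), -1)

    died = any_death
    death_age = np.where(died, first_death, -1)

    # heaping: deaths at 10-14 months reported as exactly 12
    heapable = died & (death_age >= 10) & (death_age <= 14)
    heap = heapable & (rng.random(n) < bias.heaping_at_12m)
    death_age = np.where(heap, 12, death_age)

    # survivor bias: each child death independently removes the mother
    if bias.survivor_bias > 0:
        removes = died & (rng.random(n) < bias.survivor_bias)
        removed_women = np.unique(woman_id[removes])
        keep = ~np.isin(woman_id, removed_women)
    else:
        keep = np.ones(n, dtype=bool)

    if design.weight_dispersion > 0:
        sigma = np.sqrt(np.log(1.0 + design.weight_dispersion**2))
        w_mother = rng.lognormal(-(sigma**2) / 2.0, sigma, size=design.n_women)
    else:
        w_mother = np.ones(design.n_women)

    rec = pd.DataFrame(
        {
            "woman_id": woman_id,
            "child_id": np.arange(n),
            "dob_cmc": dob,
            "died": died,
            "death_age_months": pd.array(np.where(died, death_age, -1), dtype="Int64"),
            "interview_cmc": interview,
            "weight": w_mother[woman_id],
        }
    )
    rec.loc[~rec["died"], "death_age_months"] = pd.NA
    return rec.loc[keep].reset_index(drop=True)


def write_birth_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_true_surface(surface: TrueSurface, path) -> None:
    long = surface.m.stack().rename("m").reset_index()
    long.to_csv(path, index=False)
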