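# Methods

This note records the statistical model behind `u5mort`, the defaults and
the reasoning behind them, and what the synthetic data can and cannot
establish about behaviour on real surveys.

## Data model and date arithmetic

All dates are century-month codes (CMC = 12·(year − 1900) + month), the
DHS convention, and all age arithmetic is in completed months. Within a
calendar month, death and censoring are resolved at month granularity
only; sub-month timing is never represented, which is exactly the
assumption the rate→probability conversion (below) supplies. A month
straddling two calendar years is assigned to the year containing its
first day — a deterministic, order-free allocation rule.

## Direct estimation

A child contributes one person-month to cell (x, t) for every completed
age-month x lived inside the estimation window, **half** a person-month
plus one death for the month of death, and nothing for the interview
month (the child is censored there). The half-month rule is the exposure
counterpart of assuming deaths fall uniformly within the month: with
monthly death probability q, a cohort of n children yields D ~ Bin(n, q)
deaths and n − D/2 person-months, so the annualized rate estimator
m̂ = 12D/(n − D/2) has expectation 12q/(1 − q/2) — precisely the inverse
of the conversion

    q = (m/12) / (1 + m/24),

making the chain tabulate → rates → probabilities consistent by
construction. The conversion is valid (q < 1) for m < 24 deaths per
person-year; far above any plausible monthly schedule. Cells with zero
exposure are *missing*, not zero: they carry zero weight in the smoother
rather than being imputed.

Records whose reported death age would place the death after the
interview month are rejected and counted. Sampling weights are accepted
but off by default: whether design weights belong in the rate estimator
is genuinely unsettled for this design, so both modes exist behind a
flag.

The retrospective window is a single configurable look-back length per
survey (survey-specific period recommendations from the literature are
out of scope); the generator default is the 25-year maximum usable span
of a birth history, while 5 years is a common conservative choice.

## Calibration

External country-year estimates (UN-IGME-style NMR/IMR/U5MR) are treated
as exact targets for the survival of three age bands: neonatal p[0],
postneonatal ∏₁..₁₁p[x], child ∏₁₂..₅₉p[x]. Each band's survival is
multiplied by f_M = S*_M/S_M. The source definition fixes f_M only at
band level; `u5mort` spreads it uniformly on the log-survival scale
(every monthly p in a band of width w is scaled by f^(1/w)), which
preserves the within-band age shape and achieves exact matching — the
recomputed summary rates equal the targets to 1e-12. Months whose
adjusted p would exceed 1 (possible only when a month had no observed
deaths) are capped just below 1 and the shortfall redistributed over the
band's remaining months, with the band flagged. The reported measurement
error is d_M = 1 − f_M. Years with no target, or with empty cells in the
raw schedule, are left uncalibrated and flagged.

## Penalized Poisson smoothing

Deaths are modelled as y ~ Poisson(e·μ) with person-year exposure e and
log link, log E(y) = log e + Bα. B is a cubic B-spline basis on equally
spaced knots (default one knot per 2 age-months and per 2 years,
configurable); the roughness penalty is λ‖D₂α‖² with a second-order
difference operator, giving a linear-trend null space. The 2-D penalty
is the Kronecker sum over the two coefficient dimensions with one λ per
dimension. Fitting is IRWLS (penalized Fisher scoring) with convergence
at max|Δα| < 1e-8 or 200 iterations (non-convergence returns a flagged
result). Linear predictors are clipped at ±30 to keep the saturated
(λ→0) limit finite. Grids here are at most 60×~30, so dense solves of
the coefficient system are used; array-factorized algorithms for huge
grids are unnecessary at this size.

λ is selected by minimizing BIC = deviance + log(n)·ED over a log-spaced
grid, where ED = tr[(BᵀWB + P)⁻¹BᵀWB] and n counts cells with positive
exposure; ties break toward the smoother fit. BIC rather than AIC is a
deliberate choice: with heavily structured, modest-sized grids the
heavier penalty guards against tracking sampling noise. A consequence
worth knowing: at small-survey exposure BIC will flatten the steep
neonatal end of the age profile (the statistically defensible call, but
it biases NMR downward relative to the truth); the bias vanishes as
exposure grows, which is how the pipeline-consistency tests frame it.
Because calibration rescales *rates* rather than counts, the smoother
consumes calibrated expected counts D′ = (E/12)·m_cal on the original
exposure; the deviance handles non-integer y.

## Lee–Carter / LLT stage

The smoothed log surface is decomposed as log m = a[x] + b[x]k_t +
e[x,t]: a is the age mean over observed years, (b, k) the first singular
triplet of the centered surface, normalized to Σb = 1, Σk = 0 (any
numerical mean of k is absorbed back into a). Variance explained is
s₁²/Σsⱼ². A constant surface is degenerate-safe: b uniform, k ≡ 0,
ve reported as 1 with a flag, never a silent zero. At least three
observed years are required; years with missing values are dropped
(complete-case in time), which is how multiyear gaps are supported.
No second-stage re-estimation of k against observed death counts is
performed: the decomposition is fit to smoothed, calibrated rates, so
the SVD-stage k is used directly.

ve is measured on the calibrated, pre-smoothing surface in the
acceptance tests (the smoothed surface is nearly rank-1 by
construction, so measuring it there would be uninformative).

Forecasting treats k_t as a random walk with drift observed at possibly
unequal intervals. The drift estimator is the endpoint slope
ĉ = (k_T − k_1)/(t_T − t_1), which is the ML drift estimator for this
model under any spacing; the innovation variance is the ML form
σ̂² = mean[(Δk − ĉΔt)²/Δt]. Forecast variance at horizon h stacks three
components:

- process: σ̂²h (narrow bound),
- drift estimation: σ̂²h²/(t_T − t_1) (added for the unbiased bound),
- fitting error: ê²/Σb[x]² — the variance of reading k off a single
  year's age profile — (added for the wide bound).

Intervals are Gaussian on the k scale and mapped monotonically to rates
(b ≥ 0 in practice makes the map monotone age-by-age). The exact
composition of the three published bound widths is not fully specified
in the source literature; the decomposition above is the implementable
reading and is treated as this package's definition. A horizon equal to
the last observed year is allowed and collapses the narrow bound to the
fitted value.

## Indicators and SDG-3 classification

Decline D = 1 − r_end/r_start (negative when mortality rises) and
ARR = 100·(1 − (1−D)^(1/t)) percent per year. Period lengths are
calendar-year differences (1990–2017 = 27). Classification compares
median forecasts (optionally upper bounds for a conservative reading) at
per-1,000 scale without rounding, inclusively: on track by 2030 iff
NMR₂₀₃₀ ≤ 12 and U5MR₂₀₃₀ ≤ 25; else between 2030 and 2050 iff both
thresholds are met by 2050; else after 2050; missing forecasts give
"indeterminate".

## Synthetic data: what it emulates and what it does not

The generator draws log m[x,t] = a[x] + b[x]k_t + e[x,t] — the
generative twin of the model the pipeline fits. Defaults sketch a
high-mortality, steadily improving setting:

- a[x] = log(0.25·e^(−0.25x) + 0.006) per person-year: NMR ≈ 21,
  IMR ≈ 90, U5MR ≈ 115 per 1,000 at the anchored mid-period, with the
  steep early-age decline characteristic of under-5 schedules;
- b[x] ∝ 1 + x/59, normalized: neonatal log-rates decline at about
  0.02/year and child rates at about 0.04/year under the default drift
  k_drift = −1.8 — mirroring the observed pattern that neonatal ARR
  (~2%) lags under-5 ARR (~3%);
- k_sigma = 0.3 and e_sigma = 0.05 give year-to-year wiggle and
  age-period noise of a few percent, comparable to sampling noise in a
  mid-sized survey.

Fertility is a Poisson number of births per woman (mean 3 in the
retrospective window) with uniform birth months; survival is a monthly
Bernoulli walk on q[x,t] with censoring at the interview month. Two
reporting distortions are available and off by default: survivor bias
(each child death independently removes the mother and all her births
with the configured probability) and age heaping of deaths at 12 months.

Passing tests on these data establish internal consistency — that the
estimator inverts the generator, the calibration is exact, and the
decomposition recovers known components. They do *not* establish
robustness to what real birth histories add: displacement and omission
of births, correlated cluster sampling, recall decay with time before
interview, and transfer of deaths across the eligibility boundary. The
bias toggles are deliberately simple mechanisms for exercising the
pipeline's response direction (e.g. survivor bias must depress estimated
U5MR), not calibrated models of those phenomena.

## Problem sizes and determinism

The test suite simulates surveys of roughly 500–17,000 women (up to
~50,000 children) over windows of 10–25 years, and the stochastic
acceptance checks use 50 seeded replicate surfaces; these sizes put
Monte-Carlo error well below the tolerances being asserted while keeping
the whole suite inside a half-minute run. All randomness flows from
explicit integer seeds through named per-stage substreams
(`default_rng([seed, stage])`), so identical configurations produce
byte-identical artifacts.

## Known limitations

- Calibration distributes band factors log-uniformly; if the true
  miscalibration is age-structured within a band, the within-band shape
  is preserved rather than corrected.
- BIC smoothing at small exposure biases the neonatal edge downward (see
  above); a finer knot grid or AIC trades this against noise tracking.
- Forecast intervals are Gaussian on the k scale and ignore parameter
  uncertainty in a and b beyond the wide bound's fitting term.
- Single-country fitting only; no coherence constraints across
  countries, sexes, or causes.
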