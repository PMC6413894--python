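"""Penalized Poisson B-spline smoothing of mortality surfaces.

Death counts y (cellwise) are modelled as Poisson with mean e * mu, where
e is exposure in person-years and mu the hazard, via the log link

    log E(y) = log e + B alpha,

with B an equally-spaced B-spline basis over age (1-D) or the Kronecker
product of age and year bases (2-D), and a difference penalty of
configurable order on the coefficients.  Estimation is iteratively
reweighted least squares (IRWLS); the smoothing parameter(s) are chosen
by BIC over a log-spaced grid, ties broken toward the smoother fit.

Cells with zero exposure carry zero IRWLS weight, so gaps in the
observed surface are bridged by the penalty rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline

_ETA_CLIP = 30.0


@dataclass
class BasisConfig:
    """B-spline basis and penalty configuration (per dimension)."""

    degree: int = 3
    knot_spacing: float = 2.0        # distance between equally spaced knots
    penalty_order: int = 2
    lambda_grid: Sequence[float] = field(default_factory=lambda: tuple(10.0 ** np.arange(-2.0, 7.0)))

    def validate(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.penalty_order < 1:
            raise ValueError("penalty order must be >= 1")
        if self.knot_spacing <= 0:
            raise ValueError("knot spacing must be positive")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be positive")


@dataclass
class Basis1D:
    B: sparse.csr_matrix        # (n_points, n_coef) evaluation table
    D_pen: np.ndarray           # (n_coef - order, n_coef) difference operator
    knots: np.ndarray
    degree: int


@dataclass
class SmoothFit:
    alpha: np.ndarray
    log_mu: np.ndarray          # fitted log-hazard, shape of the input grid
    ed: float                   # effective dimension
    deviance: float
    bic: float
    lambdas: tuple[float, ...]
    converged: bool
    n_iter: int

    @property
    def mu(self) -> np.ndarray:
        return np.exp(self.log_mu)


def build_basis(positions: np.ndarray, config: BasisConfig | None = None) -> Basis1D:
    """Equally spaced B-spline basis with a difference penalty.

    At interior evaluation points the basis rows sum to one (partition of
    unity); the penalty is the ``penalty_order``-th difference operator on
    the coefficient vector.
    """
    config = config or BasisConfig()
    config.validate()
    x = np.asarray(positions, dtype=float)
    if len(np.unique(x)) < config.penalty_order + config.degree + 1:
        raise ValueError(
            f"need at least {config.penalty_order + config.degree + 1} distinct positions, got {len(np.unique(x))}"
        )
    dx = config.knot_spacing
    lo, hi = x.min(), x.max()
    n_seg = max(1, int(np.ceil((hi - lo) / dx)))
    inner = lo + dx * np.arange(n_seg + 1)
    knots = np.concatenate(
        [lo - dx * np.arange(config.degree, 0, -1), inner, inner[-1] + dx * np.arange(1, config.degree + 1)]
    )
    B = BSpline.design_matrix(x, knots, config.degree, extrapolate=True)
    n_coef = B.shape[1]
    if n_coef <= config.penalty_order:
        raise ValueError("basis too small for the requested penalty order")
    D_pen = np.diff(np.eye(n_coef), n=config.penalty_order, axis=0)
    return Basis1D(B=sparse.csr_matrix(B), D_pen=D_pen, knots=knots, degree=config.degree)


def _assemble(D, E, config_age: BasisConfig, config_year: BasisConfig | None):
    """Shared setup for 1-D (vector) and 2-D (matrix) problems.

    Returns (y, e_years, B, penalty builder) where the penalty builder
    maps a lambda tuple to the full penalty matrix.
    """
    D = np.asarray(D, dtype=float)
    E = np.asarray(E, dtype=float)
    if D.shape != E.shape:
        raise ValueError("D and E must be conformable")
    if np.nansum(E) == 0:
        raise ValueError("all-zero exposure: nothing to fit")

    if D.ndim == 1:
        ages = np.arange(D.shape[0])
        ba = build_basis(ages, config_age)
        B = ba.B
        Pa = ba.D_pen.T @ ba.D_pen

        def penalty(lams):
            return lams[0] * Pa

        return D, E, B, penalty, D.shape

    if D.ndim == 2:
        ages = np.arange(D.shape[0])
        years = np.arange(D.shape[1])
        ba = build_basis(ages, config_age)
        by = build_basis(years, config_year or config_age)
        B = sparse.kron(ba.B, by.B, format="csr")  # row-major (age-major) vectorization
        ca, cy = ba.B.shape[1], by.B.shape[1]
        Pa = sparse.kron(sparse.csr_matrix(ba.D_pen.T @ ba.D_pen), sparse.identity(cy), format="csr")
        Py = sparse.kron(sparse.identity(ca), sparse.csr_matrix(by.D_pen.T @ by.D_pen), format="csr")

        def penalty(lams):
            la, ly = (lams[0], lams[0]) if len(lams) == 1 else lams
            return (la * Pa + ly * Py).toarray()

        return D.ravel(), E.ravel(), B, penalty, D.shape

    raise ValueError("D must be a vector (age) or matrix (age x year)")


def fit_pspline(
    D,
    E,
    config: BasisConfig | None = None,
    lambdas: float | Sequence[float] | None = None,
    config_year: BasisConfig | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    _warm_start: np.ndarray | None = None,
) -> SmoothFit:
    """Fit the penalized Poisson model for fixed smoothing parameter(s).

    ``E`` is exposure in person-months (converted internally to
    person-years, so fitted hazards are annual rates).  NaN cells and
    cells with E = 0 get zero weight.  Convergence: max |delta alpha| <
    ``tol`` within ``max_iter`` IRWLS iterations; non-convergence is
    returned flagged, not raised.
    """
    config = config or BasisConfig()
    if lambdas is None:
        lambdas = (config.lambda_grid[len(config.lambda_grid) // 2],)
    if np.isscalar(lambdas):
        lambdas = (float(lambdas),)
    lambdas = tuple(float(l) for l in lambdas)

    y, E_pm, B, penalty_builder, shape = _assemble(D, E, config, config_year)
    e = E_pm / 12.0  # person-years
    valid = np.isfinite(y) & np.isfinite(e) & (e > 0)
    y = np.where(valid, y, 0.0)
    loge = np.where(valid, np.log(np.where(valid, e, 1.0)), 0.0)
    P = penalty_builder(lambdas)
    if sparse.issparse(P):
        P = P.toarray()

    n_coef = B.shape[1]
    if _warm_start is not None:
        alpha = _warm_start.copy()
    else:
        # start from smoothed raw log-rates
        eta0 = np.where(valid, np.log((y + 0.5) / np.where(valid, e, 1.0)), 0.0)
        W0 = sparse.diags(valid.astype(float))
        A0 = (B.T @ W0 @ B).toarray() + P + 1e-6 * np.eye(n_coef)
        alpha = np.linalg.solve(A0, B.T @ (valid * eta0))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(B @ alpha, -_ETA_CLIP, _ETA_CLIP)
        mu_c = np.where(valid, np.exp(loge + eta), 0.0)  # expected counts
        w = mu_c
        z = np.where(valid, eta + np.where(mu_c > 0, (y - mu_c) / np.where(mu_c > 0, mu_c, 1.0), 0.0), 0.0)
        BtW = B.T @ sparse.diags(w)
        A = (BtW @ B).toarray() + P
        rhs = BtW @ z
        try:
            alpha_new = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            alpha_new = np.linalg.lstsq(A, rhs, rcond=None)[0]
        delta = float(np.max(np.abs(alpha_new - alpha)))
        alpha = alpha_new
        if delta < tol:
            converged = True
            break

    eta = np.clip(B @ alpha, -_ETA_CLIP, _ETA_CLIP)
    mu_c = np.where(valid, np.exp(loge + eta), 0.0)
    # effective dimension and deviance at the solution
    BtW = B.T @ sparse.diags(mu_c)
    M = (BtW @ B).toarray()
    A = M + P
    ed = float(np.trace(np.linalg.solve(A, M)))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where((y > 0) & valid, y * np.log(np.where(y > 0, y, 1.0) / np.where(mu_c > 0, mu_c, 1.0)), 0.0)
    dev = float(2.0 * np.sum(term - np.where(valid, y - mu_c, 0.0)))
    n_eff = int(valid.sum())
    bic = dev + np.log(max(n_eff, 1)) * ed

    return SmoothFit(
        alpha=alpha,
        log_mu=np.asarray(B @ alpha).reshape(shape),
        ed=ed,
        deviance=dev,
        bic=float(bic),
        lambdas=lambdas,
        converged=converged,
        n_iter=it,
    )


def select_lambda(
    D,
    E,
    config: BasisConfig | None = None,
    config_year: BasisConfig | None = None,
) -> SmoothFit:
    """Grid-search the smoothing parameter(s) by BIC.

    1-D inputs search ``config.lambda_grid``; 2-D inputs search the
    Cartesian product of the age and year grids.  BIC ties break toward
    the larger (smoother) lambda.
    """
    config = config or BasisConfig()
    config.validate()
    D_arr = np.asarray(D, dtype=float)
    if D_arr.ndim == 1:
        grid = [(l,) for l in sorted(config.lambda_grid)]
    else:
        cy = config_year or config
        grid = [(la, ly) for la in sorted(config.lambda_grid) for ly in sorted(cy.lambda_grid)]
        grid.sort(key=lambda t: (t[0] * t[1], t))

    best: SmoothFit | None = None
    warm = None
    for lams in grid:
        fit = fit_pspline(D, E, config=config, lambdas=lams, config_year=config_year, _warm_start=warm)
        warm = fit.alpha
        if best is None or fit.bic <= best.bic + 1e-9:  # ties -> larger lambda (grid ascends)
            best = fit
    assert best is not None
    return best
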