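"""Model-first benchmark: fitting CARRGO and discovered models to data.

The CARRGO model is the established predator-prey description of CAR
T-cell/glioma killing: logistic tumour growth, mass-action (single-binding)
killing, a Type I functional response, and exponential effector decay::

    dx/dt = rho * x * (1 - x/K) - a_tilde * x * y
    dy/dt = alpha * x * y - theta * y

Both CARRGO and the sparse-discovered polynomial models are fit to
replicate-aggregated data (pointwise mean, weighted by the replicate range)
with bounded Levenberg-Marquardt, and compared by reduced chi-squared, AIC
and BIC.  The information criteria use the Gaussian-RSS convention
``N*ln(RSS/N) + penalty``; absolute values are therefore only comparable
within that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .models import CoefficientMatrix, LIBRARY_TERMS
from .synthetic import IntegrationError, simulate_trajectories

__all__ = [
    "CarrgoParameters",
    "FitStatistics",
    "carrgo_matrix",
    "aggregate_replicates",
    "fit_statistics",
    "lmo_fit",
]


@dataclass(frozen=True)
class CarrgoParameters:
    """CARRGO model parameters (all positive)."""

    rho: float       # tumour growth rate, 1/h
    K: float         # tumour carrying capacity, CI
    a_tilde: float   # killing rate, 1/(CI h)
    alpha: float     # CAR T response rate, 1/(CI h)
    theta: float     # CAR T death rate, 1/h

    def __post_init__(self):
        for name in ("rho", "K", "a_tilde", "alpha", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def carrgo_matrix(p: CarrgoParameters) -> CoefficientMatrix:
    """CARRGO expressed on the cubic library (it is a sub-model of it)."""
    xi = np.zeros((2, 9))
    xi[0, LIBRARY_TERMS.index("x")] = p.rho
    xi[0, LIBRARY_TERMS.index("x^2")] = -p.rho / p.K
    xi[0, LIBRARY_TERMS.index("xy")] = -p.a_tilde
    xi[1, LIBRARY_TERMS.index("xy")] = p.alpha
    xi[1, LIBRARY_TERMS.index("y")] = -p.theta
    return CoefficientMatrix(xi)


@dataclass
class FitStatistics:
    chi2_reduced: float
    aic: float
    bic: float
    rss: float
    n_points: int
    n_params: int


def aggregate_replicates(
    wells: list[np.ndarray], floor_frac: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and range (max - min) across replicate series.

    The range doubles as the fit weight, so it is floored at ``floor_frac``
    of the series maximum to avoid infinite weights where replicates agree.
    A single replicate has no range; a constant floor is used with a
    warning.
    """
    arr = np.asarray(wells, dtype=float)
    mean = arr.mean(axis=0)
    floor = floor_frac * max(float(arr.max()), 1e-12)
    if arr.shape[0] < 2:
        warnings.warn(
            "single replicate: range undefined, using constant floor sigma",
            stacklevel=2,
        )
        return mean, np.full(mean.shape, floor)
    rng = arr.max(axis=0) - arr.min(axis=0)
    return mean, np.maximum(rng, floor)


def fit_statistics(
    residuals: np.ndarray, n_params: int, rss_floor: float = 1e-300
) -> FitStatistics:
    """Reduced chi-squared, AIC and BIC from weighted residuals.

    ``chi2_reduced = sum(r^2) / (N - k)``;
    ``AIC = N ln(RSS/N) + 2k``; ``BIC = N ln(RSS/N) + k ln N``.  An exactly
    zero RSS is floored and the information criteria reported as ``-inf``.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    n, k = r.size, int(n_params)
    if n <= k:
        raise ValueError(f"need more residuals ({n}) than parameters ({k})")
    rss = float(np.sum(r * r))
    chi2 = rss / (n - k)
    if rss <= rss_floor:
        return FitStatistics(chi2, -np.inf, -np.inf, rss, n, k)
    aic = n * np.log(rss / n) + 2 * k
    bic = n * np.log(rss / n) + k * np.log(n)
    return FitStatistics(chi2, aic, bic, rss, n, k)


def _bounds(value: float, frac: tuple[float, float]) -> tuple[float, float]:
    lo, hi = frac[0] * value, frac[1] * value
    return (min(lo, hi), max(lo, hi))   # sign-aware


def lmo_fit(
    model: CoefficientMatrix | CarrgoParameters,
    times: np.ndarray,
    cancer_mean: np.ndarray,
    cancer_range: np.ndarray,
    y0: float,
    cart_endpoints: tuple[float, float] | None = None,
    cart_mean: np.ndarray | None = None,
    cart_range: np.ndarray | None = None,
    bounds_frac: tuple[float, float] = (0.8, 1.2),
    endpoint_sigma_frac: float = 0.1,
) -> tuple[CoefficientMatrix, FitStatistics, lmfit.minimizer.MinimizerResult]:
    """Bounded Levenberg-Marquardt fit of a model to aggregated data.

    ``model`` provides both structure and initial guesses: a
    :class:`CarrgoParameters` fits the five CARRGO constants, a
    :class:`CoefficientMatrix` fits its active coefficients.  The search is
    boxed to ``bounds_frac`` (80-120%) of each guess, sign-aware.

    Residuals are range-weighted cancer deviations, plus either the two
    CAR T endpoint deviations (real-data mode) or, when ``cart_mean`` is
    given, the full CAR T series (dense validation mode).  Returns the
    fitted model as a coefficient matrix, its statistics, and the raw
    lmfit result.
    """
    if isinstance(model, CarrgoParameters):
        names = ["rho", "K", "a_tilde", "alpha", "theta"]
        guesses = {n: getattr(model, n) for n in names}

        def build(values: dict) -> CoefficientMatrix:
            return carrgo_matrix(CarrgoParameters(**values))

    else:
        support = np.argwhere(model.xi != 0)
        names = [f"c_{r}_{c}" for r, c in support]
        guesses = {f"c_{r}_{c}": float(model.xi[r, c]) for r, c in support}

        def build(values: dict) -> CoefficientMatrix:
            xi = np.zeros((2, 9))
            for (r, c) in support:
                xi[r, c] = values[f"c_{r}_{c}"]
            return CoefficientMatrix(xi)

    params = lmfit.Parameters()
    for n in names:
        lo, hi = _bounds(guesses[n], bounds_frac)
        if lo == hi:  # zero guess: keep fixed
            params.add(n, value=guesses[n], vary=False)
        else:
            params.add(n, value=guesses[n], min=lo, max=hi)

    x0 = float(cancer_mean[0])
    endpoint_sigma = endpoint_sigma_frac * max(
        abs(cart_endpoints[0]) if cart_endpoints else 1.0, 1e-12
    )

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        values = {n: p[n].value for n in names}
        try:
            xi = build(values)
        except ValueError:
            return np.full(len(times) + 2, 1e6)
        try:
            xs, ys = simulate_trajectories(xi, x0, y0, times)
        except IntegrationError:
            return np.full(len(times) + 2, 1e6)
        res = [(xs - cancer_mean) / cancer_range]
        if cart_mean is not None:
            rng = (
                cart_range
                if cart_range is not None
                else np.full(cart_mean.shape, endpoint_sigma)
            )
            res.append((ys - cart_mean) / rng)
        elif cart_endpoints is not None:
            res.append(
                np.array(
                    [
                        (ys[0] - cart_endpoints[0]) / endpoint_sigma,
                        (ys[-1] - cart_endpoints[1]) / endpoint_sigma,
                    ]
                )
            )
        return np.concatenate(res)

    out = lmfit.minimize(residuals, params, method="leastsq")
    if not out.success:
        warnings.warn("LM optimization did not converge; using last iterate",
                      stacklevel=2)
    fitted = {n: out.params[n].value for n in names}
    for n in names:
        p = out.params[n]
        if p.vary and (
            np.isclose(p.value, p.min, rtol=1e-3)
            or np.isclose(p.value, p.max, rtol=1e-3)
        ):
            warnings.warn(f"parameter {n} sits at its search bound",
                          stacklevel=2)
    xi_fit = build(fitted)
    stats = fit_statistics(out.residual, n_params=int(out.nvarys))
    return xi_fit, stats, out
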