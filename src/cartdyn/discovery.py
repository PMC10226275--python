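"""Constrained sparse regression over the cubic two-species library.

The discovery stage regresses numerical time derivatives onto the nine
monomials [x, y, x^2, xy, y^2, x^3, x^2y, xy^2, y^3], under the sign/zero
constraint pattern implied by the effective predator-prey theory, and scans
the sparsity weight ``lambda`` over a log grid to build a Pareto front of
(number of active terms) versus (simulation RMSE).  The selected model is
the sparsest one whose simulated trajectories stay within a small slack of
the best-fitting model on the front.

Solver
------
The sparse estimate minimizes the relaxed objective

    min_{Xi, W}  1/2 ||Xdot - Theta Xi||^2 + lam R(W) + 1/(2 nu) ||Xi - W||^2

with an l1-type regularizer and nu = 1e-5.  Eliminating ``Xi`` in closed
form leaves a convex quadratic-plus-l1 problem in ``W`` that coordinate
descent solves exactly; the per-coordinate threshold is expressed in
coefficient units so that ``lambda`` is directly comparable to coefficient
magnitudes.  Because the single-trajectory library is near-degenerate
(smallest singular-value ratios of order 1e-4), the relaxation is followed
by a sequentially-thresholded constrained least-squares refinement —
the standard unbiasing step — seeded from the full constraint-allowed
support and iterated to a fixed point.  The refined matrix is the sparse
model reported everywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import lstsq as dense_lstsq
from scipy.optimize import lsq_linear

from .models import LIBRARY_TERMS, CoefficientMatrix
from .synthetic import AssayDataset, IntegrationError, simulate_trajectories

__all__ = [
    "FREE",
    "ZERO",
    "NONPOS",
    "NONNEG",
    "DEFAULT_CONSTRAINTS",
    "DEFAULT_LAMBDA_GRID",
    "RegressionProblem",
    "ParetoPoint",
    "ParetoFront",
    "build_library",
    "estimate_derivatives",
    "stack_replicates",
    "sr3_solve",
    "model_rmse",
    "pareto_scan",
    "select_model",
    "forward_stability_report",
    "coefficient_histograms",
]

# Constraint codes per coefficient.
FREE, ZERO, NONPOS, NONNEG = 1, 0, -1, 2

#: Constraint pattern of the effective predator-prey theory: the cancer
#: equation carries no pure-y terms and only killing (nonpositive)
#: interactions; the CAR T equation carries no pure-x terms, free response
#: terms on xy and x^2y, and nonpositive double-binding/self-limit terms.
DEFAULT_CONSTRAINTS = np.array(
    [
        #  x     y     x^2   xy     y^2   x^3     x^2y  xy^2    y^3
        [FREE, ZERO, FREE, NONPOS, ZERO, NONPOS, ZERO, NONPOS, ZERO],
        [ZERO, FREE, ZERO, FREE,   FREE, ZERO,   FREE, NONPOS, NONPOS],
    ]
)

#: 40 log-spaced sparsity weights covering lambda in [1e-8, 1e1].
DEFAULT_LAMBDA_GRID = np.logspace(-8, 1, 40)


@dataclass
class RegressionProblem:
    """Stacked regression data for one experimental condition."""

    theta: np.ndarray                 # rows x 9 evaluated library
    xdot: np.ndarray                  # rows x 2 derivative matrix
    constraints: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONSTRAINTS.copy()
    )
    nu: float = 1e-5

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.xdot = np.asarray(self.xdot, dtype=float)
        if self.theta.shape[0] != self.xdot.shape[0]:
            raise ValueError("theta and xdot row counts differ")
        if self.theta.shape[1] != len(LIBRARY_TERMS):
            raise ValueError("theta must have 9 library columns")
        if self.xdot.ndim != 2 or self.xdot.shape[1] != 2:
            raise ValueError("xdot must be rows x 2")
        if np.asarray(self.constraints).shape != (2, 9):
            raise ValueError("constraint spec must cover all 18 entries")
        if self.nu <= 0:
            raise ValueError("nu must be positive")


@dataclass
class ParetoPoint:
    lam: float
    n_active: int
    rmse: float
    xi: CoefficientMatrix


ParetoFront = list  # list[ParetoPoint]


def build_library(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate the cubic monomial library, columns in canonical order."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return np.column_stack(
        [x, y, x * x, x * y, y * y, x**3, x * x * y, x * y * y, y**3]
    )


def estimate_derivatives(values: np.ndarray, dt: float) -> np.ndarray:
    """Centered finite differences, one-sided at the boundaries.

    The boundary estimates are only first-order accurate; callers stacking
    regression rows should drop them (see :func:`stack_replicates`).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 points to differentiate")
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
    d[0] = (v[1] - v[0]) / dt
    d[-1] = (v[-1] - v[-2]) / dt
    return d


def stack_replicates(
    wells: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    constraints: np.ndarray | None = None,
    nu: float = 1e-5,
    boundary_trim: int = 1,
) -> RegressionProblem:
    """Row-stack per-well (x, y, xdot, ydot) blocks into one problem.

    Derivatives must be computed per well before stacking (differences must
    never straddle well boundaries).  ``boundary_trim`` rows are dropped at
    each end of every well, discarding the low-order one-sided derivative
    estimates whose errors otherwise leak into near-degenerate library
    directions.  Wells may have different lengths.
    """
    if not wells:
        raise ValueError("need at least one well")
    thetas, derivs = [], []
    for x, y, xd, yd in wells:
        if not (len(x) == len(y) == len(xd) == len(yd)):
            raise ValueError("well arrays must share a length")
        sl = slice(boundary_trim, len(x) - boundary_trim or None)
        thetas.append(build_library(np.asarray(x)[sl], np.asarray(y)[sl]))
        derivs.append(np.column_stack([np.asarray(xd)[sl], np.asarray(yd)[sl]]))
    return RegressionProblem(
        theta=np.vstack(thetas),
        xdot=np.vstack(derivs),
        constraints=(
            DEFAULT_CONSTRAINTS.copy() if constraints is None else constraints
        ),
        nu=nu,
    )


def _cd_l1_row(
    P: np.ndarray,
    q: np.ndarray,
    con_row: np.ndarray,
    lam: float,
    w0: np.ndarray | None = None,
    max_sweeps: int = 10_000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Exact coordinate descent on the W-marginal of the relaxed objective.

    The soft threshold acts in coefficient units (per-coordinate weight
    ``lam * P_jj``); zero-constrained entries are projected out and
    sign-constraint violators projected to zero.
    """
    n = q.size
    W = np.zeros(n) if w0 is None else w0.copy()
    W[con_row == ZERO] = 0.0
    for _ in range(max_sweeps):
        prev = W.copy()
        for j in range(n):
            cj = con_row[j]
            if cj == ZERO:
                continue
            r = q[j] - P[j] @ W + P[j, j] * W[j]
            w = np.sign(r) * max(abs(r) - lam * P[j, j], 0.0) / P[j, j]
            if cj == NONPOS and w > 0:
                w = 0.0
            elif cj == NONNEG and w < 0:
                w = 0.0
            W[j] = w
        if np.max(np.abs(W - prev)) < tol:
            break
    return W


def _constrained_lstsq(
    theta_act: np.ndarray, d: np.ndarray, con_act: np.ndarray
) -> np.ndarray:
    """Least squares with per-entry sign bounds on the active columns."""
    if np.all(con_act == FREE):
        sol, *_ = dense_lstsq(theta_act, d)
        return sol
    ub = np.where(con_act == NONPOS, 0.0, np.inf)
    lb = np.where(con_act == NONNEG, 0.0, -np.inf)
    res = lsq_linear(theta_act, d, bounds=(lb, ub))
    return res.x


def _refine_row(
    theta: np.ndarray,
    d: np.ndarray,
    con_row: np.ndarray,
    lam: float,
    max_iter: int = 20,
) -> np.ndarray:
    """Sequentially-thresholded constrained least squares (unbiasing).

    Starts from the full constraint-allowed support, alternately refits and
    drops entries with |coefficient| <= lam until the support is stable.
    """
    n = theta.shape[1]
    act = con_row != ZERO
    W = np.zeros(n)
    for _ in range(max_iter):
        if not act.any():
            return np.zeros(n)
        sol = _constrained_lstsq(theta[:, act], d, con_row[act])
        W = np.zeros(n)
        W[act] = sol
        new_act = np.abs(W) > lam
        if np.array_equal(new_act, act):
            break
        act = new_act
    W[np.abs(W) <= lam] = 0.0
    return W


def sr3_solve(
    problem: RegressionProblem,
    lam: float,
    w0: np.ndarray | None = None,
    refine: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the constrained sparse regression at one sparsity weight.

    Returns ``(Xi, W)``: ``Xi`` is the relaxed (dense) coefficient matrix,
    ``W`` the sparse constrained matrix.  With ``lam=0`` and an
    all-free constraint pattern both equal the least-squares solution.
    ``w0`` (2x9) warm-starts the coordinate descent, e.g. along a lambda
    path.  ``refine=False`` skips the unbiasing refinement and returns the
    projected relaxation solution as ``W``.
    """
    theta, con = problem.theta, np.asarray(problem.constraints)
    A = theta.T @ theta
    n = A.shape[1]
    # marginal problem after eliminating Xi:  P = (nu A + I)^-1 A
    rhs = np.column_stack([A, theta.T @ problem.xdot])
    M = np.linalg.solve(problem.nu * A + np.eye(n), rhs)
    P, Q = M[:, :n], M[:, n:]

    W = np.zeros((2, n))
    Xi = np.zeros((2, n))
    for row in range(2):
        w_init = None if w0 is None else np.asarray(w0)[row]
        W[row] = _cd_l1_row(P, Q[:, row], con[row], lam, w_init)
        # relaxed (dense) solution given the sparse W
        Xi[row] = np.linalg.solve(
            problem.nu * A + np.eye(n),
            problem.nu * (theta.T @ problem.xdot[:, row]) + W[row],
        )
    if refine:
        for row in range(2):
            W[row] = _refine_row(theta, problem.xdot[:, row], con[row], lam)
    return Xi, W


def model_rmse(
    xi: CoefficientMatrix | np.ndarray,
    times: np.ndarray,
    wells: Sequence[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Pooled simulation RMSE of a candidate model against measured wells.

    The model is integrated from each well's initial conditions over the
    observation window and compared to both species across all replicates.
    Integration failure or divergence yields ``inf``.
    """
    sq, count = 0.0, 0
    for x_obs, y_obs in wells:
        try:
            xs, ys = simulate_trajectories(xi, x_obs[0], y_obs[0], times)
        except IntegrationError:
            return float("inf")
        sq += float(np.sum((xs - x_obs) ** 2) + np.sum((ys - y_obs) ** 2))
        count += 2 * len(times)
    return float(np.sqrt(sq / count))


def pareto_scan(
    problem: RegressionProblem,
    times: np.ndarray,
    wells: Sequence[tuple[np.ndarray, np.ndarray]],
    lam_grid: np.ndarray | None = None,
    refine: bool = True,
) -> ParetoFront:
    """Sparsity-versus-accuracy front over the lambda grid.

    For every lambda the constrained solve runs (warm-started along the
    grid), the candidate ODE is simulated from the data's initial
    conditions, and the pooled RMSE recorded; blow-ups are kept on the
    front with ``rmse = inf``.
    """
    lam_grid = DEFAULT_LAMBDA_GRID if lam_grid is None else np.asarray(lam_grid)
    front: ParetoFront = []
    w_prev: np.ndarray | None = None
    for lam in lam_grid:
        _, W = sr3_solve(problem, float(lam), w0=w_prev, refine=refine)
        w_prev = W
        xi = CoefficientMatrix(W)
        rmse = model_rmse(xi, times, wells)
        front.append(
            ParetoPoint(
                lam=float(lam),
                n_active=xi.n_active,
                rmse=rmse,
                xi=xi,
            )
        )
    return front


def select_model(front: ParetoFront, slack: float = 0.05) -> ParetoPoint:
    """Pareto-knee selection: sparsest model within slack of the best RMSE.

    Among models with ``rmse <= (1 + slack) * min_finite_rmse`` the one with
    fewest active terms wins; ties break toward larger lambda.
    """
    finite = [p for p in front if np.isfinite(p.rmse)]
    if not finite:
        raise RuntimeError("no finite-RMSE model on the Pareto front")
    best = min(p.rmse for p in finite)
    candidates = [p for p in finite if p.rmse <= (1.0 + slack) * best]
    candidates.sort(key=lambda p: (p.n_active, -p.lam))
    return candidates[0]


def forward_stability_report(
    xi: CoefficientMatrix | np.ndarray,
    x0: float,
    y0: float,
    horizon: float,
    dt: float = 0.25,
    extension_factor: float = 2.0,
) -> dict:
    """Qualitative stability of a model under forward prediction.

    Integrates to ``extension_factor * horizon`` and reports per-species
    minima, negativity flags, and a steady-state classification:
    ``extinct`` (a species ends below tolerance), ``steady`` (terminal
    derivatives vanish), or ``oscillatory`` (persistent sign changes of the
    derivative over the extension window).
    """
    t = np.arange(0.0, extension_factor * horizon + 0.5 * dt, dt)
    try:
        xs, ys = simulate_trajectories(xi, x0, y0, t)
    except IntegrationError as err:
        return {
            "integrated": False,
            "last_time": err.last_time,
            "classification": "divergent",
        }
    m = xi.xi if isinstance(xi, CoefficientMatrix) else np.asarray(xi)
    tol = 1e-6 * max(1.0, abs(x0) + abs(y0))
    dxs = np.gradient(xs, dt)
    dys = np.gradient(ys, dt)
    tail = slice(int(0.75 * len(t)), None)

    def sign_changes(v):
        s = np.sign(v[np.abs(v) > tol])
        return int(np.sum(s[1:] != s[:-1]))

    terminal_rate = max(abs(dxs[-1]), abs(dys[-1]))
    oscillating = sign_changes(dxs[tail]) + sign_changes(dys[tail]) > 2
    if oscillating and terminal_rate > tol:
        classification = "oscillatory"
    elif xs[-1] < tol or ys[-1] < tol:
        classification = "extinct"
    elif terminal_rate <= 10 * tol:
        classification = "coexistent-steady"
    else:
        classification = "transient"
    return {
        "integrated": True,
        "min_cancer": float(xs.min()),
        "min_cart": float(ys.min()),
        "negative_cancer": bool(xs.min() < -tol),
        "negative_cart": bool(ys.min() < -tol),
        "final_cancer": float(xs[-1]),
        "final_cart": float(ys[-1]),
        "classification": classification,
    }


def coefficient_histograms(
    front: ParetoFront, bins: int = 12
) -> dict[str, dict]:
    """Per-term coefficient values collected across the lambda scan.

    For every library term (per equation) the values at which the term is
    active anywhere on the front are pooled; the summary includes a modal
    bin, mirroring how persistently-active terms tend to concentrate near
    their selected value until deactivation.
    """
    out: dict[str, dict] = {}
    for row, lhs in enumerate(("dx/dt", "dy/dt")):
        for col, term in enumerate(LIBRARY_TERMS):
            values = np.array(
                [p.xi[row, col] for p in front if p.xi[row, col] != 0.0]
            )
            key = f"{lhs}:{term}"
            if values.size == 0:
                out[key] = {"values": values, "count": 0}
                continue
            counts, edges = np.histogram(values, bins=bins)
            mode_bin = int(np.argmax(counts))
            out[key] = {
                "values": values,
                "count": int(values.size),
                "bin_edges": edges,
                "bin_counts": counts,
                "modal_value": float(
                    0.5 * (edges[mode_bin] + edges[mode_bin + 1])
                ),
            }
    return out
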