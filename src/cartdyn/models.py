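"""Effective predator-prey model space for CAR T-cell / cancer-cell kinetics.

The two-species system couples a cancer-cell population ``x`` (prey, in Cell
Index units) and a CAR T-cell population ``y`` (predator)::

    dx/dt = G_x(x) - x * B_x(y)
    dy/dt = G_y(y) + y * R(x) - x * B_y(y)

with three interchangeable building blocks:

* growth/death ``G`` — logistic, weak Allee, or strong Allee;
* cell-cell binding ``B`` — single or double CAR T-cell conjugation to one
  cancer cell, under fast irreversible kinetics;
* functional response ``R`` — Type I (linear), II (saturating, fast-to-slow)
  or III (sigmoidal, slow-to-fast).

Because the binding and response terms are ratios of polynomials, the system
is approximated by *effective* models: binomial expansions truncated at
second order, valid for small predator counts (``y < h/k``) and effective
treatment (``x < g``).  Every effective model is a polynomial ODE over the
cubic two-species monomial library, represented here as a 2x9 coefficient
matrix.  The inverse direction — reading growth family, response type and
binding mode off a discovered coefficient matrix — is what makes sparse
model discovery biologically interpretable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "LIBRARY_TERMS",
    "GrowthParameters",
    "BindingParameters",
    "ResponseParameters",
    "CoefficientMatrix",
    "InterpretedModel",
    "expand_growth",
    "factor_growth",
    "exact_binding_rate",
    "effective_binding_coeffs",
    "exact_response",
    "truncated_response",
    "effective_response_coeffs",
    "assemble_effective_rhs",
    "classify_coefficients",
]

#: Fixed column order of the cubic monomial library.  Row 1 of a coefficient
#: matrix is dx/dt, row 2 is dy/dt.
LIBRARY_TERMS: tuple[str, ...] = (
    "x", "y", "x^2", "xy", "y^2", "x^3", "x^2y", "xy^2", "y^3",
)

GrowthFamily = Literal["logistic", "weak_allee", "strong_allee", "none"]


class ParameterError(ValueError):
    """Invalid or inconsistent model parameters."""


@dataclass(frozen=True)
class GrowthParameters:
    """Single-species growth/death model.

    Parameters
    ----------
    family : {"logistic", "weak_allee", "strong_allee", "none"}
    rho : float
        Net growth rate (1/h).  Positive for any family other than ``none``.
    K : float
        Carrying capacity (CI).
    A : float, optional
        Weak-Allee constant (CI); required for ``weak_allee``.  The weak
        Allee factor ``(1 + x/A)`` reduces the per-capita rate at low
        density; ``A -> inf`` recovers logistic growth.
    B : float, optional
        Strong-Allee survival threshold (CI); required for ``strong_allee``
        and must satisfy ``0 < B < K``.
    """

    family: GrowthFamily
    rho: float = 0.0
    K: float = 0.0
    A: float | None = None
    B: float | None = None

    def __post_init__(self) -> None:
        if self.family == "none":
            return
        if self.rho <= 0:
            raise ParameterError(f"rho must be positive, got {self.rho}")
        if self.K <= 0:
            raise ParameterError(f"K must be positive, got {self.K}")
        if self.family == "weak_allee":
            if self.A is None or self.A <= 0:
                raise ParameterError("weak Allee growth requires A > 0")
        if self.family == "strong_allee":
            if self.B is None or not (0 < self.B < self.K):
                raise ParameterError(
                    "strong Allee growth requires 0 < B < K, got "
                    f"B={self.B}, K={self.K}"
                )

    def rate(self, x: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the factored growth rate G(x)."""
        x = np.asarray(x, dtype=float)
        if self.family == "none":
            return np.zeros_like(x)
        if self.family == "logistic":
            return self.rho * x * (1 - x / self.K)
        if self.family == "weak_allee":
            return self.rho * x * (1 - x / self.K) * (1 + x / self.A)
        return self.rho * x * (1 - x / self.K) * (x / self.B - 1)


@dataclass(frozen=True)
class BindingParameters:
    """Rate constants of the fast-irreversible conjugate-binding model.

    ``a, b`` (``c, d``) collect the conjugate-outcome rates that remove
    cancer cells (CAR T-cells) through single and double conjugates; ``h``
    is the summed single-conjugate death rate and ``k`` the double-conjugate
    association rate.  The effective quadratic expansion is valid only while
    ``y < h/k``.
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    h: float = 1.0
    k: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "h", "k"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class ResponseParameters:
    """Functional response of the predator to prey density.

    ``p`` is the response rate; ``g`` the prey-density threshold at which
    predator behaviour changes (only meaningful for Types II/III).
    """

    type: Literal["I", "II", "III"]
    p: float
    g: float | None = None

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ParameterError("p must be positive")
        if self.type in ("II", "III") and (self.g is None or self.g <= 0):
            raise ParameterError(f"Type {self.type} response requires g > 0")


def expand_growth(g: GrowthParameters) -> np.ndarray:
    """Expand a factored growth model into monomial coefficients.

    Returns the coefficients ``(c1, c2, c3)`` of ``c1*x + c2*x^2 + c3*x^3``.
    The cubic coefficient is never positive, and vanishes exactly for
    logistic growth.
    """
    if g.family == "none":
        return np.zeros(3)
    if g.family == "logistic":
        return np.array([g.rho, -g.rho / g.K, 0.0])
    if g.family == "weak_allee":
        return np.array([
            g.rho,
            g.rho / g.A - g.rho / g.K,
            -g.rho / (g.K * g.A),
        ])
    # strong Allee
    return np.array([
        -g.rho,
        g.rho / g.K + g.rho / g.B,
        -g.rho / (g.K * g.B),
    ])


def factor_growth(
    c1: float, c2: float, c3: float, tol: float = 1e-8
) -> GrowthParameters:
    """Classify and factor a monomial coefficient triple into a growth model.

    The sign pattern decides the family:

    * ``c3 == 0``, ``c1 > 0``, ``c2 < 0`` — logistic, ``rho = c1``,
      ``K = -c1/c2``;
    * ``c1 > 0``, ``c3 < 0`` — weak Allee.  From ``K*A = -c1/c3`` and
      ``K - A = -c2/c3``, ``K`` solves ``K^2 - S*K - P = 0`` with
      ``S = -c2/c3``, ``P = -c1/c3`` (positive root);
    * ``c1 < 0``, ``c2 > 0``, ``c3 < 0`` — strong Allee, ``K`` and ``B`` are
      the roots of ``z^2 - S*z + P = 0`` with ``S = -c2/c3``,
      ``P = c1/c3`` (``K`` the larger);
    * all coefficients below ``tol`` — no growth.

    Any other pattern yields family ``"none"`` with a warning rather than an
    exception, so that discovered models with unanticipated sign structure
    still produce a report.
    """
    c1, c2, c3 = float(c1), float(c2), float(c3)
    z1, z2, z3 = (abs(v) <= tol for v in (c1, c2, c3))
    if z1 and z2 and z3:
        return GrowthParameters("none")
    if z3:
        if c1 > 0 and c2 < 0:
            return GrowthParameters("logistic", rho=c1, K=-c1 / c2)
        warnings.warn(
            f"coefficient triple ({c1:g}, {c2:g}, {c3:g}) matches no growth "
            "family; classifying as none",
            stacklevel=2,
        )
        return GrowthParameters("none")
    if c3 < 0 and c1 > 0:
        # weak Allee: K*A = -c1/c3 > 0 and K - A = -c2/c3
        P = -c1 / c3
        S = -c2 / c3
        K = 0.5 * (S + np.sqrt(S * S + 4.0 * P))
        A = K - S
        return GrowthParameters("weak_allee", rho=c1, K=K, A=A)
    if c3 < 0 and c1 < 0 and c2 > 0:
        # strong Allee: K+B = -c2/c3, K*B = c1/c3
        S = -c2 / c3
        P = c1 / c3
        disc = S * S - 4.0 * P
        if disc >= 0:
            K = 0.5 * (S + np.sqrt(disc))
            B = 0.5 * (S - np.sqrt(disc))
            if B > 0:
                return GrowthParameters("strong_allee", rho=-c1, K=K, B=B)
    warnings.warn(
        f"coefficient triple ({c1:g}, {c2:g}, {c3:g}) matches no growth "
        "family; classifying as none",
        stacklevel=2,
    )
    return GrowthParameters("none")


def exact_binding_rate(
    bp: BindingParameters,
    y: np.ndarray | float,
    mode: Literal["single", "double"] = "double",
    side: Literal["cancer", "cart"] = "cancer",
) -> np.ndarray | float:
    """Per-cell loss rate from conjugate binding, exact rational form.

    ``side="cancer"`` evaluates B_x(y) (uses ``a``, ``b``); ``side="cart"``
    evaluates B_y(y) (uses ``c``, ``d``).  Single binding is ``a*y/h``;
    double binding ``(a*y + b*y^2)/(h + k*y)``.
    """
    if bp.h == 0:
        raise ZeroDivisionError("binding rate undefined for h = 0")
    y = np.asarray(y, dtype=float)
    lin, quad = (bp.a, bp.b) if side == "cancer" else (bp.c, bp.d)
    if mode == "single":
        return lin * y / bp.h
    return (lin * y + quad * y * y) / (bp.h + bp.k * y)


def effective_binding_coeffs(
    bp: BindingParameters, side: Literal["cancer", "cart"] = "cancer"
) -> tuple[float, float]:
    """Coefficients ``(linear, quadratic)`` of the effective binding model.

    Binomial expansion of the double-binding denominator truncated at
    O(y^2): the cancer side gives ``(a/h, (b*h - a*k)/h^2)``, the CAR T side
    ``(c/h, (d*h - c*k)/h^2)``.  A negative quadratic coefficient flips the
    concavity relative to the exact model (it arises when the
    double-conjugate death rates ``b`` or ``d`` are too small) and triggers
    a warning.
    """
    if bp.h == 0:
        raise ZeroDivisionError("effective binding undefined for h = 0")
    lin, quad = (bp.a, bp.b) if side == "cancer" else (bp.c, bp.d)
    first = lin / bp.h
    second = (quad * bp.h - lin * bp.k) / bp.h**2
    if second < 0:
        warnings.warn(
            f"effective double binding ({side}): quadratic coefficient "
            f"{second:g} is negative — concavity no longer matches the "
            "exact rational model",
            stacklevel=2,
        )
    return first, second


def exact_response(rp: ResponseParameters, x: np.ndarray | float):
    """Functional response R(x) in its exact rational form."""
    x = np.asarray(x, dtype=float)
    if rp.type == "I":
        return rp.p * x
    if rp.type == "II":
        return rp.p * x / (rp.g + x)
    return rp.p * x * x / (rp.g * rp.g + x * x)


def truncated_response(
    rp: ResponseParameters, x: np.ndarray | float, order: int
) -> np.ndarray | float:
    """Binomial expansion of R(x) truncated after ``order`` terms.

    For ``x/g < 1`` the partial sums alternate around the exact value and
    converge monotonically in error.  ``order=1`` keeps only the leading
    term (Type II then coincides with a Type I response of rate ``p/g``).
    """
    if order < 1:
        raise ParameterError("order must be >= 1")
    x = np.asarray(x, dtype=float)
    if rp.type == "I":
        return rp.p * x
    if rp.type == "II":
        u = x / rp.g
        total = np.zeros_like(x)
        for j in range(order):
            total = total + (-u) ** j
        return rp.p * u * total
    u = (x / rp.g) ** 2
    total = np.zeros_like(x)
    for j in range(order):
        total = total + (-u) ** j
    return rp.p * u * total


def effective_response_coeffs(rp: ResponseParameters) -> tuple[float, float]:
    """Coefficients ``(on x, on x^2)`` of the truncated functional response.

    Type I -> ``(p, 0)``; Type II -> ``(p/g, -p/g^2)``; Type III ->
    ``(0, p/g^2)``, i.e. the O(x^2/g^2) truncation of the expansions.
    """
    if rp.type == "I":
        return rp.p, 0.0
    if rp.type == "II":
        return rp.p / rp.g, -rp.p / rp.g**2
    return 0.0, rp.p / rp.g**2


class CoefficientMatrix:
    """2x9 coefficient matrix over the cubic monomial library.

    Row 0 holds the dx/dt coefficients, row 1 dy/dt, with columns in the
    fixed :data:`LIBRARY_TERMS` order.
    """

    __slots__ = ("xi",)

    def __init__(self, xi: np.ndarray | Iterable):
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (2, 9):
            raise ParameterError(f"expected a 2x9 matrix, got {xi.shape}")
        if not np.all(np.isfinite(xi)):
            raise ParameterError("coefficient matrix must be finite")
        self.xi = xi

    def __getitem__(self, key):
        return self.xi[key]

    def __eq__(self, other):
        return isinstance(other, CoefficientMatrix) and np.array_equal(
            self.xi, other.xi
        )

    def __repr__(self) -> str:
        rows = []
        for r, lhs in enumerate(("dx/dt", "dy/dt")):
            terms = [
                f"{c:+.3g}*{t}"
                for c, t in zip(self.xi[r], LIBRARY_TERMS)
                if c != 0
            ]
            rows.append(f"{lhs} = " + (" ".join(terms) or "0"))
        return "CoefficientMatrix(" + "; ".join(rows) + ")"

    def term(self, row: int, name: str) -> float:
        """Coefficient of library term ``name`` in equation ``row`` (0=x)."""
        return float(self.xi[row, LIBRARY_TERMS.index(name)])

    @property
    def support(self) -> np.ndarray:
        """Boolean 2x9 mask of active (nonzero) terms."""
        return self.xi != 0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.xi))

    def rhs(self, state: np.ndarray) -> np.ndarray:
        """Evaluate the ODE right-hand side at ``state = (x, y)``."""
        x, y = state
        monomials = np.array(
            [x, y, x * x, x * y, y * y, x**3, x * x * y, x * y * y, y**3]
        )
        return self.xi @ monomials

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"library_order": list(LIBRARY_TERMS), "xi": self.xi.tolist()}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "CoefficientMatrix":
        order = tuple(doc.get("library_order", LIBRARY_TERMS))
        if order != LIBRARY_TERMS:
            # permute columns back into canonical order
            perm = [order.index(t) for t in LIBRARY_TERMS]
            return cls(np.asarray(doc["xi"], dtype=float)[:, perm])
        return cls(np.asarray(doc["xi"], dtype=float))

    @classmethod
    def from_json(cls, source: str | Path) -> "CoefficientMatrix":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass
class InterpretedModel:
    """Biological reading of a discovered coefficient matrix.

    Reported interaction magnitudes follow the convention of the summary
    tables: ``a_tilde``, ``b_tilde``, ``c_tilde`` are absolute values, while
    ``alpha`` and ``beta`` keep their signs (the signs carry the response
    type).
    """

    cancer_growth: GrowthParameters
    cart_growth: GrowthParameters
    response_type: Literal["I_or_II_leading", "II", "III", "none"]
    binding_mode: Literal["single", "double", "mixed", "none"]
    alpha: float = 0.0
    beta: float = 0.0
    a_tilde: float = 0.0
    b_tilde: float = 0.0
    c_tilde: float = 0.0

    def to_dict(self) -> dict:
        out: dict = {}
        for species, g in (
            ("cancer", self.cancer_growth),
            ("cart", self.cart_growth),
        ):
            out[f"{species}_growth"] = g.family
            out[f"{species}_rho"] = g.rho if g.family != "none" else None
            out[f"{species}_K"] = g.K if g.family != "none" else None
            out[f"{species}_allee"] = (
                g.A if g.family == "weak_allee"
                else g.B if g.family == "strong_allee" else None
            )
        out["response_type"] = self.response_type
        out["binding_mode"] = self.binding_mode
        for k in ("alpha", "beta", "a_tilde", "b_tilde", "c_tilde"):
            out[k] = getattr(self, k)
        return out


def assemble_effective_rhs(
    gx: GrowthParameters,
    gy: GrowthParameters,
    bp: BindingParameters | None = None,
    rp: ResponseParameters | None = None,
    binding_mode: Literal["single", "double"] = "double",
) -> CoefficientMatrix:
    """Compose growth, binding and response blocks into the 2x9 matrix.

    The cancer equation receives its growth expansion on (x, x^2, x^3) and
    loses ``x * B_x(y)``; the CAR T equation receives its growth expansion on
    (y, y^2, y^3), gains ``y * R(x)`` and loses ``x * B_y(y)``.  All columns
    that the effective theory leaves empty stay structurally zero.
    """
    xi = np.zeros((2, 9))
    xi[0, [0, 2, 5]] = expand_growth(gx)
    xi[1, [1, 4, 8]] = expand_growth(gy)
    if bp is not None:
        if binding_mode == "single":
            xi[0, 3] -= bp.a / bp.h
            xi[1, 3] -= bp.c / bp.h
        else:
            bx1, bx2 = effective_binding_coeffs(bp, "cancer")
            by1, by2 = effective_binding_coeffs(bp, "cart")
            xi[0, 3] -= bx1
            xi[0, 7] -= bx2
            xi[1, 3] -= by1
            xi[1, 7] -= by2
    if rp is not None:
        r1, r2 = effective_response_coeffs(rp)
        xi[1, 3] += r1
        xi[1, 6] += r2
    return CoefficientMatrix(xi)


def classify_coefficients(
    xi: CoefficientMatrix | np.ndarray, tol: float = 1e-8
) -> InterpretedModel:
    """Read biological structure off a (discovered) coefficient matrix.

    Growth families come from factoring the pure-species triples; the
    response type from the signs of the xy and x^2y coefficients of dy/dt
    ((+,-) Type II, (-,+) Type III, (+,0) Type I or leading-order Type II);
    the binding mode from which killing terms are active in dx/dt (xy^2 ->
    double, xy only -> single, xy in dx/dt plus xy^2 in dy/dt -> mixed).
    Entries with magnitude below ``tol`` count as inactive.
    """
    m = xi.xi if isinstance(xi, CoefficientMatrix) else np.asarray(xi, float)
    a = np.where(np.abs(m) > tol, m, 0.0)

    cancer_growth = factor_growth(a[0, 0], a[0, 2], a[0, 5], tol=tol)
    cart_growth = factor_growth(a[1, 1], a[1, 4], a[1, 8], tol=tol)

    alpha, beta = a[1, 3], a[1, 6]
    if alpha > 0 and beta < 0:
        response = "II"
    elif beta > 0:
        response = "III"
    elif alpha > 0:
        response = "I_or_II_leading"
    else:
        response = "none"

    cancer_xy, cancer_xy2, cart_xy2 = a[0, 3], a[0, 7], a[1, 7]
    if cancer_xy2 != 0:
        binding = "double"
    elif cancer_xy != 0 and cart_xy2 != 0:
        binding = "mixed"
    elif cancer_xy != 0:
        binding = "single"
    else:
        binding = "none"

    return InterpretedModel(
        cancer_growth=cancer_growth,
        cart_growth=cart_growth,
        response_type=response,
        binding_mode=binding,
        alpha=float(alpha),
        beta=float(beta),
        a_tilde=float(abs(cancer_xy)),
        b_tilde=float(abs(cancer_xy2)),
        c_tilde=float(abs(cart_xy2)),
    )
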