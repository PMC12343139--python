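"""Closed-form analysis of the normalized IFFL1 system.

The normalized system is

    x'(t) = -x(t) + u,      x(0) = x0,
    y'(t) = -x(t) y(t) + u, y(0) = 1,

for a constant dose u > 0.  The controller solves exactly to
``x(t) = u - (u - x0) e^{-t}``, and variation of parameters gives the
output, its cumulative integral (the cDR) and the u-derivative of the cDR
as explicit integrals involving the exponential-integral function Ei.
These closed forms serve as exact oracles for the ODE machinery and carry
the substance of the unconditional cDR-monotonicity result: the integrand
of the u-derivative is controlled by a single-sign-change function f_kappa
and a positivity statement about

    G(u) = ∫₀^∞ (e^{-u w(s)} - e^{-u s}) / (1 - e^{-s}) ds,
    w(s) = s + e^{-s} - 1,

which also admits the factorially convergent series
``G(u) = Σ_{n≥0} L_n(u)/(n+1)`` with ``L_n(u) = Π_{j=1..n} u/(u+j)``.

All functions are pure; callers normalize general IFFL1 parameters first
(see :func:`cdrmotifs.motifs.normalize`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import expi

__all__ = [
    "NormalizedIFFL1Input",
    "x_closed",
    "y_closed",
    "exp_integral",
    "boundary_integral_I",
    "cdr_closed",
    "dcdr_du_closed",
    "lemma_functions",
    "G_value",
]

_QUAD_KW = {"epsabs": 1e-10, "epsrel": 1e-10, "limit": 200}


class QuadratureError(RuntimeError):
    """Adaptive quadrature failed to converge."""


@dataclass(frozen=True)
class NormalizedIFFL1Input:
    """Normalized dose, initial controller and horizon; kappa = u - x0."""

    u: float
    x0: float
    T: float

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("u must be positive")
        if self.x0 < 0:
            raise ValueError("x0 must be non-negative")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def kappa(self) -> float:
        return self.u - self.x0


def x_closed(t: float, u: float, x0: float) -> float:
    """Controller trajectory x(t) = u - (u - x0) e^{-t}."""
    return u - (u - x0) * np.exp(-t)


def y_closed(t: float, u: float, x0: float) -> float:
    """Output trajectory by variation of parameters.

    y(t) = e^{(u-x0)(1-e^{-t}) - u t}
           + u ∫₀ᵗ e^{(u-x0) e^{-t}(e^s - 1) - u s} ds.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return 1.0
    kappa = u - x0
    if kappa == 0:
        return 1.0  # x ≡ u keeps y stationary at 1
    emt = math.exp(-t)
    head = math.exp(kappa * (1.0 - emt) - u * t)

    def integrand(s: float) -> float:
        return math.exp(kappa * emt * math.expm1(s) - u * s)

    val, err = quad(integrand, 0.0, t, **_QUAD_KW)
    if err > 1e-7 * max(1.0, abs(val)):
        raise QuadratureError(f"y_closed quadrature error {err:.2e}")
    return head + u * val


def exp_integral(t: float) -> float:
    """Exponential integral Ei(t) = PV ∫_{-∞}^t e^w / w dw.

    For t < 0 this equals -E1(-t); t = 0 is a logarithmic singularity.
    """
    if t == 0:
        raise ValueError("Ei has a singularity at 0")
    return float(expi(t))


def _ei_diff_series(a1: float, a2: float) -> float:
    """Ei(a1) - Ei(a2) - log(a1/a2) via the entire part of Ei.

    Ei(z) = euler_gamma + log|z| + Σ_{n≥1} zⁿ/(n·n!); the log difference
    is handled by the caller, which knows it analytically.
    """
    total = 0.0
    p1, p2 = 1.0, 1.0
    for n in range(1, 60):
        p1 *= a1
        p2 *= a2
        term = (p1 - p2) / (n * math.factorial(n))
        total += term
        if abs(term) < 1e-17 * max(1.0, abs(total)):
            break
    return total


def boundary_integral_I(s: float, T: float, u: float, x0: float) -> float:
    """The boundary term I(s,T) = Ei(κ(1-e^{-s})) - Ei(κ(e^{s-T}-e^{-T})).

    κ = u - x0.  Continuous limits: I(s,T) → T as s → 0⁺, I(T,T) = 0, and
    at κ = 0 the value is exactly T - s.  Near s = 0 both Ei arguments
    vanish and the difference is evaluated by the series expansion of the
    entire part of Ei with the exact log difference T - s.
    """
    if not (0 < s <= T):
        raise ValueError("require 0 < s <= T")
    kappa = u - x0
    if kappa == 0:
        return T - s
    if s == T:
        return 0.0  # equal Ei arguments; avoids inf - inf for large kappa
    a1 = kappa * (-math.expm1(-s))
    a2 = kappa * math.exp(-T) * math.expm1(s)
    # log(a1/a2) = T - s exactly: a1/a2 = e^{T-s}
    if max(abs(a1), abs(a2)) < 0.1:
        return (T - s) + _ei_diff_series(a1, a2)
    return float(expi(a1) - expi(a2))


def _stable_ratio(s: float) -> float:
    """s / (1 - e^{-s}) with the s → 0 limit 1."""
    if s == 0:
        return 1.0
    return s / (-math.expm1(-s))


def cdr_closed(u: float, x0: float, T: float) -> float:
    """Cumulative dose response of the normalized IFFL1 system.

    cDR(u,T) = T + ∫₀ᵀ e^{-u s}/(1-e^{-s})
               (e^{κ(1-e^{-s})} - e^{κ(e^{s-T}-e^{-T})}) ds,  κ = u - x0.

    The integrand's removable singularity at s = 0 (limit κ(1 - e^{-T}))
    is benign once the bracketed difference is written with expm1:
    the difference equals e^{a2} expm1(κ ρ(s)) with
    ρ(s) = (1-e^{-s})(1-e^{s-T}).
    """
    if u <= 0 or T <= 0:
        raise ValueError("require u > 0 and T > 0")
    kappa = u - x0
    if kappa == 0:
        return T

    def integrand(s: float) -> float:
        if s == 0.0:
            return kappa * (-math.expm1(-T))
        one_memt = -math.expm1(-s)              # 1 - e^{-s}
        rho = one_memt * (-math.expm1(s - T))   # (1-e^{-s})(1-e^{s-T})
        a1 = kappa * one_memt
        a2 = kappa * math.exp(-T) * math.expm1(s)
        if abs(kappa * rho) < 1.0:
            # expm1 factoring is exact where the two exponentials cancel
            return math.exp(-u * s + a2) * math.expm1(kappa * rho) / one_memt
        # far from cancellation both exponents are <= 0 (kappa <= u), so
        # the direct difference cannot overflow
        return (math.exp(-u * s + a1) - math.exp(-u * s + a2)) / one_memt

    val, err = quad(integrand, 0.0, T, **_QUAD_KW)
    if err > 1e-7 * max(1.0, abs(val)):
        raise QuadratureError(f"cdr_closed quadrature error {err:.2e}")
    return T + val


def dcdr_du_closed(u: float, x0: float, T: float) -> float:
    """u-derivative of the cDR of the normalized IFFL1 system.

    d(cDR)/du = ∫₀ᵀ e^{-u s} ( e^{κ(1-e^{-s})} (1 - s/(1-e^{-s}))
                + e^{κ(e^{s-T}-e^{-T})} (s/(1-e^{-s}) - e^{s-T}) ) ds.

    The integral is split at T/2 where the integrand changes character
    (the single-sign-change function f_kappa crosses there in the worst
    case).  The result is non-negative for every (u, x0, T) — this is the
    unconditional cDR monotonicity of IFFL1.
    """
    if u <= 0 or T <= 0:
        raise ValueError("require u > 0 and T > 0")
    kappa = u - x0

    def integrand(s: float) -> float:
        r = _stable_ratio(s)
        a1 = kappa * (-math.expm1(-s))
        a2 = kappa * math.exp(-T) * math.expm1(s)
        return math.exp(-u * s) * (math.exp(a1) * (1.0 - r)
                                   + math.exp(a2) * (r - math.exp(s - T)))

    total = 0.0
    for lo, hi in ((0.0, T / 2), (T / 2, T)):
        val, err = quad(integrand, lo, hi, **_QUAD_KW)
        if err > 1e-6 * max(1.0, abs(val)):
            raise QuadratureError(f"dcdr_du quadrature error {err:.2e}")
        total += val
    return total


def phi(z: float) -> float:
    """phi(z) = z / (e^z - 1) with phi(0) = 1; decreasing, -1 <= phi' <= 0."""
    if z == 0:
        return 1.0
    return z / math.expm1(z)


def lemma_functions(s: float, kappa: float, T: float
                    ) -> tuple[float, float, float]:
    """The single-crossing machinery: (rho(s), f_kappa(s), phi(kappa*rho)).

    rho(s) = (1 - e^{-s})(1 - e^{s-T});
    f_kappa(s) = e^{-kappa*rho(s)} (s/(1-e^{-s}) - e^{s-T})
                 - (s/(1-e^{-s}) - 1).

    f_kappa tends to 1 - e^{-T} > 0 as s → 0⁺, vanishes at s = T, and
    crosses zero at most once on (0, T).
    """
    if not (0 <= s <= T):
        raise ValueError("require 0 <= s <= T")
    rho = (-math.expm1(-s)) * (-math.expm1(s - T))
    r = _stable_ratio(s)
    f = math.exp(-kappa * rho) * (r - math.exp(s - T)) - (r - 1.0)
    return rho, f, phi(kappa * rho)


def _G_series(u: float, tol: float = 1e-13, max_terms: int = 100_000
              ) -> float:
    # L_n(u) = prod_{j<=n} u/(u+j); terms L_n/(n+1) decay factorially once
    # n exceeds u, so plain truncation with a geometric tail bound suffices.
    total = 1.0  # n = 0 term: L_0 = 1
    L = 1.0
    for n in range(1, max_terms):
        L *= u / (u + n)
        term = L / (n + 1)
        total += term
        ratio = u * (n + 1) / ((u + n + 1) * (n + 2))
        if ratio < 0.5 and term * ratio / (1 - ratio) < tol:
            return total
    raise QuadratureError(
        f"G series did not reach tail bound {tol} in {max_terms} terms "
        f"(u={u})")


def _G_integral(u: float) -> float:
    def integrand(s: float) -> float:
        if s == 0.0:
            return 0.0
        one_memt = -math.expm1(-s)
        # e^{-u w(s)} - e^{-u s} = e^{-u s}(e^{u(1-e^{-s})} - 1)
        return math.exp(-u * s) * math.expm1(u * one_memt) / one_memt

    val, err = quad(integrand, 0.0, np.inf, **_QUAD_KW)
    if err > 1e-7 * max(1.0, abs(val)):
        raise QuadratureError(f"G integral quadrature error {err:.2e}")
    return val


def G_value(u: float, method: str = "series", tol: float = 1e-13,
            max_terms: int = 100_000) -> float:
    """G(u), by its series or its defining integral.

    series:   G(u) = Σ_{n≥0} L_n(u)/(n+1), L_n(u) = Π_{j=1..n} u/(u+j),
              truncated when a geometric tail bound falls below ``tol``.
    integral: G(u) = ∫₀^∞ (e^{-u w(s)} - e^{-u s})/(1 - e^{-s}) ds,
              w(s) = s + e^{-s} - 1, by adaptive quadrature.

    G is strictly increasing in u; its derivative is the infinite-horizon
    cDR u-sensitivity of the normalized IFFL1 system at x0 = 0.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    if method == "series":
        return _G_series(u, tol=tol, max_terms=max_terms)
    if method == "integral":
        return _G_integral(u)
    raise ValueError(f"unknown method {method!r}")
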