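"""Error-system analysis of the normalized integral-feedback motif.

The normalized IFB system (K = 0) is

    x'(t) = x(t) (y(t) - p),   x(0) = x0 > 0,
    y'(t) = u / x(t) - y(t),   y(0) = p,

with set-point p.  In the error coordinate ỹ = y - p and the inverse
controller z = u/x the dynamics become

    z' = -z ỹ,     ỹ' = z - p - ỹ,

and ỹ satisfies a damped harmonic oscillator with time-varying frequency
ω(t) = sqrt(z(t)):  ỹ'' + ỹ' + z ỹ = 0.  The scaled cDR sensitivity
β(t) = 1 - u ∫₀ᵗ ∂u ỹ ds obeys the same oscillator from β(0)=1, β'(0)=0.
The Hamiltonians

    H  = ỹ² + (ỹ'/ω)²,     Hβ = β² + (β'/ω)²

decay whenever ỹ < 2, which yields:

* if (u - p·x0)² ≤ 4·u·x0 (i.e. H(0) ≤ 4) then ỹ ≤ 2 for all time and
  the cDR is monotone in u at every horizon;
* in general, monotonicity can only fail on [0, Tu] where
  Tu = inf{t : H(t) ≤ 4 and Hβ(t) ≤ 1}; after Tu, β(t) ≤ 1 always holds.

The non-monotonicity score S(u) = ∫₀^{Tu} (β(t) - 1)₊ dt is positive
exactly when the cDR is non-monotonic at some horizon.  For x0 = p = 1
the score first becomes positive near u ≈ 220.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .motifs import MotifError, MotifSpec, steady_states
from .response import SimulationError, SolverOptions, Trajectory

__all__ = [
    "ErrorDiagnostics",
    "ScoreResult",
    "simulate_error_system",
    "steady_error_cdr",
    "condition_h0",
    "compute_Tu",
    "score_S",
    "scan_scores",
    "lyapunov_check",
]

# Normalized-time step for the Tu pre-scan and the S(u) quadrature grid;
# resolves the beta oscillation period 2*pi/sqrt(u) up to u ~ 4e5.
_SCAN_STEP = 0.01


@dataclass(frozen=True)
class ErrorDiagnostics:
    """Joint trajectory of the IFB error system and its diagnostics."""

    times: np.ndarray
    y_err: np.ndarray       # ỹ(t) = y(t) - p
    y_err_integral: np.ndarray  # ∫₀ᵗ ỹ ds (quadrature state)
    z_values: np.ndarray    # z(t) = u / x(t)
    omega: np.ndarray       # ω(t) = sqrt(z(t))
    H: np.ndarray           # ỹ² + (ỹ'/ω)²
    beta_values: np.ndarray
    beta_dot: np.ndarray
    H_beta: np.ndarray      # β² + (β'/ω)²
    u: float
    p: float
    x0: float


@dataclass(frozen=True)
class ScoreResult:
    """Non-monotonicity diagnostics at a single dose."""

    u: float
    Tu: float
    S: float
    condition_holds: bool


def _error_rhs(p: float):
    def rhs(t, s):
        z, ye, beta, beta_d, _w = s
        return (-z * ye,
                z - p - ye,
                beta_d,
                -beta_d - z * beta,
                ye)
    return rhs


def _diagnostics_from(sol_t, sol_y, u: float, p: float, x0: float
                      ) -> ErrorDiagnostics:
    z, ye, beta, beta_d, w = sol_y
    if z.min() <= 0:
        raise SimulationError(
            f"z reached {z.min():.3e} <= 0 at u={u} (analytically z > 0; "
            "integration failure)")
    omega = np.sqrt(z)
    ye_dot = z - p - ye
    H = ye ** 2 + (ye_dot / omega) ** 2
    H_beta = beta ** 2 + (beta_d / omega) ** 2
    return ErrorDiagnostics(times=sol_t, y_err=ye, y_err_integral=w,
                            z_values=z, omega=omega, H=H, beta_values=beta,
                            beta_dot=beta_d, H_beta=H_beta, u=u, p=p, x0=x0)


def simulate_error_system(u: float, p: float, x0: float, horizon: float,
                          solver_options: SolverOptions | None = None
                          ) -> ErrorDiagnostics:
    """Integrate (z, ỹ, β, β') from (u/x0, 0, 1, 0) and derive H, Hβ."""
    if min(u, p, x0, horizon) <= 0:
        raise ValueError("u, p, x0 and horizon must all be positive")
    opts = solver_options or SolverOptions()
    n = max(opts.n_points, int(horizon / _SCAN_STEP) + 1)
    t_eval = np.linspace(0.0, horizon, n)
    sol = solve_ivp(_error_rhs(p), (0.0, horizon),
                    [u / x0, 0.0, 1.0, 0.0, 0.0], t_eval=t_eval,
                    **opts.ivp_kwargs())
    if not sol.success:
        raise SimulationError(f"error-system solver failed at u={u}: "
                              f"{sol.message}")
    return _diagnostics_from(sol.t, sol.y, u, p, x0)


def steady_error_cdr(u: float, p: float, x0: float) -> tuple[float, float]:
    """Infinite-horizon error cDR and its u-derivative, in closed form.

    ∫₀^∞ ỹ dt = log(u) - log(p·x0)  (from z(t) = (u/x0) e^{-∫ỹ} and
    z(∞) = p), and differentiating gives ∫₀^∞ ∂u ỹ dt = 1/u > 0: at
    infinite horizon the error cDR is always increasing in the dose.
    """
    if min(u, p, x0) <= 0:
        raise ValueError("u, p and x0 must be positive")
    return math.log(u) - math.log(p * x0), 1.0 / u


def condition_h0(u: float, p: float, x0: float) -> tuple[float, bool]:
    """Initial Hamiltonian H(0) = (u - p·x0)²/(u·x0) and the test H(0) ≤ 4.

    When the condition holds the error stays ≤ 2 forever and the cDR is
    monotone at every horizon.
    """
    if min(u, p, x0) <= 0:
        raise ValueError("u, p and x0 must be positive")
    H0 = (u - p * x0) ** 2 / (u * x0)
    return H0, H0 <= 4.0


def _integrate_dense(u: float, p: float, x0: float, horizon: float,
                     opts: SolverOptions):
    sol = solve_ivp(_error_rhs(p), (0.0, horizon), [u / x0, 0.0, 1.0, 0.0, 0.0],
                    dense_output=True, **opts.ivp_kwargs())
    if not sol.success:
        raise SimulationError(f"error-system solver failed at u={u}: "
                              f"{sol.message}")
    return sol


def _g_of(sol, p: float):
    """g(t) = max(H - 4, Hβ - 1); Tu is the first root crossing g <= 0."""
    def g(t: float) -> float:
        z, ye, beta, beta_d, _w = sol.sol(t)
        ye_dot = z - p - ye
        H = ye ** 2 + ye_dot ** 2 / z
        Hb = beta ** 2 + beta_d ** 2 / z
        return max(H - 4.0, Hb - 1.0)
    return g


def compute_Tu(u: float, p: float, x0: float,
               solver_options: SolverOptions | None = None,
               max_horizon: float | None = None) -> float:
    """First time at which both H(t) ≤ 4 and Hβ(t) ≤ 1.

    Hβ(0) = 1 always, so Tu = 0 whenever H(0) ≤ 4.  Otherwise the dense
    solver output is scanned at step 0.01 (the admissible set need not be
    an interval) and the entry time is refined by bisection to 1e-8.
    """
    opts = solver_options or SolverOptions()
    H0, holds = condition_h0(u, p, x0)
    if holds:
        return 0.0
    if max_horizon is None:
        max_horizon = 50.0 * max(1.0, 1.0 / p)
    sol = _integrate_dense(u, p, x0, max_horizon, opts)
    g = _g_of(sol, p)
    ts = np.arange(0.0, max_horizon + _SCAN_STEP, _SCAN_STEP)
    prev = 0.0
    for t in ts[1:]:
        if g(t) <= 0.0:
            if g(prev) <= 0.0:  # pathological: entered within first step
                return float(prev)
            return float(brentq(g, prev, t, xtol=1e-8))
        prev = t
    raise SimulationError(
        f"Tu not reached within horizon {max_horizon} at u={u} "
        "(increase max_horizon)")


def score_S(u: float, p: float, x0: float,
            solver_options: SolverOptions | None = None,
            max_horizon: float | None = None) -> ScoreResult:
    """Non-monotonicity score S(u) = ∫₀^{Tu} (β(t) - 1)₊ dt.

    S > 0 certifies that the cDR map u ↦ ∫₀ᵀ ỹ dt is non-monotonic at some
    horizon T ≤ Tu; S = 0 whenever the initial-energy condition holds
    (then Tu = 0).
    """
    opts = solver_options or SolverOptions()
    H0, holds = condition_h0(u, p, x0)
    Tu = compute_Tu(u, p, x0, solver_options=opts, max_horizon=max_horizon)
    if Tu == 0.0:
        return ScoreResult(u=u, Tu=0.0, S=0.0, condition_holds=holds)
    sol = _integrate_dense(u, p, x0, Tu, opts)
    n = max(2, int(math.ceil(Tu / _SCAN_STEP)) + 1)
    ts = np.linspace(0.0, Tu, n)
    beta = sol.sol(ts)[2]
    excess = np.maximum(beta - 1.0, 0.0)
    S = float(np.trapezoid(excess, ts))
    return ScoreResult(u=u, Tu=Tu, S=S, condition_holds=holds)


def scan_scores(u_grid, p: float, x0: float,
                solver_options: SolverOptions | None = None,
                onset_tol: float = 0.5, score_tol: float = 1e-10
                ) -> tuple[list[ScoreResult], float | None]:
    """Score every dose on the grid and locate the onset of S > 0.

    Returns the per-dose results and the smallest dose with a positive
    score, refined by bisection between the last zero-score and first
    positive-score grid doses to within ``onset_tol``.  ``None`` when the
    whole scan stays at zero.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    results = [score_S(u, p, x0, solver_options=solver_options)
               for u in u_grid]
    scores = np.array([r.S for r in results])
    positive = np.where(scores > score_tol)[0]
    if len(positive) == 0:
        return results, None
    i = int(positive[0])
    if i == 0:
        return results, float(u_grid[0])
    lo, hi = float(u_grid[i - 1]), float(u_grid[i])
    while hi - lo > onset_tol:
        mid = 0.5 * (lo + hi)
        if score_S(mid, p, x0, solver_options=solver_options).S > score_tol:
            hi = mid
        else:
            lo = mid
    return results, 0.5 * (lo + hi)


def scores_to_json(results: list[ScoreResult], path: str | Path,
                   onset: float | None = None) -> None:
    payload = {"onset": onset,
               "records": [{"u": r.u, "Tu": r.Tu, "S": r.S,
                            "condition_holds": r.condition_holds}
                           for r in results]}
    Path(path).write_text(json.dumps(payload, indent=2))


def scores_to_csv(results: list[ScoreResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["u", "Tu", "S", "condition_holds"])
        for r in results:
            writer.writerow([r.u, r.Tu, r.S, int(r.condition_holds)])


def lyapunov_check(spec: MotifSpec, u: float, trajectory: Trajectory,
                   slack: float = 1e-8) -> tuple[np.ndarray, float]:
    """Energy Lyapunov function V along an IFB trajectory.

    In the coordinates (ln x, alpha*y - delta) the IFB system is a
    mass-spring system with nonlinear spring f(x) = c - alpha*beta*u /
    (K + e^x), c = gamma*delta, and V(x, y) = ∫_{x̄}^x f(r) dr + y²/2
    decreases along trajectories (dV/dt = -gamma*y² ≤ 0), which proves
    global stability of the interior fixed point.

    Returns the V(t) series and the maximum observed increase between
    consecutive samples; raises if V increases by more than ``slack``.
    """
    if spec.motif_id != "IFB":
        raise MotifError("lyapunov_check applies to IFB only")
    a, b, g, d, K = spec.alpha, spec.beta, spec.gamma, spec.delta, spec.K
    interior = [pt for pt in steady_states(spec, u) if pt[0] > 0]
    if not interior:
        raise MotifError(
            f"no interior fixed point for u={u} (K >= alpha*beta*u/"
            "(gamma*delta))")
    x_bar_orig = interior[0][0]
    xbar = math.log(x_bar_orig)
    c = g * d

    def f_integral(x: float) -> float:
        # ∫_{xbar}^{x} (c - a*b*u/(K + e^r)) dr
        if K == 0:
            return (c * (x - xbar)
                    + a * b * u * (math.exp(-x) - math.exp(-xbar)))
        val, _ = quad(lambda r: c - a * b * u / (K + math.exp(r)),
                      xbar, x, **{"epsabs": 1e-12, "epsrel": 1e-12})
        return val

    V = np.array([
        f_integral(math.log(x)) + 0.5 * (a * y - d) ** 2
        for x, y in zip(trajectory.x_values, trajectory.y_values)])
    increases = np.diff(V)
    max_increase = float(increases.max()) if len(increases) else 0.0
    if max_increase > slack:
        raise SimulationError(
            f"Lyapunov function increased by {max_increase:.3e} (> {slack})")
    return V, max_increase
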