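"""Numerical dose-response machinery.

Builds trajectories, dose-response curves DR(u,T) = y_u(T) and cumulative
dose-response curves cDR(u,T) = integral of y_u over [0,T], forward
sensitivities d/du of the state, monotonicity verdicts, and the
scale-invariance (fold-change detection) deviation.

The cumulative output z(t) is carried as an extra quadrature state
(dz/dt = y) so cDR values are exact to solver tolerance and independent of
the output grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .motifs import Dose, MotifError, MotifSpec, evaluate_rhs

__all__ = [
    "SolverOptions",
    "Trajectory",
    "ResponseCurve",
    "SensitivityTrajectory",
    "MonotonicityVerdict",
    "simulate",
    "response_curve",
    "sensitivity",
    "check_monotone",
    "fcd_deviation",
    "monotone_embedding_check",
]


class SimulationError(RuntimeError):
    """Integration failed or produced an unphysical state."""


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive-solver controls shared by every simulation entry point.

    Defaults (rtol 1e-9, atol 1e-12, DOP853) are tight because the
    Hamiltonian event detection and monotonicity verdicts downstream are
    tolerance-sensitive.
    """

    rtol: float = 1e-9
    atol: float = 1e-12
    method: str = "DOP853"
    max_step: float = np.inf
    n_points: int = 400  # output grid size (uniform on [0, horizon])

    def ivp_kwargs(self) -> dict:
        return {"rtol": self.rtol, "atol": self.atol,
                "method": self.method, "max_step": self.max_step}


@dataclass(frozen=True)
class Trajectory:
    """State trajectory with the running output integral z(t) = ∫₀ᵗ y."""

    times: np.ndarray
    x_values: np.ndarray
    y_values: np.ndarray
    z_values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.x_values) == len(self.y_values)
                == len(self.z_values) == n):
            raise ValueError("trajectory arrays must share one length")

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    @property
    def cdr(self) -> float:
        """cDR(u, horizon): the final value of the running integral."""
        return float(self.z_values[-1])

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack(
            [self.times, self.x_values, self.y_values, self.z_values])
        np.savetxt(path, arr, delimiter=",", header="time,x,y,z", comments="")


@dataclass(frozen=True)
class ResponseCurve:
    """DR or cDR values on a dose grid at a fixed horizon T."""

    kind: str                # "DR" or "cDR"
    horizon_T: float
    u_grid: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("DR", "cDR"):
            raise ValueError(f"kind must be 'DR' or 'cDR', got {self.kind!r}")
        u = np.asarray(self.u_grid, dtype=float)
        if len(u) != len(self.values):
            raise ValueError("u_grid and values must share one length")
        if len(u) > 1 and not np.all(np.diff(u) > 0):
            raise ValueError("u_grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.u_grid, self.values]),
                   delimiter=",", header="u,value", comments="")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "horizon_T": self.horizon_T,
            "u_grid": np.asarray(self.u_grid).tolist(),
            "values": np.asarray(self.values).tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class SensitivityTrajectory:
    """Forward sensitivities ∂x/∂u, ∂y/∂u and their output integral."""

    times: np.ndarray
    du_x: np.ndarray
    du_y: np.ndarray
    du_z: np.ndarray

    @property
    def dcdr_du(self) -> float:
        return float(self.du_z[-1])


@dataclass(frozen=True)
class MonotonicityVerdict:
    """Result of scanning a response curve for decreases."""

    is_monotone: bool
    violations: list[tuple[int, int]]
    max_decrease: float

    def __bool__(self) -> bool:
        return self.is_monotone


def _augmented_rhs(spec: MotifSpec, u: float):
    def rhs(t, state):
        dx, dy = evaluate_rhs(spec, u, (state[0], state[1]))
        return (dx, dy, max(state[1], 0.0))  # dz = y, clipped at 0
    return rhs


def simulate(spec: MotifSpec, u: Dose | float, horizon: float,
             solver_options: SolverOptions | None = None) -> Trajectory:
    """Integrate the motif ODE plus the quadrature state z' = y.

    Raises :class:`SimulationError` on solver failure or if the state dips
    below -1e-9 (the models are positivity-preserving analytically, so a
    larger excursion indicates an integration-quality problem).
    """
    opts = solver_options or SolverOptions()
    uu = u.u if isinstance(u, Dose) else float(u)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t_eval = np.linspace(0.0, horizon, opts.n_points)
    sol = solve_ivp(_augmented_rhs(spec, uu), (0.0, horizon),
                    [spec.x0, spec.y0, 0.0], t_eval=t_eval,
                    **opts.ivp_kwargs())
    if not sol.success:
        raise SimulationError(
            f"solver failed for {spec.motif_id} at u={uu}: {sol.message}")
    x, y, z = sol.y
    if min(x.min(), y.min()) < -1e-9:
        raise SimulationError(
            f"negative state excursion for {spec.motif_id} at u={uu}: "
            f"min(x)={x.min():.3e}, min(y)={y.min():.3e}")
    return Trajectory(times=sol.t, x_values=x,
                      y_values=np.maximum(y, 0.0), z_values=z)


def response_curve(spec: MotifSpec, u_grid, horizon: float,
                   kind: str = "cDR",
                   solver_options: SolverOptions | None = None
                   ) -> ResponseCurve:
    """DR or cDR values over a dose grid at fixed horizon."""
    u_grid = np.asarray(u_grid, dtype=float)
    values = np.empty_like(u_grid)
    for i, u in enumerate(u_grid):
        try:
            traj = simulate(spec, u, horizon, solver_options)
        except SimulationError as exc:
            raise SimulationError(f"dose u={u}: {exc}") from exc
        values[i] = traj.y_values[-1] if kind == "DR" else traj.cdr
    meta = {"motif": spec.motif_id,
            "params": {"alpha": spec.alpha, "beta": spec.beta,
                       "gamma": spec.gamma, "delta": spec.delta,
                       "K": spec.K, "x0": spec.x0, "y0": spec.y0}}
    return ResponseCurve(kind=kind, horizon_T=horizon, u_grid=u_grid,
                         values=values, metadata=meta)


def _state_jacobian(spec: MotifSpec, u: float, x: float, y: float):
    """Jacobian wrt (x, y) and the partial derivative of the RHS wrt u."""
    a, b, g, d, K = spec.alpha, spec.beta, spec.gamma, spec.delta, spec.K
    if spec.motif_id == "IFFL1":
        J = ((-d, 0.0), (-g * y, -g * x))
        fu = (a, b)
    elif spec.motif_id == "IFFL2":
        J = ((-d, 0.0), (-b * u / (K + x) ** 2, -g))
        fu = (a, b / (K + x))
    else:  # IFB
        J = ((a * y - d, a * x), (-b * u / (K + x) ** 2, -g))
        fu = (0.0, b / (K + x))
    return J, fu


def sensitivity(spec: MotifSpec, u: Dose | float, horizon: float,
                solver_options: SolverOptions | None = None
                ) -> SensitivityTrajectory:
    """Forward variational sensitivities of the state with respect to u.

    Integrates the variational ODE s' = J(x,y) s + ∂f/∂u jointly with the
    state from zero initial sensitivity (the initial condition does not
    depend on the dose), plus the quadrature state (∂z/∂u)' = ∂y/∂u.
    """
    opts = solver_options or SolverOptions()
    uu = u.u if isinstance(u, Dose) else float(u)

    def rhs(t, state):
        x, y, sx, sy, sz = state
        dx, dy = evaluate_rhs(spec, uu, (x, y))
        J, fu = _state_jacobian(spec, uu, x, y)
        dsx = J[0][0] * sx + J[0][1] * sy + fu[0]
        dsy = J[1][0] * sx + J[1][1] * sy + fu[1]
        return (dx, dy, dsx, dsy, sy)

    t_eval = np.linspace(0.0, horizon, opts.n_points)
    sol = solve_ivp(rhs, (0.0, horizon),
                    [spec.x0, spec.y0, 0.0, 0.0, 0.0],
                    t_eval=t_eval, **opts.ivp_kwargs())
    if not sol.success:
        raise SimulationError(
            f"sensitivity solver failed for {spec.motif_id} at u={uu}: "
            f"{sol.message}")
    return SensitivityTrajectory(times=sol.t, du_x=sol.y[2],
                                 du_y=sol.y[3], du_z=sol.y[4])


def check_monotone(curve: ResponseCurve, rel_tol: float = 1e-6,
                   abs_tol: float = 0.0) -> MonotonicityVerdict:
    """Flag adjacent-dose decreases beyond ``rel_tol`` of the curve range.

    A decrease must exceed rel_tol * (max - min) + abs_tol to count as a
    violation, separating genuine non-monotonicity from solver noise.
    ``abs_tol`` guards the degenerate case of a near-flat (fully adapted)
    curve whose range is itself at the level of integration error.
    """
    v = np.asarray(curve.values, dtype=float)
    if len(v) < 2:
        return MonotonicityVerdict(True, [], 0.0)
    scale = float(v.max() - v.min())
    threshold = rel_tol * scale + abs_tol
    diffs = np.diff(v)
    bad = np.where(diffs < -threshold)[0]
    violations = [(int(i), int(i) + 1) for i in bad]
    max_decrease = float(-diffs.min()) if diffs.min() < 0 else 0.0
    return MonotonicityVerdict(len(violations) == 0, violations, max_decrease)


def fcd_deviation(spec: MotifSpec, u: Dose | float, scale_factor: float,
                  horizon: float,
                  solver_options: SolverOptions | None = None) -> float:
    """Fold-change-detection test: sup_t |y(t; p*u, p*x0) - y(t; u, x0)|.

    IFFL2 and IFB with K=0 are scale-invariant (the rescaling of u and x
    cancels in the output equation), so the deviation vanishes to solver
    tolerance; IFFL1 admits no such symmetry.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    uu = u.u if isinstance(u, Dose) else float(u)
    base = simulate(spec, uu, horizon, solver_options)
    scaled_spec = spec.with_initial(x0=scale_factor * spec.x0)
    scaled = simulate(scaled_spec, scale_factor * uu, horizon, solver_options)
    return float(np.max(np.abs(scaled.y_values - base.y_values)))


def monotone_embedding_check(spec: MotifSpec, u1: float, u2: float,
                             horizon: float,
                             solver_options: SolverOptions | None = None,
                             slack: float = 1e-9) -> bool:
    """Trajectory-ordering check for the monotone embedding of IFFL2.

    Embeds IFFL2 into the extended system (u, x, p, y) with p = u/(K+x)::

        u' = 0,  x' = alpha*u - delta*x,
        p' = p*(delta*x/(K+x) - alpha*p),  y' = beta*p - gamma*y

    whose off-diagonal Jacobian entries are all non-negative, so the flow
    preserves the componentwise order.  Simulates both doses from the same
    (x0, y0) and verifies componentwise ordering at all grid times.
    """
    if spec.motif_id != "IFFL2":
        raise MotifError("monotone embedding is defined for IFFL2 only")
    if u1 > u2:
        raise ValueError("require u1 <= u2")
    opts = solver_options or SolverOptions()
    a, b, g, d, K = spec.alpha, spec.beta, spec.gamma, spec.delta, spec.K

    def rhs(t, s):
        u, x, p, y = s
        return (0.0,
                a * u - d * x,
                p * (d * x / (K + x) - a * p),
                b * p - g * y)

    t_eval = np.linspace(0.0, horizon, opts.n_points)
    sols = []
    for u in (u1, u2):
        p0 = u / (K + spec.x0)
        sol = solve_ivp(rhs, (0.0, horizon), [u, spec.x0, p0, spec.y0],
                        t_eval=t_eval, **opts.ivp_kwargs())
        if not sol.success:
            raise SimulationError(
                f"embedding solver failed at u={u}: {sol.message}")
        sols.append(sol.y)
    lo, hi = sols
    return bool(np.all(hi >= lo - slack))
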