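"""The three paradigmatic two-species adaptation motifs.

Each motif couples a controller species ``x`` to an output species ``y``
under a constant input (dose) ``u``:

* **IFFL1** — incoherent feedforward loop with degradation enhancement::

      dx/dt = alpha*u - delta*x
      dy/dt = beta*u  - gamma*x*y

* **IFFL2** — incoherent feedforward loop with production inhibition::

      dx/dt = alpha*u - delta*x
      dy/dt = beta*u/(K + x) - gamma*y

* **IFB** — nonlinear integral feedback::

      dx/dt = x*(alpha*y - delta)
      dy/dt = beta*u/(K + x) - gamma*y

All rate constants are strictly positive and ``K >= 0``.  When ``K = 0``
each motif adapts perfectly: the output converges to a steady value that
does not depend on the dose (beta*delta/(gamma*alpha) for the IFFLs with
K=0, delta/alpha for IFB).

This module holds the model definitions, exact steady states, and the
rescalings of IFFL1 and IFB (K=0) to parameter-free normalized coordinates
used by the closed-form and error-system analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO

import yaml

__all__ = [
    "MOTIF_IDS",
    "MotifSpec",
    "NormalizedProblem",
    "Dose",
    "evaluate_rhs",
    "steady_states",
    "normalize",
]

MOTIF_IDS = ("IFFL1", "IFFL2", "IFB")


class MotifError(ValueError):
    """Invalid motif configuration or state."""


def _adapted_y0(motif_id: str, alpha: float, beta: float, gamma: float,
                delta: float) -> float:
    # Adapted (dose-independent) output value used as the default initial
    # condition; for IFFL2 the convention is the same K=0 adapted value.
    if motif_id in ("IFFL1", "IFFL2"):
        return beta * delta / (gamma * alpha)
    return delta / alpha


@dataclass(frozen=True)
class Dose:
    """A constant, strictly positive input level."""

    u: float

    def __post_init__(self) -> None:
        if not self.u > 0:
            raise MotifError(f"dose must be positive, got u={self.u}")


@dataclass(frozen=True)
class MotifSpec:
    """Motif identity, rate constants and initial state.

    ``y0=None`` selects the adapted value (the convention under which the
    cDR monotonicity results hold): beta*delta/(gamma*alpha) for IFFL1 and
    IFFL2, delta/alpha for IFB.
    """

    motif_id: str
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    K: float = 0.0
    x0: float = 1.0
    y0: float | None = None

    def __post_init__(self) -> None:
        if self.motif_id not in MOTIF_IDS:
            raise MotifError(f"unknown motif_id {self.motif_id!r}; "
                             f"expected one of {MOTIF_IDS}")
        for name in ("alpha", "beta", "gamma", "delta"):
            if not getattr(self, name) > 0:
                raise MotifError(f"{name} must be strictly positive")
        if self.K < 0:
            raise MotifError("K must be non-negative")
        if self.x0 < 0:
            raise MotifError("x0 must be non-negative")
        if self._divides_by_x and self.x0 <= 0:
            raise MotifError(
                f"{self.motif_id} with K={self.K} requires x0 > 0 "
                "(the output equation divides by K + x)")
        if self.y0 is None:
            object.__setattr__(
                self, "y0",
                _adapted_y0(self.motif_id, self.alpha, self.beta,
                            self.gamma, self.delta))
        elif self.y0 < 0:
            raise MotifError("y0 must be non-negative")

    @property
    def _divides_by_x(self) -> bool:
        return self.motif_id == "IFB" or (self.motif_id == "IFFL2"
                                          and self.K == 0)

    def with_initial(self, x0: float | None = None,
                     y0: float | None = None) -> "MotifSpec":
        """Copy of the spec with a replaced initial state."""
        kwargs = {}
        if x0 is not None:
            kwargs["x0"] = x0
        if y0 is not None:
            kwargs["y0"] = y0
        return replace(self, **kwargs)

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self, stream: IO[str] | None = None) -> str | None:
        payload = {
            "motif": self.motif_id,
            "alpha": float(self.alpha), "beta": float(self.beta),
            "gamma": float(self.gamma), "delta": float(self.delta),
            "K": float(self.K), "x0": float(self.x0), "y0": float(self.y0),
        }
        return yaml.safe_dump(payload, stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, source: str | IO[str] | Path) -> "MotifSpec":
        if isinstance(source, Path):
            source = source.read_text()
        payload = yaml.safe_load(source)
        return cls(motif_id=payload["motif"],
                   alpha=payload.get("alpha", 1.0),
                   beta=payload.get("beta", 1.0),
                   gamma=payload.get("gamma", 1.0),
                   delta=payload.get("delta", 1.0),
                   K=payload.get("K", 0.0),
                   x0=payload.get("x0", 1.0),
                   y0=payload.get("y0"))


@dataclass(frozen=True)
class NormalizedProblem:
    """Parameter-free form of IFFL1 or IFB (K=0).

    IFFL1 normalizes to ``x' = -x + u_hat, y' = -x*y + u_hat`` with
    ``y(0) = 1``; IFB (K=0) normalizes to ``x' = x*(y - p),
    y' = u_hat/x - y`` with ``y(0) = p``.  ``time_scale`` maps one unit of
    normalized time to ``time_scale`` units of original time, and the state
    scales invert the normalization of x and y.
    """

    motif_id: str
    u_hat: float
    x0_hat: float
    y0_hat: float
    time_scale: float
    x_scale: float          # x_hat = x_scale * x
    y_scale: float          # y_hat = y_scale * y
    p: float | None = None  # IFB set-point delta/gamma

    def to_original_y(self, y_hat: float) -> float:
        return y_hat / self.y_scale

    def to_original_x(self, x_hat: float) -> float:
        return x_hat / self.x_scale


def evaluate_rhs(spec: MotifSpec, u: Dose | float,
                 state: tuple[float, float]) -> tuple[float, float]:
    """Right-hand side (dx/dt, dy/dt) of the motif ODEs at ``state``."""
    uu = u.u if isinstance(u, Dose) else float(u)
    x, y = state
    if spec.motif_id == "IFFL1":
        return (spec.alpha * uu - spec.delta * x,
                spec.beta * uu - spec.gamma * x * y)
    if spec.K + x <= 0:
        raise MotifError(
            f"invalid state for {spec.motif_id}: K + x = {spec.K + x} <= 0")
    if spec.motif_id == "IFFL2":
        return (spec.alpha * uu - spec.delta * x,
                spec.beta * uu / (spec.K + x) - spec.gamma * y)
    # IFB
    return (x * (spec.alpha * y - spec.delta),
            spec.beta * uu / (spec.K + x) - spec.gamma * y)


def steady_states(spec: MotifSpec, u: Dose | float) -> list[tuple[float, float]]:
    """Exact fixed points of the motif at constant dose ``u``.

    IFFL1 and IFFL2 have a single fixed point.  IFB has a boundary point
    (0, beta*u/(gamma*K)) whenever K > 0, plus the interior point
    (alpha*beta*u/(gamma*delta) - K, delta/alpha) when that x is positive.
    """
    uu = u.u if isinstance(u, Dose) else float(u)
    if uu <= 0:
        raise MotifError("steady states are defined for u > 0")
    a, b, g, d, K = spec.alpha, spec.beta, spec.gamma, spec.delta, spec.K
    if spec.motif_id == "IFFL1":
        return [(a * uu / d, b * d / (g * a))]
    if spec.motif_id == "IFFL2":
        return [(a * uu / d, b * uu * d / (g * (d * K + a * uu)))]
    points: list[tuple[float, float]] = []
    if K > 0:
        points.append((0.0, b * uu / (g * K)))
    x_int = a * b * uu / (g * d) - K
    if x_int > 0:
        points.append((x_int, d / a))
    return points


def normalize(spec: MotifSpec, u: Dose | float) -> NormalizedProblem:
    """Rescale IFFL1 or IFB (K=0) to its parameter-free form.

    IFFL1: time is scaled by delta, x by gamma/delta and y by
    gamma*alpha/(delta*beta), giving ``u_hat = (gamma*alpha/delta**2)*u``.
    (The y scale is fixed by requiring y_hat(0)=1 at the adapted initial
    output beta*delta/(gamma*alpha) and by consistency of the normalized
    ODE y' = -x*y + u_hat.)

    IFB with K=0: time is scaled by gamma, y by alpha/gamma, x unchanged,
    giving ``u_hat = (alpha*beta/gamma**2)*u`` and set-point
    ``p = delta/gamma``.
    """
    uu = u.u if isinstance(u, Dose) else float(u)
    a, b, g, d = spec.alpha, spec.beta, spec.gamma, spec.delta
    if spec.motif_id == "IFFL1":
        x_scale = g / d
        y_scale = g * a / (d * b)
        return NormalizedProblem(
            motif_id="IFFL1",
            u_hat=(g * a / d ** 2) * uu,
            x0_hat=x_scale * spec.x0,
            y0_hat=y_scale * spec.y0,
            time_scale=1.0 / d,
            x_scale=x_scale,
            y_scale=y_scale,
        )
    if spec.motif_id == "IFB":
        if spec.K != 0:
            raise MotifError("IFB normalization requires K = 0")
        y_scale = a / g
        return NormalizedProblem(
            motif_id="IFB",
            u_hat=(a * b / g ** 2) * uu,
            x0_hat=spec.x0,
            y0_hat=y_scale * spec.y0,
            time_scale=1.0 / g,
            x_scale=1.0,
            y_scale=y_scale,
            p=d / g,
        )
    raise MotifError(f"no normalization is defined for {spec.motif_id}")
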