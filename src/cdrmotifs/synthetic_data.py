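"""Synthetic cumulative-assay tables from motif simulations.

Emulates the structure of a cytokine-secretion time course: a panel of
log-spaced doses, hourly sampling (t = 1..8 h by default), a few
biological replicates, and positive heteroscedastic measurement noise.
The noiseless signal is the simulated running integral z(t) = ∫₀ᵗ y of the
chosen motif; each measurement applies mean-corrected multiplicative
lognormal noise plus an optional additive baseline, and a running-maximum
pass keeps every series non-decreasing (secreted totals cannot shrink —
a generator artifact, not a property of the noise model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
import yaml

from .empirical import TABLE_COLUMNS, CumulativeTable
from .motifs import MotifSpec
from .response import SimulationError, SolverOptions, simulate

__all__ = ["AssayDesign", "generate_table"]


def _default_doses() -> tuple[float, ...]:
    return tuple(np.logspace(-1, 2, 8))


def _default_times() -> tuple[float, ...]:
    return tuple(float(t) for t in range(1, 9))


@dataclass(frozen=True)
class AssayDesign:
    """Sampling design and noise model for a synthetic assay.

    noise_cv is the coefficient of variation of the multiplicative
    lognormal noise; the lognormal is mean-corrected so the expected
    measurement equals the noiseless cumulative signal.
    """

    doses: tuple[float, ...] = field(default_factory=_default_doses)
    times: tuple[float, ...] = field(default_factory=_default_times)
    replicates: int = 3
    noise_cv: float = 0.1
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if any(t <= 0 for t in self.times):
            raise ValueError("sampling times must be positive")
        if sorted(self.times) != list(self.times):
            raise ValueError("sampling times must be increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0 or self.baseline < 0:
            raise ValueError("noise_cv and baseline must be non-negative")

    def to_yaml(self, stream: IO[str] | None = None) -> str | None:
        payload = {"doses": list(map(float, self.doses)),
                   "times": list(map(float, self.times)),
                   "replicates": self.replicates,
                   "noise_cv": self.noise_cv,
                   "baseline": self.baseline,
                   "seed": self.seed}
        return yaml.safe_dump(payload, stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, source: str | IO[str] | Path) -> "AssayDesign":
        if isinstance(source, Path):
            source = source.read_text()
        payload = yaml.safe_load(source)
        return cls(doses=tuple(payload["doses"]),
                   times=tuple(payload["times"]),
                   replicates=payload.get("replicates", 3),
                   noise_cv=payload.get("noise_cv", 0.1),
                   baseline=payload.get("baseline", 0.0),
                   seed=payload.get("seed", 0))


def generate_table(spec: MotifSpec, design: AssayDesign,
                   solver_options: SolverOptions | None = None
                   ) -> CumulativeTable:
    """Simulate the motif per dose and emit a noisy cumulative table.

    For sigma derived from noise_cv, each cell is
    ``baseline + z(t) * exp(eps)`` with
    ``eps ~ Normal(-sigma**2/2, sigma)`` so that E[measurement] =
    baseline + z(t); the lognormal CV equals sqrt(exp(sigma²) - 1) ≈
    noise_cv for small values.  Deterministic per design.seed.
    """
    rng = np.random.default_rng(design.seed)
    sigma = design.noise_cv
    horizon = design.times[-1]
    records = []
    for dose in design.doses:
        try:
            traj = simulate(spec, dose, horizon, solver_options)
        except SimulationError as exc:
            raise SimulationError(f"dose {dose}: {exc}") from exc
        z = np.interp(design.times, traj.times, traj.z_values)
        for rep in range(1, design.replicates + 1):
            if sigma > 0:
                eps = rng.normal(-sigma ** 2 / 2.0, sigma, size=len(z))
                noisy = design.baseline + z * np.exp(eps)
            else:
                noisy = design.baseline + z
            noisy = np.maximum.accumulate(noisy)  # totals cannot decrease
            for t, value in zip(design.times, noisy):
                records.append((float(dose), float(t), rep, float(value)))
    frame = pd.DataFrame(records, columns=TABLE_COLUMNS)
    return CumulativeTable(frame)
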