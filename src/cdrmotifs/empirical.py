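"""Response estimation from cumulative dose-time tables.

Cytokine-secretion assays measure the *cumulative* output
z(t) = ∫₀ᵗ y(s) ds per dose and replicate (e.g. TNF-α accumulated in the
culture medium at hourly time points).  This module recovers the response
rate y(t) by first differences, imposing y(0) = 0, and summarizes
adaptation: if the motif adapts, the late-time rate estimates collapse to
a common value across doses.

Tables are long-format pandas DataFrames with columns
``dose, time, replicate, cumulative``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_COLUMNS",
    "CumulativeTable",
    "RateEstimate",
    "read_table",
    "write_table",
    "estimate_rates",
    "average_replicates",
    "adaptation_summary",
]

TABLE_COLUMNS = ["dose", "time", "replicate", "cumulative"]


class TableError(ValueError):
    """Malformed cumulative table."""


@dataclass(frozen=True)
class CumulativeTable:
    """Long-format dose x time x replicate cumulative measurements."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableError(f"table is missing columns {missing}")
        dup = self.data.duplicated(subset=["dose", "replicate", "time"])
        if dup.any():
            keys = self.data.loc[dup, ["dose", "replicate", "time"]]
            raise TableError(
                f"duplicate (dose, replicate, time) entries:\n{keys}")
        for (dose, rep), grp in self.data.groupby(["dose", "replicate"]):
            t = grp["time"].to_numpy()
            if not np.all(np.diff(np.sort(t)) > 0):
                raise TableError(
                    f"non-increasing times for dose={dose}, "
                    f"replicate={rep}")

    def series(self):
        """Iterate (dose, replicate, times, cumulative) per series,
        with the (t=0, z=0) origin prepended when absent."""
        for (dose, rep), grp in self.data.groupby(["dose", "replicate"]):
            grp = grp.sort_values("time")
            t = grp["time"].to_numpy(dtype=float)
            z = grp["cumulative"].to_numpy(dtype=float)
            if t[0] > 0:
                t = np.concatenate([[0.0], t])
                z = np.concatenate([[0.0], z])
            yield dose, rep, t, z

    def to_csv(self, path: str | Path) -> None:
        self.data[TABLE_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class RateEstimate:
    """First-difference estimate of y(t) for one (dose, replicate) series.

    ``y_est[0] = 0`` by convention (no secretion before stimulation);
    subsequent values are assigned to the interval endpoint per
    ``convention`` ("right", the measurement time, or "midpoint").
    """

    dose: float
    replicate: object
    times: np.ndarray
    y_est: np.ndarray
    has_negative: bool


def read_table(path: str | Path) -> CumulativeTable:
    return CumulativeTable(pd.read_csv(path))


def write_table(table: CumulativeTable, path: str | Path) -> None:
    table.to_csv(path)


def estimate_rates(table: CumulativeTable, convention: str = "right",
                   baseline_subtract: bool = False) -> list[RateEstimate]:
    """Estimate y(t) per series by first differences of the cumulative z.

    y_est(t_i) = (z(t_i) - z(t_{i-1})) / (t_i - t_{i-1}), with y(0) = 0.
    Negative estimates (noise / baseline artifacts in real assays) are
    retained and flagged; ``baseline_subtract`` removes the per-series
    minimum rate instead.
    """
    if convention not in ("right", "midpoint"):
        raise ValueError("convention must be 'right' or 'midpoint'")
    out: list[RateEstimate] = []
    for dose, rep, t, z in table.series():
        if len(t) < 2:
            raise TableError(
                f"series dose={dose}, replicate={rep} needs >= 2 points")
        rates = np.diff(z) / np.diff(t)
        has_negative = bool(np.any(rates < 0))
        if baseline_subtract:
            rates = rates - rates.min()
        if convention == "right":
            times = t
            y = np.concatenate([[0.0], rates])
        else:
            times = np.concatenate([[t[0]], 0.5 * (t[:-1] + t[1:])])
            y = np.concatenate([[0.0], rates])
        out.append(RateEstimate(dose=float(dose), replicate=rep,
                                times=times, y_est=y,
                                has_negative=has_negative))
    return out


def average_replicates(table: CumulativeTable) -> CumulativeTable:
    """Average the cumulative values across replicates per (dose, time).

    All replicates must share the dose and time grids.
    """
    grids = {}
    for (dose, rep), grp in table.data.groupby(["dose", "replicate"]):
        grids[(dose, rep)] = tuple(sorted(grp["time"]))
    by_dose: dict[object, set] = {}
    for (dose, _rep), grid in grids.items():
        by_dose.setdefault(dose, set()).add(grid)
    bad = [dose for dose, gs in by_dose.items() if len(gs) > 1]
    if bad:
        raise TableError(f"replicate time grids differ for doses {bad}")
    mean = (table.data.groupby(["dose", "time"], as_index=False)
            ["cumulative"].mean())
    mean["replicate"] = "mean"
    return CumulativeTable(mean[TABLE_COLUMNS])


def adaptation_summary(rates: list[RateEstimate],
                       tail_fraction: float = 0.25) -> dict:
    """Tail-mean rate per dose and the cross-dose spread.

    Averages y_est over the final ``tail_fraction`` of time points of each
    series (pooling replicates per dose) and reports the maximum pairwise
    difference of those tail means across doses.  A small spread relative
    to the peak response indicates adaptation: the late response no longer
    depends on the dose.
    """
    if not rates:
        raise ValueError("rates must be non-empty")
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    tail_means: dict[float, list[float]] = {}
    peak = 0.0
    for r in rates:
        n = len(r.y_est)
        k = max(1, int(np.ceil(tail_fraction * (n - 1))))
        tail_means.setdefault(r.dose, []).append(float(np.mean(r.y_est[-k:])))
        peak = max(peak, float(np.max(np.abs(r.y_est))))
    per_dose = {dose: float(np.mean(v)) for dose, v in tail_means.items()}
    vals = list(per_dose.values())
    spread = float(max(vals) - min(vals)) if len(vals) > 1 else 0.0
    return {"tail_mean_by_dose": per_dose,
            "spread": spread,
            "peak_response": peak,
            "relative_spread": spread / peak if peak > 0 else 0.0}
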