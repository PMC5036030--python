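"""Occupancy summary statistics and the per-cell occurrence surface.

Produces the standard summary of a regional occupancy analysis: the naïve
occupancy estimate ``x / M`` (sites with at least one detection, uncorrected
for imperfect detection), the mean model-averaged occupancy over surveyed
sites (ψ̂), and regional means of model-averaged occupancy (ψ̄) and
detection (p̄) over a prediction grid of cells, plus the estimated
false-positive rate when misclassification models enter the average.  The
grid export is the numeric content behind an occurrence map: one row per
cell with covariates and averaged probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OccupancySummary", "naive_occupancy", "summarize", "export_grid"]


@dataclass(frozen=True)
class OccupancySummary:
    """Region-level occupancy and detection summary."""

    x: int  # sites with >=1 detection
    n_sites: int
    naive_psi: float  # x / n_sites
    psi_hat_sites: float  # mean averaged psi over surveyed sites
    psi_bar_region: float  # mean averaged psi over grid cells
    p_bar_region: float  # mean averaged p over grid cells
    p10_hat: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n_sites:
            raise ValueError("x must lie in [0, n_sites]")
        for name in ("naive_psi", "psi_hat_sites", "psi_bar_region", "p_bar_region"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")

    def to_frame(self) -> pd.DataFrame:
        row = {
            "x": self.x,
            "n_sites": self.n_sites,
            "naive_psi": self.naive_psi,
            "psi_hat_sites": self.psi_hat_sites,
            "psi_bar_region": self.psi_bar_region,
            "p_bar_region": self.p_bar_region,
            "p10_hat": np.nan if self.p10_hat is None else self.p10_hat,
        }
        return pd.DataFrame([row])


def naive_occupancy(detections) -> tuple[int, float]:
    """Count of sites with at least one detection and the naïve ψ = x/M.

    A site with any 1 among its non-missing replicates counts as detected;
    missing entries are ignored.
    """
    y = np.asarray(pd.DataFrame(detections).to_numpy(), dtype=float)
    if y.size == 0:
        raise ValueError("empty detection matrix")
    detected = np.nansum(y, axis=1) > 0
    x = int(detected.sum())
    return x, x / y.shape[0]


def summarize(
    site_predictions: pd.DataFrame,
    grid_predictions: pd.DataFrame,
    detections,
    p10: float | None = None,
) -> OccupancySummary:
    """Assemble the region summary from averaged predictions and raw data.

    ``site_predictions`` and ``grid_predictions`` carry ``psi_avg`` (and the
    grid additionally ``p_avg``) as produced by model averaging; ``p10`` is
    reported only when misclassification models contributed.
    """
    site_psi = np.asarray(site_predictions["psi_avg"], dtype=float)
    grid_psi = np.asarray(grid_predictions["psi_avg"], dtype=float)
    grid_p = np.asarray(grid_predictions["p_avg"], dtype=float)
    if site_psi.size == 0 or grid_psi.size == 0:
        raise ValueError("prediction vectors must be nonempty")
    y = pd.DataFrame(detections)
    if len(y) != site_psi.size:
        raise ValueError("detections and site predictions differ in length")
    x, naive = naive_occupancy(y)
    return OccupancySummary(
        x=x,
        n_sites=len(y),
        naive_psi=naive,
        psi_hat_sites=float(site_psi.mean()),
        psi_bar_region=float(grid_psi.mean()),
        p_bar_region=float(grid_p.mean()),
        p10_hat=None if p10 is None else float(p10),
    )


GRID_KEY_COLUMNS = ("cell_id", "easting", "northing")


def export_grid(grid: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell prediction grid as CSV, sorted by ``cell_id``.

    Column order: ``cell_id[,easting,northing],<covariates...>,psi_avg,p_avg``;
    probabilities at 6 decimal places.
    """
    grid = pd.DataFrame(grid)
    if "cell_id" not in grid.columns:
        grid = grid.reset_index()
    required = {"cell_id", "psi_avg", "p_avg"}
    missing = required - set(grid.columns)
    if missing:
        raise ValueError(f"grid lacks column(s): {', '.join(sorted(missing))}")
    keys = [c for c in GRID_KEY_COLUMNS if c in grid.columns]
    others = [c for c in grid.columns if c not in keys and c not in ("psi_avg", "p_avg")]
    ordered = grid[keys + others + ["psi_avg", "p_avg"]].sort_values("cell_id")
    ordered.to_csv(path, index=False, float_format="%.6f")
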