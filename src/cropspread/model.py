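"""Arrival-time prediction and RMSE fitness for a cost vector.

The front leaves the origin at ``t0`` (cal BP) and advances at local speed
``v0 / cost``; a site at accumulated weighted distance D km is reached at

    t = t0 − D / v0            (cal BP decreases forward in time)

A cost vector is scored by the root mean square error (years) between these
predicted arrival times and the observed median calibrated ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import COST_FLOOR, ClassRaster, accumulate_cost, sample_surface


@dataclass
class SimulationConfig:
    """Origin, start date and base front speed."""

    origin_cell: tuple[int, int]
    t0: float  # cal BP at the origin
    v0: float = 1.0  # km / yr
    origin_site_id: str = ""

    def __post_init__(self) -> None:
        if not self.v0 > 0:
            raise ValueError("base speed v0 must be positive")
        if not self.t0 > 0:
            raise ValueError("origin date t0 must be positive (cal BP)")


@dataclass
class FitScore:
    rmse: float
    n_sites_used: int
    n_sites_excluded: int
    residuals: pd.DataFrame  # site, D_km, predicted_cal_bp, observed_cal_bp, residual


def predict_arrival(d_km: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Arrival date (cal BP) at accumulated distance ``d_km``."""
    d_km = np.asarray(d_km, dtype=float)
    if np.any(d_km < 0):
        raise ValueError("accumulated distance must be non-negative")
    t = config.t0 - d_km / config.v0
    n_future = int(np.sum(t <= 0))
    if n_future:
        warnings.warn(
            f"{n_future} predicted arrival(s) beyond the present (cal BP <= 0); "
            "kept with their residuals",
            stacklevel=2,
        )
    return t


def speeds_from_costs(costs: np.ndarray, v0: float = 1.0) -> np.ndarray:
    """Per-class local front speed (km/yr): v = v0 / cost.

    Cost 1 is neutral; cost 0.5 doubles the local speed, cost 2 halves it.
    """
    costs = np.asarray(costs, dtype=float)
    if np.any(costs < COST_FLOOR):
        raise ValueError(f"costs must be >= {COST_FLOOR}")
    return v0 / costs


def score(
    costs: np.ndarray,
    raster: ClassRaster,
    sites: pd.DataFrame,
    config: SimulationConfig,
) -> FitScore:
    """RMSE (years) of predicted vs observed arrival over usable sites.

    ``sites`` needs columns x, y (km, raster CRS) and observed_cal_bp.  Sites
    outside the extent or on unreachable cells are excluded and counted,
    never imputed.
    """
    surface = accumulate_cost(raster, costs, config.origin_cell)
    sampled = sample_surface(surface, sites)
    return score_sampled(sampled, config)


def score_sampled(sampled: pd.DataFrame, config: SimulationConfig) -> FitScore:
    """Score from a frame already carrying D_km/D_status (see `score`)."""
    usable = sampled[sampled["D_status"] == "ok"].copy()
    n_excluded = len(sampled) - len(usable)
    if len(usable) == 0:
        raise ValueError("no usable sites: all outside extent or unreachable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # beyond-present warning handled by caller
        usable["predicted_cal_bp"] = predict_arrival(usable["D_km"].to_numpy(), config)
    usable["residual"] = usable["predicted_cal_bp"] - usable["observed_cal_bp"]
    rmse = float(np.sqrt(np.mean(usable["residual"].to_numpy() ** 2)))
    cols = [c for c in ("site", "D_km", "predicted_cal_bp", "observed_cal_bp", "residual")
            if c in usable.columns]
    return FitScore(
        rmse=rmse,
        n_sites_used=len(usable),
        n_sites_excluded=n_excluded,
        residuals=usable[cols].reset_index(drop=True),
    )


def speed_raster(raster: ClassRaster, costs: np.ndarray, v0: float = 1.0) -> np.ndarray:
    """Per-cell local speed map (km/yr); NaN on nodata."""
    speeds = speeds_from_costs(costs, v0)
    out = np.full(raster.classes.shape, np.nan)
    mask = raster.classes >= 0
    out[mask] = speeds[raster.classes[mask]]
    return out


def arrival_raster(surface_dist: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Arrival-time grid (cal BP); NaN where unreachable."""
    out = np.full(surface_dist.shape, np.nan)
    mask = np.isfinite(surface_dist)
    out[mask] = config.t0 - surface_dist[mask] / config.v0
    return out
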