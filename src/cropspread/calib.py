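"""Radiocarbon dates, calibration curves and median calibrated ages.

A determination (lab measurement ``age ± error`` in ¹⁴C yr BP) is calibrated
against a curve (cal BP grid, curve ¹⁴C age mu, curve 1σ) with the standard
Gaussian-combination likelihood

    prob(t) ∝ exp( −(age − mu(t))² / (2 (error² + σ_curve(t)²)) )

normalised over the curve support on a 1-calendar-year grid.  Each date is
summarised by the median of its calibrated distribution — the smallest grid
age at which the cumulative probability reaches 0.5 — which is the
observation the arrival-time model is fitted against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DATE_COLUMNS = [
    "site", "lab_code", "c14_age", "c14_error", "lon", "lat",
    "affiliation", "included", "exclusion_reason",
]

AGGREGATION_MODES = ("earliest_per_site", "all_dates")


class DateFormatError(ValueError):
    """Malformed radiocarbon date table."""


class CurveRangeError(ValueError):
    """Determination outside the calibration curve's support."""


@dataclass
class C14Determination:
    """One radiocarbon measurement with spatial and cultural metadata."""

    site_id: str
    lab_code: str
    age_rcybp: float
    error_rcybp: float
    lon: float
    lat: float
    affiliation: str = ""
    included: bool = True
    exclusion_reason: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.age_rcybp > 0:
            raise ValueError(f"{self.site_id}/{self.lab_code}: age must be > 0")
        if not self.error_rcybp > 0:
            raise ValueError(f"{self.site_id}/{self.lab_code}: error must be > 0")
        if not (-180 <= self.lon <= 180 and -90 <= self.lat <= 90):
            raise ValueError(f"{self.site_id}/{self.lab_code}: lon/lat out of range")


@dataclass
class CalCurve:
    """Calibration curve on an ascending cal BP grid."""

    cal_bp: np.ndarray
    mu: np.ndarray
    sigma_curve: np.ndarray
    name: str = "curve"

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma_curve = np.asarray(self.sigma_curve, dtype=float)
        if not (len(self.cal_bp) == len(self.mu) == len(self.sigma_curve)):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("cal_bp grid must be strictly increasing")
        if np.any(self.sigma_curve < 0):
            raise ValueError("curve sigma must be non-negative")


@dataclass
class CalibratedDensity:
    """Posterior over calendar age for one determination."""

    cal_bp: np.ndarray
    prob: np.ndarray
    median_cal_bp: float


def load_cal_curve(path: str | Path, name: str | None = None) -> CalCurve:
    """Read an IntCal-format CSV: comment lines start with '#', then columns
    cal BP, ¹⁴C age, error.  Descending rows (the distributed convention) are
    re-sorted ascending."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", header=None,
                     names=["cal_bp", "mu", "sigma"], usecols=[0, 1, 2])
    df = df.sort_values("cal_bp").reset_index(drop=True)
    return CalCurve(
        cal_bp=df["cal_bp"].to_numpy(),
        mu=df["mu"].to_numpy(),
        sigma_curve=df["sigma"].to_numpy(),
        name=name or path.stem,
    )


def load_dates(path: str | Path) -> list[C14Determination]:
    """Read a radiocarbon date table (CSV).

    Required columns: site, lab_code, c14_age, c14_error, lon, lat.  Optional:
    affiliation, included (default true), exclusion_reason.  Unknown columns
    are preserved per record in ``metadata``.  Rows violating invariants are
    rejected with row-indexed diagnostics.
    """
    df = pd.read_csv(path)
    required = ["site", "lab_code", "c14_age", "c14_error", "lon", "lat"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DateFormatError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in DATE_COLUMNS]

    records: list[C14Determination] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                C14Determination(
                    site_id=str(row["site"]),
                    lab_code=str(row["lab_code"]),
                    age_rcybp=float(row["c14_age"]),
                    error_rcybp=float(row["c14_error"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    affiliation=str(row.get("affiliation", "") or ""),
                    included=_parse_bool(row.get("included", True)),
                    exclusion_reason=str(row.get("exclusion_reason", "") or ""),
                    metadata={c: row[c] for c in extra_cols},
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise DateFormatError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors))
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("true", "t", "yes", "1"):
            return True
        if v in ("false", "f", "no", "0"):
            return False
        raise ValueError(f"cannot parse boolean {value!r}")
    if pd.isna(value):
        return True
    return bool(value)


def dates_to_frame(dates: list[C14Determination]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [d.site_id for d in dates],
            "lab_code": [d.lab_code for d in dates],
            "c14_age": [d.age_rcybp for d in dates],
            "c14_error": [d.error_rcybp for d in dates],
            "lon": [d.lon for d in dates],
            "lat": [d.lat for d in dates],
            "affiliation": [d.affiliation for d in dates],
            "included": [d.included for d in dates],
            "exclusion_reason": [d.exclusion_reason for d in dates],
        }
    )


def calibrate(det: C14Determination, curve: CalCurve, grid_step: float = 1.0) -> CalibratedDensity:
    """Calibrate one determination onto the curve's support.

    The density is evaluated on a ``grid_step``-year grid spanning the curve,
    normalised to sum to 1; the median is read off the cumulative sum.
    """
    span = 6.0 * (det.error_rcybp + float(np.max(curve.sigma_curve)))
    if det.age_rcybp + span < np.min(curve.mu) or det.age_rcybp - span > np.max(curve.mu):
        raise CurveRangeError(
            f"{det.site_id}/{det.lab_code}: ¹⁴C age {det.age_rcybp} outside the "
            f"support of curve '{curve.name}'"
        )
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + grid_step / 2, grid_step)
    mu = np.interp(grid, curve.cal_bp, curve.mu)
    sig = np.interp(grid, curve.cal_bp, curve.sigma_curve)
    var = det.error_rcybp**2 + sig**2
    log_p = -((det.age_rcybp - mu) ** 2) / (2.0 * var)
    prob = np.exp(log_p - log_p.max())
    total = prob.sum()
    if total == 0 or not np.isfinite(total):
        raise CurveRangeError(f"{det.site_id}/{det.lab_code}: degenerate calibration density")
    prob /= total
    cdf = np.cumsum(prob)
    median = float(grid[int(np.searchsorted(cdf, 0.5))])
    return CalibratedDensity(cal_bp=grid, prob=prob, median_cal_bp=median)


def median_per_site(
    dates: list[C14Determination], curve: CalCurve, mode: str = "earliest_per_site"
) -> pd.DataFrame:
    """Calibrate every included date and aggregate to site observations.

    ``earliest_per_site`` keeps, per site, the date with the largest median
    cal BP (the earliest attestation = the arrival of the crop package);
    ``all_dates`` emits one observation per included date.  Returns a frame
    with columns site, lon, lat, median_cal_bp, n_dates.
    """
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"mode must be one of {AGGREGATION_MODES}, got {mode!r}")
    excluded_sites = {d.site_id for d in dates if not d.included} - {
        d.site_id for d in dates if d.included
    }
    if excluded_sites:
        warnings.warn(
            f"{len(excluded_sites)} site(s) have no included dates and are dropped: "
            f"{sorted(excluded_sites)}",
            stacklevel=2,
        )
    rows = []
    for det in dates:
        if not det.included:
            continue
        dens = calibrate(det, curve)
        rows.append((det.site_id, det.lon, det.lat, dens.median_cal_bp))
    df = pd.DataFrame(rows, columns=["site", "lon", "lat", "median_cal_bp"])
    if mode == "all_dates":
        df["n_dates"] = 1
        return df.reset_index(drop=True)
    grouped = (
        df.sort_values(["site", "median_cal_bp"], ascending=[True, False])
        .groupby("site", as_index=False)
        .agg(lon=("lon", "first"), lat=("lat", "first"),
             median_cal_bp=("median_cal_bp", "max"), n_dates=("median_cal_bp", "size"))
    )
    return grouped
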