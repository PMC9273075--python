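"""Synthetic worlds with known terrain-class speeds, dated sites and a toy
calibration curve.

The generator emulates the structure of the real inputs — a banded
terrain-class raster traversed west→east, sites whose observed ages derive
from the arrival model plus dating noise, and an invertible calibration curve
so the full calibrate→median→fit path can be exercised — with every true
parameter known, making parameter recovery measurable.

Site arrival distances are computed with the networkx reference shortest path
(:mod:`cropspread.reference`), not the production Dijkstra kernel, so that
recovering the true speeds genuinely cross-checks the production code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calib import CalCurve
from .raster import (
    ClassRaster,
    GridTransform,
    write_class_raster,
    xy_to_lonlat,
)
from .reference import reference_distances

#: dates excluded from the published compilation (printed reasons); coordinates
#: are approximate stand-ins, as the published table of exclusions prints none.
EXCLUDED_DATES = [
    ("Aq Kupruk", "Hy-428", 7220, 100, 66.9, 36.1, "Pastoralism without evidence for the founder crops"),
    ("Mehrgarh", "Beta 1407", 7328, 290, 67.6, 29.4, "Still isolated"),
    ("Budihal", "PRL-1532", 7725, 210, 76.6, 16.3, "Pastoralism with local plant domestication (Ashmound Tradition)"),
    ("Hanumantaraopeta", "R-28680/34", 3167, 40, 79.3, 14.2, "Pastoralism with local plant domestication (Ashmound Tradition)"),
    ("Utnur", "BM-54", 4125, 150, 77.2, 16.6, "Pastoralism with local plant domestication (Ashmound Tradition)"),
    ("Watgal", "PRL-1575", 4350, 100, 76.4, 15.9, "Pastoralism with local plant domestication (Ashmound Tradition)"),
    ("Kodekal", "TF-748", 4415, 105, 76.8, 16.5, "Pastoralism with local plant domestication (Ashmound Tradition)"),
    ("Bagor", "TF-1011&1012", 5240, 80, 74.4, 25.4, "Mesolithic with domesticated animals"),
    ("Sannarachamma (Sanganakallu)", "R-28680/22", 5469, 35, 76.9, 15.1, "Pastoralism with local plant domestication (Ashmound Tradition)"),
]


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic dispersal world.

    Defaults mirror the desk-scale recovery design: a 100×200 grid of 20 km
    cells (≈ the real ~4000 km west–east extent), four terrain bands with
    true speeds spanning mountain-slow to tropical-fast, 60 dated sites and
    100 yr of dating noise.
    """

    n_rows: int = 100
    n_cols: int = 200
    cell_size: float = 20.0  # km
    band_widths: tuple[int, ...] = (50, 50, 50, 50)  # cols, west→east
    true_speeds: tuple[float, ...] = (0.4, 0.8, 1.5, 2.0)  # km/yr
    origin_cell: tuple[int, int] = (50, 0)
    t0: float = 10000.0  # cal BP at the origin
    v0: float = 1.0  # km/yr base speed
    n_sites: int = 60
    date_noise_sd: float = 100.0  # yr
    c14_error: float = 50.0  # yr, reported 1σ of synthetic determinations
    lon0: float = 38.0  # map x=0 to this longitude (equirectangular)
    lat0: float = 30.0  # map y=0 to this latitude
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.band_widths) != len(self.true_speeds):
            raise ValueError("band_widths and true_speeds must have equal length")
        if sum(self.band_widths) != self.n_cols:
            raise ValueError(
                f"band widths sum to {sum(self.band_widths)}, raster has {self.n_cols} cols"
            )
        if any(s <= 0 for s in self.true_speeds):
            raise ValueError("true speeds must be positive")
        if self.n_sites < len(self.true_speeds):
            raise ValueError("need at least one site per class: n_sites >= K")

    @property
    def n_classes(self) -> int:
        return len(self.true_speeds)

    @property
    def true_costs(self) -> np.ndarray:
        return self.v0 / np.asarray(self.true_speeds, dtype=float)


def make_banded_raster(spec: SyntheticSpec) -> ClassRaster:
    """Vertical bands of the K classes in order, west→east."""
    classes = np.zeros((spec.n_rows, spec.n_cols), dtype=np.int32)
    edges = np.cumsum((0,) + tuple(spec.band_widths))
    for k in range(spec.n_classes):
        classes[:, edges[k]:edges[k + 1]] = k
    transform = GridTransform(
        x_ll=0.0, y_ll=0.0, cell_size=spec.cell_size,
        n_rows=spec.n_rows, n_cols=spec.n_cols,
    )
    legend = [f"band_{k}" for k in range(spec.n_classes)]
    return ClassRaster(classes=classes, transform=transform,
                       legend=legend, raw_ids=list(range(spec.n_classes)))


def toy_cal_curve(max_cal_bp: float = 14000.0, wiggle: float = 20.0,
                  sigma: float = 10.0) -> CalCurve:
    """Invertible toy calibration curve: mu(t) = t + wiggle·sin(t/300).

    Monotonic (slope ≥ 1 − wiggle/300 > 0 for the default), so back-converting
    a calendar age to a ¹⁴C age and re-calibrating recovers it.
    """
    cal_bp = np.arange(0.0, max_cal_bp + 1, 5.0)
    mu = cal_bp + wiggle * np.sin(cal_bp / 300.0)
    return CalCurve(cal_bp=cal_bp, mu=mu,
                    sigma_curve=np.full_like(cal_bp, sigma), name="toy")


def simulate_sites(
    raster: ClassRaster,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    dist: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample dated sites from the true arrival model.

    Cells are drawn uniformly over the non-nodata grid (without replacement);
    observed ages are ``t0 − D/v0`` plus Gaussian dating noise, with D from
    the independent reference shortest path.  Returns a frame with columns
    site, row, col, x, y, lon, lat, class_id, D_true_km, true_cal_bp,
    observed_cal_bp.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if dist is None:
        dist = reference_distances(raster, spec.true_costs, spec.origin_cell)
    valid = np.argwhere((raster.classes >= 0) & np.isfinite(dist))
    if spec.n_sites > len(valid):
        raise ValueError(f"n_sites={spec.n_sites} exceeds {len(valid)} usable cells")
    pick = rng.choice(len(valid), size=spec.n_sites, replace=False)
    rows = valid[pick, 0]
    cols = valid[pick, 1]
    d = dist[rows, cols]
    true_t = spec.t0 - d / spec.v0
    observed = true_t + rng.normal(0.0, spec.date_noise_sd, size=spec.n_sites) \
        if spec.date_noise_sd > 0 else true_t.copy()
    xy = np.array([raster.transform.cell_center(r, c) for r, c in zip(rows, cols)])
    lon, lat = xy_to_lonlat(xy[:, 0], xy[:, 1], lon0=spec.lon0, lat0=spec.lat0)
    return pd.DataFrame(
        {
            "site": [f"S{i:03d}" for i in range(spec.n_sites)],
            "row": rows,
            "col": cols,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "lon": lon,
            "lat": lat,
            "class_id": raster.classes[rows, cols],
            "D_true_km": d,
            "true_cal_bp": true_t,
            "observed_cal_bp": observed,
        }
    )


def sites_to_c14_table(
    sites: pd.DataFrame, spec: SyntheticSpec, curve: CalCurve
) -> pd.DataFrame:
    """Back-convert observed calendar ages to ¹⁴C determinations.

    Each observed cal BP age is pushed through the (invertible) curve so that
    calibrating the resulting determination and taking the median recovers
    the observation, exercising the full pipeline end-to-end.  An ORIGIN row
    dated t0 anchors the dispersal start.
    """
    obs = sites["observed_cal_bp"].to_numpy()
    c14 = np.interp(obs, curve.cal_bp, curve.mu)
    frame = pd.DataFrame(
        {
            "site": sites["site"],
            "lab_code": [f"SYN-{i:03d}" for i in range(len(sites))],
            "c14_age": np.round(c14, 1),
            "c14_error": spec.c14_error,
            "lon": sites["lon"],
            "lat": sites["lat"],
            "affiliation": "synthetic",
            "included": True,
            "exclusion_reason": "",
        }
    )
    o_r, o_c = spec.origin_cell
    tr = GridTransform(0.0, 0.0, spec.cell_size, spec.n_rows, spec.n_cols)
    ox, oy = tr.cell_center(o_r, o_c)
    olon, olat = xy_to_lonlat(np.array([ox]), np.array([oy]),
                              lon0=spec.lon0, lat0=spec.lat0)
    origin_row = pd.DataFrame(
        {
            "site": ["ORIGIN"],
            "lab_code": ["SYN-ORIGIN"],
            "c14_age": [round(float(np.interp(spec.t0, curve.cal_bp, curve.mu)), 1)],
            "c14_error": [spec.c14_error],
            "lon": olon,
            "lat": olat,
            "affiliation": ["synthetic"],
            "included": [True],
            "exclusion_reason": [""],
        }
    )
    return pd.concat([origin_row, frame], ignore_index=True)


def make_archive_style_table(
    n_included: int = 143, seed: int = 0
) -> pd.DataFrame:
    """Synthetic stand-in for the published radiocarbon compilation.

    Generates ``n_included`` included determinations laid out along the
    southwest-Asia→India corridor, plus the real printed excluded dates
    (``EXCLUDED_DATES``) flagged ``included=False`` with their reasons.  Site
    coordinates and ages are synthetic; only the excluded records carry
    published values.
    """
    rng = np.random.default_rng(seed)
    frac = rng.random(n_included)
    lon = 38.0 + frac * 40.0 + rng.normal(0, 1.5, n_included)
    lat = 33.0 - frac * 15.0 + rng.normal(0, 2.0, n_included)
    age = 10000.0 - frac * 6000.0 + rng.normal(0, 300.0, n_included)
    rows = pd.DataFrame(
        {
            "site": [f"Site_{i:03d}" for i in range(n_included)],
            "lab_code": [f"LAB-{i:04d}" for i in range(n_included)],
            "c14_age": np.round(age, 0),
            "c14_error": rng.integers(30, 120, n_included),
            "lon": np.clip(lon, -180, 180),
            "lat": np.clip(lat, -90, 90),
            "affiliation": "synthetic",
            "included": True,
            "exclusion_reason": "",
        }
    )
    excl = pd.DataFrame(
        EXCLUDED_DATES,
        columns=["site", "lab_code", "c14_age", "c14_error", "lon", "lat",
                 "exclusion_reason"],
    )
    excl["affiliation"] = "excluded"
    excl["included"] = False
    excl = excl[rows.columns]
    return pd.concat([rows, excl], ignore_index=True)


def write_fixture(directory: str | Path, spec: SyntheticSpec) -> dict[str, Path]:
    """Write a complete self-describing fixture: raster, legend, dates,
    curve and run configuration.  Returns the path of each artifact."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raster = make_banded_raster(spec)
    curve = toy_cal_curve(max_cal_bp=max(14000.0, spec.t0 + 2000.0))
    sites = simulate_sites(raster, spec)
    dates = sites_to_c14_table(sites, spec, curve)

    paths = {
        "raster": directory / "terrain.asc",
        "legend": directory / "legend.csv",
        "dates": directory / "dates.csv",
        "curve": directory / "curve.csv",
        "config": directory / "config.yaml",
        "truth": directory / "truth.csv",
    }
    write_class_raster(paths["raster"], raster, legend_path=paths["legend"])
    dates.to_csv(paths["dates"], index=False)
    with open(paths["curve"], "w") as fh:
        fh.write("# synthetic invertible calibration curve (cal BP, c14 age, error)\n")
        pd.DataFrame(
            {"cal_bp": curve.cal_bp[::-1], "mu": curve.mu[::-1],
             "sigma": curve.sigma_curve[::-1]}
        ).to_csv(fh, index=False, header=False)
    config = {
        "dates": str(paths["dates"].name),
        "raster": str(paths["raster"].name),
        "legend": str(paths["legend"].name),
        "curve": str(paths["curve"].name),
        "origin_site_id": "ORIGIN",
        "t0": "origin_median",
        "v0": spec.v0,
        "aggregation": "earliest_per_site",
        "projection": {"lon0": spec.lon0, "lat0": spec.lat0},
        "ga": {"pop_size": 500, "n_parents": 250, "n_elite": 50,
               "p_mutation": 0.2, "n_generations": 20},
        "seed": spec.seed,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    truth = pd.DataFrame(
        {
            "class_id": list(range(spec.n_classes)),
            "label": raster.legend,
            "true_speed_km_per_yr": list(spec.true_speeds),
            "true_cost": spec.true_costs,
        }
    )
    truth.to_csv(paths["truth"], index=False)
    return paths
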