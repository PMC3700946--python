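"""Occupancy grid, turtle-days accounting, habitat GLM and threat overlap.

A 10 x 10 km grid is laid over the neritic study extent (cells whose centre
depth is outside (-200, 0) m are excluded). Turtle-days — distinct calendar
days a turtle had at least one fix in a cell — are modelled with a Poisson
log-link GLM against bathymetry and distance to the tagging site. Threat
scoring counts non-removed platforms within a 10 km buffer of each home
range centroid and looks up trawl-effort days of the containing zone.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import Point, Polygon

from .geo import BathymetryGrid, EqualAreaFrame, LatLon, depth_at, distance_to_shore_km, haversine_km_arrays
from .io_formats import ArgosFix


@dataclass
class GridCell:
    cell_id: int
    center: LatLon
    depth_m: float
    distance_to_mainland_km: float = float("nan")
    distance_to_tagging_km: float = float("nan")
    turtle_days: int = 0


@dataclass
class ThreatScore:
    centroid_id: str
    trawl_days: int | None
    trawl_band: str | None
    platforms_within_10km: int


@dataclass
class OccupancyGrid:
    frame: EqualAreaFrame
    cell_km: float
    x0: float
    y0: float
    nx: int
    ny: int
    cells: dict = field(default_factory=dict)  # (ix, iy) -> GridCell

    def cell_index(self, p: LatLon) -> tuple[int, int]:
        x, y = self.frame.forward(p)
        return int(np.floor((x - self.x0) / self.cell_km)), int(np.floor((y - self.y0) / self.cell_km))


def build_grid(
    extent: tuple[LatLon, LatLon],
    grid: BathymetryGrid,
    cell_km: float = 10.0,
    cutoff_m: float = -200.0,
    tagging: LatLon | None = None,
    with_shore_distance: bool = False,
) -> OccupancyGrid:
    """Axis-aligned cells in the equal-area frame over ``extent``.

    Only cells whose centre depth lies strictly inside (cutoff, 0) are kept.
    Raises if no cell survives.
    """
    sw, ne = extent
    ref = LatLon((sw.lat + ne.lat) / 2.0, (sw.lon + ne.lon) / 2.0)
    frame = EqualAreaFrame(ref)
    corners_lat = np.array([sw.lat, sw.lat, ne.lat, ne.lat])
    corners_lon = np.array([sw.lon, ne.lon, sw.lon, ne.lon])
    cx, cy = frame.forward_xy(corners_lat, corners_lon)
    x0, x1 = float(cx.min()), float(cx.max())
    y0, y1 = float(cy.min()), float(cy.max())
    nx = max(1, int(np.ceil((x1 - x0) / cell_km)))
    ny = max(1, int(np.ceil((y1 - y0) / cell_km)))
    out = OccupancyGrid(frame, cell_km, x0, y0, nx, ny)
    cell_id = 0
    for ix in range(nx):
        for iy in range(ny):
            center = frame.inverse(x0 + (ix + 0.5) * cell_km, y0 + (iy + 0.5) * cell_km)
            if not grid.contains(center):
                continue
            depth = depth_at(grid, center)
            if depth is None or not (cutoff_m < depth < 0):
                continue
            cell = GridCell(cell_id, center, depth)
            if with_shore_distance:
                cell.distance_to_mainland_km = distance_to_shore_km(grid, center)
            if tagging is not None:
                cell.distance_to_tagging_km = float(
                    haversine_km_arrays(center.lat, center.lon, tagging.lat, tagging.lon)
                )
            out.cells[(ix, iy)] = cell
            cell_id += 1
    if not out.cells:
        raise ValueError("occupancy grid empty: extent holds no neritic water cells")
    return out


def turtle_days(tracks: dict[str, list[ArgosFix]], grid: OccupancyGrid) -> dict:
    """Distinct (turtle, date) visits per cell; totals summed over turtles.

    A turtle visiting two cells on one day contributes one day to each.
    """
    visits: set[tuple[str, dt.date, tuple[int, int]]] = set()
    for turtle, fixes in tracks.items():
        for f in fixes:
            key = grid.cell_index(f.pos)
            if key in grid.cells:
                visits.add((turtle, f.timestamp.date(), key))
    counts: dict = {}
    for _turtle, _date, key in visits:
        counts[key] = counts.get(key, 0) + 1
    for key, cell in grid.cells.items():
        cell.turtle_days = counts.get(key, 0)
    return counts


def glm_turtle_days(cells: list[GridCell], covariates=("depth_m", "distance_to_tagging_km")):
    """Poisson log-link GLM of turtle-days on cell covariates.

    Fit by iteratively reweighted least squares (relative tolerance 1e-8,
    at most 100 iterations); reports coefficient, standard error, Wald
    chi-square and p-value per covariate at alpha 0.05.
    """
    if len(cells) < 10:
        raise ValueError(f"GLM needs >= 10 cells, got {len(cells)}")
    df = pd.DataFrame(
        {
            "turtle_days": [c.turtle_days for c in cells],
            **{cov: [getattr(c, cov) for c in cells] for cov in covariates},
        }
    )
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("non-finite covariate in GLM input")
    X = sm.add_constant(df[list(covariates)]) if covariates else pd.DataFrame(
        {"const": np.ones(len(df))}
    )
    model = sm.GLM(df["turtle_days"], X, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(f"Poisson GLM failed to converge:\n{res.summary()}")
    rows = []
    for name in X.columns:
        coef = float(res.params[name])
        se = float(res.bse[name])
        chi2 = (coef / se) ** 2 if se > 0 else float("inf")
        rows.append(
            {
                "term": name,
                "coef": coef,
                "se": se,
                "wald_chi2": chi2,
                "p": float(res.pvalues[name]),
                "significant_0.05": bool(res.pvalues[name] < 0.05),
            }
        )
    return pd.DataFrame(rows), res


def platforms_within_buffer(
    centroid: LatLon, platforms: pd.DataFrame, r_km: float = 10.0
) -> int:
    """Count active platforms within ``r_km`` (boundary inclusive).

    ``platforms`` columns: lat, lon, optional removal_date (non-empty value
    means the platform was removed and is not counted).
    """
    if platforms.empty:
        return 0
    active = platforms
    if "removal_date" in platforms.columns:
        active = platforms[platforms["removal_date"].isna() | (platforms["removal_date"] == "")]
    if active.empty:
        return 0
    d = haversine_km_arrays(
        centroid.lat, centroid.lon, active["lat"].to_numpy(), active["lon"].to_numpy()
    )
    return int(np.sum(d <= r_km))


#: Printed trawl-effort bands (days, May–Aug), closed intervals.
TRAWL_BANDS = (
    (4, 4, "4"),
    (5, 1500, "5-1500"),
    (1501, 3000, "1501-3000"),
    (3001, 7000, "3001-7000"),
)


def trawl_band_label(days: int) -> str:
    for lo, hi, label in TRAWL_BANDS:
        if lo <= days <= hi:
            return label
    raise ValueError(f"trawl effort {days} days outside the defined bands")


def trawl_category(
    centroid: LatLon, zones: list[tuple[Polygon, int]]
) -> tuple[int | None, str | None]:
    """Effort-days and band label of the zone containing the centroid.

    Zones are (lon/lat polygon, effort days). Returns (None, None) when no
    zone contains the point.
    """
    pt = Point(centroid.lon, centroid.lat)
    for poly, days in zones:
        if poly.covers(pt):
            return int(days), trawl_band_label(int(days))
    return None, None


def score_threats(
    centroids: dict[str, LatLon],
    platforms: pd.DataFrame,
    zones: list[tuple[Polygon, int]],
    r_km: float = 10.0,
) -> list[ThreatScore]:
    out = []
    for cid, c in centroids.items():
        days, band = trawl_category(c, zones)
        out.append(ThreatScore(cid, days, band, platforms_within_buffer(c, platforms, r_km)))
    return out
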