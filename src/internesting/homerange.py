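"""Home-range estimation: fixed-kernel KDE with LSCV bandwidth, probability
contours clipped to water, and the minimum convex polygon.

Points enter in lon/lat, are projected into a local equal-area frame (km)
centred on their centroid, and all densities, contours, hulls and areas are
computed there; polygons are carried back to lon/lat for serialisation.
The 50% contour is the core-use area, the 95% contour the overall range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import transform as shp_transform, unary_union
from skimage import measure

from .geo import BathymetryGrid, EqualAreaFrame, LatLon


@dataclass
class KDEResult:
    frame: EqualAreaFrame
    bandwidth: tuple[float, float]  # km per axis after back-scaling
    rescaled: bool
    contours: dict  # level -> list of shapely Polygons in frame km
    masses: dict  # level -> grid-integrated probability mass inside contour
    in_water_area_km2: dict = field(default_factory=dict)
    centroid: LatLon | None = None
    occupancy_days: int = 0

    def contours_latlon(self, level: float) -> list[Polygon]:
        inv = lambda x, y: self.frame.inverse_latlon(x, y)[::-1]
        return [shp_transform(lambda x, y: inv(x, y), p) for p in self.contours[level]]


@dataclass
class MCPResult:
    frame: EqualAreaFrame
    hull: Polygon
    area_km2: float
    centroid: LatLon
    occupancy_days: int = 0
    degenerate: bool = False


def project_points(points: list[LatLon], frame: EqualAreaFrame | None = None):
    lat = np.array([p.lat for p in points])
    lon = np.array([p.lon for p in points])
    if frame is None:
        frame = EqualAreaFrame(LatLon(float(lat.mean()), float(lon.mean())))
    x, y = frame.forward_xy(lat, lon)
    return np.column_stack([x, y]), frame


# ---------------------------------------------------------------------------
# LSCV bandwidth


def _pairwise_r2(xy: np.ndarray) -> np.ndarray:
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    return d2[np.triu_indices(xy.shape[0], k=1)]


def _lscv_score_r2(r2: np.ndarray, n: int, h: float) -> float:
    term1 = (n + 2.0 * np.exp(-r2 / (4.0 * h * h)).sum()) / (n * n * 4.0 * math.pi * h * h)
    term2 = (2.0 / (n * (n - 1))) * np.exp(-r2 / (2.0 * h * h)).sum() * 2.0 / (2.0 * math.pi * h * h)
    return float(term1 - term2)


def lscv_score(xy: np.ndarray, h: float) -> float:
    """Least-squares cross-validation risk of a 2-D Gaussian kernel, sd h."""
    xy = np.asarray(xy, dtype=float)
    return _lscv_score_r2(_pairwise_r2(xy), xy.shape[0], h)


def lscv_bandwidth(xy: np.ndarray, n_candidates: int = 50) -> tuple[tuple[float, float], bool]:
    """Bandwidth minimising the LSCV score over a logarithmic search grid.

    When the axis standard deviations differ by more than 10%, coordinates
    are rescaled to unit variance, one h is chosen, and it is back-scaled
    per axis. Returns ((h_x, h_y), rescaled_flag) in the units of ``xy``.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 2 or np.allclose(xy, xy[0]):
        raise ValueError("bandwidth undefined: all points identical")
    sx, sy = xy.std(axis=0, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("bandwidth undefined: degenerate spread on one axis")
    rescaled = abs(sx - sy) / max(sx, sy) > 0.10
    if rescaled:
        work = xy / np.array([sx, sy])
        sigma = 1.0
    else:
        work = xy
        sigma = math.sqrt(0.5 * (sx * sx + sy * sy))
    cands = np.geomspace(0.05 * sigma, 2.0 * sigma, n_candidates)
    r2 = _pairwise_r2(work)
    scores = [_lscv_score_r2(r2, work.shape[0], h) for h in cands]
    h = float(cands[int(np.argmin(scores))])
    if rescaled:
        return (h * sx, h * sy), True
    return (h, h), False


# ---------------------------------------------------------------------------
# density grid and contours


def kde_grid(xy: np.ndarray, h: tuple[float, float], max_cells: int = 512):
    """Gaussian product-kernel density on a regular grid padded 3h.

    Grid resolution is at most h/3 per axis (coarsened only if the extent
    would need more than ``max_cells`` cells on an axis). Exploits kernel
    separability: the density matrix is a single matrix product.
    """
    hx, hy = h
    x0, x1 = xy[:, 0].min() - 3 * hx, xy[:, 0].max() + 3 * hx
    y0, y1 = xy[:, 1].min() - 3 * hy, xy[:, 1].max() + 3 * hy
    dx = max(hx / 3.0, (x1 - x0) / max_cells)
    dy = max(hy / 3.0, (y1 - y0) / max_cells)
    gx = np.arange(x0, x1 + dx, dx)
    gy = np.arange(y0, y1 + dy, dy)
    n = xy.shape[0]
    Gx = np.exp(-0.5 * ((gx[:, None] - xy[None, :, 0]) / hx) ** 2) / (hx * math.sqrt(2 * math.pi))
    Gy = np.exp(-0.5 * ((gy[:, None] - xy[None, :, 1]) / hy) ** 2) / (hy * math.sqrt(2 * math.pi))
    dens = (Gx @ Gy.T) / n  # [ix, iy]
    return gx, gy, dens


def _mass_threshold(dens: np.ndarray, cell_area: float, level: float) -> tuple[float, float]:
    """Smallest density threshold whose superlevel set holds >= level mass."""
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    total = cum[-1]
    idx = int(np.searchsorted(cum, level * total))
    idx = min(idx, flat.size - 1)
    thr = flat[idx]
    mass = float(cum[idx] / total)
    return float(thr), mass


def kde_contours(
    xy: np.ndarray, h: tuple[float, float], levels=(0.50, 0.95)
) -> tuple[dict, dict, tuple]:
    """Highest-density-region contour polygons at the requested masses.

    Contours are extracted by marching squares at the mass-matched density
    threshold. Returns ({level: [Polygon]}, {level: attained grid mass},
    (gx, gy, dens)).
    """
    for lv in levels:
        if not 0.0 < lv < 1.0:
            raise ValueError(f"contour level {lv} outside (0, 1)")
    gx, gy, dens = kde_grid(xy, h)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    contours: dict = {}
    masses: dict = {}
    for lv in sorted(levels):
        thr, mass = _mass_threshold(dens, cell_area, lv)
        polys = _contour_polygons(gx, gy, dens, thr)
        contours[lv] = polys
        masses[lv] = mass
    return contours, masses, (gx, gy, dens)


def _contour_polygons(gx, gy, dens, thr) -> list[Polygon]:
    """Marching-squares isolines -> valid polygons with nesting as holes."""
    loops = measure.find_contours(dens, thr)
    rings = []
    for loop in loops:
        if loop.shape[0] < 4:
            continue
        xs = np.interp(loop[:, 0], np.arange(gx.size), gx)
        ys = np.interp(loop[:, 1], np.arange(gy.size), gy)
        ring = Polygon(np.column_stack([xs, ys]))
        if ring.is_valid and ring.area > 0:
            rings.append(ring)
    if not rings:
        return []
    rings.sort(key=lambda r: r.area, reverse=True)
    # even-odd nesting: a ring inside an odd number of larger rings is a hole
    shells: list[Polygon] = []
    holes_for: list[list] = []
    for ring in rings:
        depth = sum(1 for s in rings if s.area > ring.area and s.contains(ring.representative_point()))
        if depth % 2 == 0:
            shells.append(ring)
            holes_for.append([])
        else:
            parents = [i for i, s in enumerate(shells) if s.contains(ring.representative_point())]
            if parents:
                holes_for[parents[-1]].append(ring.exterior.coords)
    out = []
    for shell, holes in zip(shells, holes_for):
        poly = Polygon(shell.exterior.coords, holes)
        if not poly.is_valid:
            poly = poly.buffer(0)
        out.append(poly)
    return out


# ---------------------------------------------------------------------------
# land clipping


def land_polygon(grid: BathymetryGrid, frame: EqualAreaFrame, bounds) -> Polygon:
    """Union of land cells (value >= 0) intersecting ``bounds``, in frame km."""
    land = grid.land_cell_centers()
    if land.shape[0] == 0:
        return Polygon()
    minx, miny, maxx, maxy = bounds
    half = grid.cell_size / 2.0
    cells = []
    for lat, lon in land:
        x, y = frame.forward_xy(lat, lon)
        # conservative bbox check in frame coordinates
        cs_km = grid.cell_size * 111.5
        if minx - cs_km <= x <= maxx + cs_km and miny - cs_km <= y <= maxy + cs_km:
            corners_lat = [lat - half, lat - half, lat + half, lat + half]
            corners_lon = [lon - half, lon + half, lon + half, lon - half]
            cx, cy = frame.forward_xy(np.array(corners_lat), np.array(corners_lon))
            cells.append(Polygon(np.column_stack([cx, cy])))
    if not cells:
        return Polygon()
    return unary_union(cells)


def clip_to_water(polygons: list[Polygon], grid: BathymetryGrid, frame: EqualAreaFrame):
    """In-water area of each polygon (km^2): land cells removed.

    Returns (clipped polygons, total in-water area). Clipped area is never
    larger than the input area.
    """
    if not polygons:
        return [], 0.0
    bounds = unary_union(polygons).bounds
    land = land_polygon(grid, frame, bounds)
    clipped = [p.difference(land) for p in polygons]
    return clipped, float(sum(p.area for p in clipped))


# ---------------------------------------------------------------------------
# MCP and centroids


def mcp(points: list[LatLon], occupancy_days: int = 0) -> MCPResult:
    """Minimum convex polygon over 100% of the points, area in km^2.

    Fewer than 3 points, or collinear points, degenerate to area 0 with the
    centroid at the point mean, flagged.
    """
    xy, frame = project_points(points)
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if hull.geom_type != "Polygon" or hull.area < 1e-9:
        cx, cy = xy.mean(axis=0)
        return MCPResult(frame, Polygon(), 0.0, frame.inverse(float(cx), float(cy)),
                         occupancy_days, degenerate=True)
    c = hull.centroid
    return MCPResult(frame, hull, float(hull.area), frame.inverse(c.x, c.y), occupancy_days)


def centroid_of_core(kde: KDEResult, level: float = 0.50) -> LatLon:
    """Centroid of the largest activity centre of the core-use contour.

    Equal-area ties break to the westernmost centroid.
    """
    polys = kde.contours.get(level) or []
    if not polys:
        raise ValueError(f"no contour at level {level}")
    best = max(polys, key=lambda p: (p.area, -kde.frame.inverse(p.centroid.x, p.centroid.y).lon))
    c = best.centroid
    return kde.frame.inverse(c.x, c.y)


def kde_homerange(
    points: list[LatLon],
    grid: BathymetryGrid | None = None,
    levels=(0.50, 0.95),
    occupancy_days: int = 0,
) -> KDEResult:
    """Full KDE pipeline step: LSCV bandwidth, contours, water clipping."""
    if len(points) < 20:
        raise ValueError(f"KDE requires >= 20 mean daily locations, got {len(points)}")
    xy, frame = project_points(points)
    h, rescaled = lscv_bandwidth(xy)
    contours, masses, _ = kde_contours(xy, h, levels)
    result = KDEResult(frame, h, rescaled, contours, masses, occupancy_days=occupancy_days)
    for lv in levels:
        if grid is not None:
            clipped, area = clip_to_water(contours[lv], grid, frame)
        else:
            area = float(sum(p.area for p in contours[lv]))
        result.in_water_area_km2[lv] = area
    result.centroid = centroid_of_core(result, min(levels))
    return result
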