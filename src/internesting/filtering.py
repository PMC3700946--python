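"""Track cleaning: quality-class, speed, and land/depth filters.

The pipeline default chain is lc -> speed -> land/depth mask, followed by
the mean-daily-location reduction used to de-autocorrelate the data before
kernel density estimation. The full chain is idempotent.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

from .geo import BathymetryGrid, LatLon, haversine_km, depth_at
from .io_formats import ArgosFix

log = logging.getLogger("internesting")

Track = list  # list[ArgosFix]


@dataclass
class FilterReport:
    """Per-rule drop counts; dropped + retained always equals the input."""

    dropped: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())


def drop_lc_z(track: Track) -> tuple[Track, FilterReport]:
    """Reject implausible class-Z fixes (no Argos error estimate exists)."""
    kept = [f for f in track if f.lc != "Z"]
    rep = FilterReport({"lc_z": len(track) - len(kept)}, len(kept))
    return kept, rep


def speed_filter(track: Track, vmax_kmh: float = 5.0) -> tuple[Track, FilterReport]:
    """Forward-sweep swim-speed filter.

    The first fix is always retained; each later fix is dropped if the
    great-circle speed from the last *retained* fix exceeds ``vmax_kmh``.
    A fix at zero time gap from the previous retained fix but a different
    position is dropped and logged. Idempotent by construction.
    """
    if not track:
        return [], FilterReport({"speed": 0, "zero_gap": 0}, 0)
    kept = [track[0]]
    n_speed = n_zero = 0
    for fix in track[1:]:
        prev = kept[-1]
        dt_h = (fix.timestamp - prev.timestamp).total_seconds() / 3600.0
        if dt_h < 0:
            raise ValueError("timestamps not increasing in speed_filter")
        d_km = haversine_km(prev.pos, fix.pos)
        if dt_h == 0.0:
            if d_km > 0.0:
                n_zero += 1
                log.debug("speed_filter: zero time gap at %s, dropped", fix.timestamp)
            else:
                n_zero += 1  # exact-time duplicate position
            continue
        if d_km / dt_h > vmax_kmh:
            n_speed += 1
            continue
        kept.append(fix)
    rep = FilterReport({"speed": n_speed, "zero_gap": n_zero}, len(kept))
    return kept, rep


def mask_land_and_deep(
    track: Track,
    grid: BathymetryGrid,
    cutoff_m: float = -200.0,
    on_outside: str = "drop",
) -> tuple[Track, FilterReport]:
    """Keep fixes in the neritic band ``cutoff_m <= depth < 0``.

    The lower bound is closed: a fix at exactly the cutoff depth is kept.
    Fixes outside the grid extent are dropped with a log entry when
    ``on_outside='drop'`` (default), else raise.
    """
    kept: Track = []
    n_land = n_deep = n_out = n_nodata = 0
    for fix in track:
        if not grid.contains(fix.pos):
            if on_outside == "drop":
                n_out += 1
                log.debug("mask_land_and_deep: fix outside grid at %s", fix.pos)
                continue
            raise ValueError(f"fix outside bathymetry extent: {fix.pos}")
        depth = depth_at(grid, fix.pos)
        if depth is None:
            n_nodata += 1
        elif depth >= 0:
            n_land += 1
        elif depth < cutoff_m:
            n_deep += 1
        else:
            kept.append(fix)
    rep = FilterReport(
        {"land": n_land, "deep": n_deep, "outside": n_out, "nodata": n_nodata}, len(kept)
    )
    return kept, rep


def apply_filter_chain(
    track: Track, grid: BathymetryGrid | None, vmax_kmh: float = 5.0, cutoff_m: float = -200.0
) -> tuple[Track, FilterReport]:
    """Default chain lc -> speed -> land/depth, with a merged report."""
    n_in = len(track)
    track, r1 = drop_lc_z(track)
    track, r2 = speed_filter(track, vmax_kmh) if len(track) >= 2 else (track, FilterReport({}, len(track)))
    if grid is not None:
        track, r3 = mask_land_and_deep(track, grid, cutoff_m)
    else:
        r3 = FilterReport({}, len(track))
    dropped = {**r1.dropped, **r2.dropped, **r3.dropped}
    log.info("filter chain: %d -> %d fixes (%s)", n_in, len(track), dropped)
    return track, FilterReport(dropped, len(track))


def mean_daily_locations(track: Track) -> list[tuple[dt.date, LatLon]]:
    """One arithmetic-mean location per UTC date with at least one fix.

    Longitudes are averaged arithmetically; the study area spans no
    antimeridian, guarded by an extent assertion.
    """
    by_date: dict[dt.date, list[LatLon]] = {}
    for f in track:
        by_date.setdefault(f.timestamp.date(), []).append(f.pos)
    lons = [f.pos.lon for f in track]
    if lons and (max(lons) - min(lons) > 180.0):
        raise ValueError("track spans the antimeridian; arithmetic lon averaging invalid")
    out = []
    for date in sorted(by_date):
        pts = by_date[date]
        out.append(
            (date, LatLon(sum(p.lat for p in pts) / len(pts), sum(p.lon for p in pts) / len(pts)))
        )
    return out
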