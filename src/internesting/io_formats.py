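"""Readers/writers for tracks, events and layers, plus the run configuration.

One CSV dialect everywhere: comma-separated, UTF-8, ISO-8601 UTC timestamps.
No raw Argos vendor formats are supported — the telemetry behind the analysis
was never deposited, so this dialect is the repository's own data contract.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping

from .geo import LatLon

log = logging.getLogger("internesting")

LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

#: Fixed per-location-class t-distribution observation-error constants:
#: (degrees of freedom, scale in km). Heavier tails / larger scale for the
#: unvalidated classes A and B, in line with published Argos calibrations.
LC_ERROR_TABLE: dict[str, tuple[float, float]] = {
    "3": (8.0, 0.25),
    "2": (6.0, 0.45),
    "1": (5.0, 0.90),
    "0": (3.0, 2.50),
    "A": (3.0, 3.50),
    "B": (2.5, 5.00),
}


@dataclass(frozen=True)
class ArgosFix:
    """One satellite-derived position with its Argos quality class."""

    turtle_id: str
    timestamp: dt.datetime
    lc: str
    pos: LatLon

    def __post_init__(self) -> None:
        if self.lc not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.lc!r}")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=dt.timezone.utc))


@dataclass(frozen=True)
class Emergence:
    """A beach emergence: a nest or an abandoned attempt (false crawl)."""

    turtle_id: str
    date: dt.date
    site_label: str
    pos: LatLon
    kind: str  # "nest" | "false_crawl"

    def __post_init__(self) -> None:
        if self.kind not in ("nest", "false_crawl"):
            raise ValueError(f"unknown emergence kind {self.kind!r}")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the study's defaults."""

    speed_limit_kmh: float = 5.0
    neritic_cutoff_m: float = -200.0
    ssm_interval_hours: float = 8.0
    mcmc_chains: int = 2
    mcmc_iterations: int = 10_000
    mcmc_burn_in: int = 7_000
    mcmc_thin: int = 5
    kde_levels: tuple[float, ...] = (0.50, 0.95)
    min_mean_daily_locations: int = 20
    fidelity_replicates: int = 100
    nest_fidelity_radius_km: float = 5.0
    grid_cell_km: float = 10.0
    platform_buffer_km: float = 10.0
    mode_cutoff_low: float = 1.25
    mode_cutoff_high: float = 1.75
    rhat_threshold: float = 1.1
    lc_error_table: dict = field(default_factory=lambda: dict(LC_ERROR_TABLE))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "speed_limit_kmh", "ssm_interval_hours", "mcmc_chains", "mcmc_iterations",
            "mcmc_thin", "min_mean_daily_locations", "fidelity_replicates",
            "nest_fidelity_radius_km", "grid_cell_km", "platform_buffer_km",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.neritic_cutoff_m >= 0:
            raise ValueError("neritic_cutoff_m must be negative (below sea level)")
        if not 0 <= self.mcmc_burn_in < self.mcmc_iterations:
            raise ValueError("burn-in must lie inside the iteration count")
        if not all(0.0 < lv < 1.0 for lv in self.kde_levels):
            raise ValueError("KDE levels must be in (0, 1)")
        if not 1.0 <= self.mode_cutoff_low < self.mode_cutoff_high <= 2.0:
            raise ValueError("mode cutoffs must satisfy 1 <= low < high <= 2")
        self.lc_error_table = {k: tuple(v) for k, v in self.lc_error_table.items()}

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["kde_levels"] = list(self.kde_levels)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["kde_levels"] = tuple(d["kde_levels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# tracks

TRACK_COLUMNS = ["turtle_id", "timestamp", "lc", "lat", "lon"]


def read_track_csv(path: str | Path) -> dict[str, list[ArgosFix]]:
    """Read a track table, returning fixes grouped by turtle.

    Rows with unparseable timestamps/coordinates or out-of-vocabulary
    location classes are rejected with a logged count; exact duplicates are
    dropped; fixes are stably sorted by (turtle_id, timestamp).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"turtle_id": str, "lc": str})
    if df.empty:
        raise ValueError(f"empty track file: {path}")
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"track file {path} missing column '{col}'")
    n_in = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    bad = (
        df["timestamp"].isna()
        | df["lat"].isna() | df["lon"].isna()
        | ~df["lat"].between(-90, 90) | ~df["lon"].between(-180, 180)
        | ~df["lc"].isin(LOCATION_CLASSES)
    )
    if bad.any():
        log.warning("read_track_csv(%s): rejected %d unparseable rows", path.name, int(bad.sum()))
    df = df[~bad]
    n_dup = int(df.duplicated(subset=TRACK_COLUMNS).sum())
    if n_dup:
        log.warning("read_track_csv(%s): dropped %d duplicate rows", path.name, n_dup)
    df = df.drop_duplicates(subset=TRACK_COLUMNS)
    df = df.sort_values(["turtle_id", "timestamp"], kind="stable")
    log.info("read_track_csv(%s): %d/%d fixes retained", path.name, len(df), n_in)
    out: dict[str, list[ArgosFix]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.turtle_id, []).append(
            ArgosFix(row.turtle_id, row.timestamp.to_pydatetime(), row.lc, LatLon(row.lat, row.lon))
        )
    return out


def write_track_csv(tracks: dict[str, list[ArgosFix]], path: str | Path) -> None:
    rows = [
        {
            "turtle_id": f.turtle_id,
            "timestamp": f.timestamp.strftime("%Y-%m-%dT%H:%M:%S+00:00"),
            "lc": f.lc,
            "lat": round(f.pos.lat, 6),
            "lon": round(f.pos.lon, 6),
        }
        for turtle in sorted(tracks)
        for f in tracks[turtle]
    ]
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# emergences

EMERGENCE_COLUMNS = ["turtle_id", "date", "site_label", "lat", "lon", "kind"]


def read_emergence_csv(path: str | Path) -> dict[str, list[Emergence]]:
    df = pd.read_csv(path, dtype={"turtle_id": str, "site_label": str, "kind": str})
    for col in EMERGENCE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"emergence file {path} missing column '{col}'")
    out: dict[str, list[Emergence]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.turtle_id, []).append(
            Emergence(
                row.turtle_id,
                dt.date.fromisoformat(str(row.date)),
                row.site_label,
                LatLon(float(row.lat), float(row.lon)),
                row.kind,
            )
        )
    for evs in out.values():
        evs.sort(key=lambda e: e.date)
    return out


def write_emergence_csv(emergences: dict[str, list[Emergence]], path: str | Path) -> None:
    rows = [
        {
            "turtle_id": e.turtle_id,
            "date": e.date.isoformat(),
            "site_label": e.site_label,
            "lat": round(e.pos.lat, 6),
            "lon": round(e.pos.lon, 6),
            "kind": e.kind,
        }
        for turtle in sorted(emergences)
        for e in emergences[turtle]
    ]
    pd.DataFrame(rows, columns=EMERGENCE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON

def write_geojson(features: list[tuple[object, dict]], path: str | Path) -> None:
    """Write (shapely geometry, properties) pairs as RFC 7946 GeoJSON.

    Coordinates are written in lon-lat order (WGS84). Invalid geometries
    raise before anything is written.
    """
    for geom, _props in features:
        if hasattr(geom, "is_valid") and not geom.is_valid:
            raise ValueError(f"invalid geometry: {geom.wkt[:80]}")
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[tuple[object, dict]]:
    from shapely.geometry import shape

    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in fc["features"]]
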