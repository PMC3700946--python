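import datetime as dt
import math

import numpy as np
import pytest

from internesting import BathymetryGrid, LatLon
from internesting.io_formats import ArgosFix

UTC = dt.timezone.utc
T0 = dt.datetime(2012, 6, 1, tzinfo=UTC)


def make_track(positions, start=T0, step_hours=8.0, lc="1", turtle="t1"):
    """Build a fix list from (lat, lon) pairs at a regular cadence."""
    return [
        ArgosFix(turtle, start + dt.timedelta(hours=i * step_hours), lc, LatLon(la, lo))
        for i, (la, lo) in enumerate(positions)
    ]


@pytest.fixture(scope="session")
def ramp_grid():
    """Analytic ramp: depth(lon) = -10 * lon over lon in [-1, 31].

    Land (value >= 0) west of lon 0, deepening eastward: -200 m is crossed
    at lon 20. Cell size 0.1 degrees, lat in [-1, 1].
    """
    cs = 0.1
    lons = -1.0 + (np.arange(320) + 0.5) * cs
    col = -10.0 * lons
    values = np.repeat(col[None, :], 20, axis=0)
    return BathymetryGrid(LatLon(-1.0, -1.0), cs, values)


@pytest.fixture(scope="session")
def coast_grid():
    """Straight coastline along lon = 0: land west (value +1), water east."""
    cs = 0.1
    lons = -1.0 + (np.arange(30) + 0.5) * cs
    col = np.where(lons < 0.0, 1.0, -30.0)
    values = np.repeat(col[None, :], 20, axis=0)
    return BathymetryGrid(LatLon(-1.0, -1.0), cs, values)


@pytest.fixture(scope="session")
def open_water_grid():
    """All-water basin at -50 m with a single land strip on its north edge."""
    cs = 0.1
    n = 60
    values = np.full((n, n), -50.0)
    values[-1, :] = 2.0
    return BathymetryGrid(LatLon(27.0, -90.0), cs, values)
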