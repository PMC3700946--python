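"""Delimit each turtle's in-water inter-nesting area.

For inter-nesting periods with at least 20 mean daily locations a fixed-
kernel KDE with LSCV bandwidth gives 50% (core) and 95% (range) contours,
land-clipped to in-water area; shorter periods fall back to the 100%
minimum convex polygon. Also reports total distance moved, centroid depth
and distance to shore per turtle.
"""

from pathlib import Path

import pandas as pd

from internesting.cli import main

WORKDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    main(["--workdir", str(WORKDIR), "homerange"], standalone_mode=False)
    hr = pd.read_csv(WORKDIR / "homerange.csv")
    cols = [c for c in ("turtle_id", "estimator", "occupancy_days", "area50_km2",
                        "area95_km2", "area_km2", "tdm_km", "tdm_per_day_km",
                        "centroid_depth_m", "centroid_to_shore_km") if c in hr.columns]
    print(hr[cols].to_string(index=False))
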