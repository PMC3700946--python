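"""Reproduce the study's printed summary statistics from the packaged
fixture tables (tracking effort, inter-nesting durations, home-range areas,
centroid spacing, emergence distances).

All values are recomputed from the per-turtle rows and rounded half-up to
the printed precision.
"""

from pathlib import Path

from internesting import load_fixture, pooled_weighted_mean, round_half_up
from internesting.cli import main

WORKDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    WORKDIR.mkdir(parents=True, exist_ok=True)
    main(["--workdir", str(WORKDIR), "summarize"], standalone_mode=False)
    rows = load_fixture("table1").dropna(subset=["mean_distance_km"])
    mean, n = pooled_weighted_mean(
        rows["mean_distance_km"].tolist(), rows["n_distances"].astype(int).tolist()
    )
    print(f"\npooled emergence distance: {round_half_up(mean)} km over {n} distances")
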