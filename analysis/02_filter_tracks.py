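"""Clean the raw Argos tracks: reject class-Z fixes, apply the 5 km/h swim
speed limit, and mask land and water deeper than the 200 m neritic cutoff.

Writes tracks_filtered.csv and a per-turtle drop-count report.
"""

from pathlib import Path

import pandas as pd

from internesting.cli import main

WORKDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    main(["--workdir", str(WORKDIR), "filter"], standalone_mode=False)
    rep = pd.read_csv(WORKDIR / "filter_report.csv")
    print(rep.to_string(index=False))
    print(f"retained {rep['retained'].sum()} of {rep['input'].sum()} fixes")
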