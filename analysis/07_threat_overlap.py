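"""Score anthropogenic-threat exposure at each inter-nesting centroid.

Counts active (non-removed) oil and gas platforms within a 10 km buffer of
each home-range centroid and assigns the trawl-effort band of the
statistical zone containing it.
"""

from pathlib import Path

import pandas as pd

from internesting.cli import main

WORKDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    main(["--workdir", str(WORKDIR), "threats"], standalone_mode=False)
    print(pd.read_csv(WORKDIR / "threats.csv").to_string(index=False))
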