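#!/usr/bin/env python
"""Step 1: generate the default synthetic cohort used by the later steps.

Writes results/cohort.csv (plus a JSON provenance sidecar via the CLI).
"""

import sys
from pathlib import Path

from snpcox.cli import main

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    seed = sys.argv[1] if len(sys.argv) > 1 else "1"
    RESULTS.mkdir(exist_ok=True)
    raise SystemExit(main(["simulate", "--out", str(RESULTS / "cohort.csv"), "--seed", seed]))
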