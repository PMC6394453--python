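#!/usr/bin/env python
"""Statistical calibration of the survival layer.

Checks, under the cohort simulator's own generative model:
* type-I error of the log-rank and Cox Wald tests on null cohorts (HR = 1);
* Cox hazard-ratio recovery without censoring at HR = 6;
* full-pipeline recovery (ROC cutoff → groups → Cox) of HR = 6.

Writes results/calibration.json.  Replicate counts here are the quick
narrative sizes; scripts/acceptance.py runs the full-sized versions.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "scripts"))

from acceptance import cox_recovery, pipeline_recovery, type_one_error  # noqa: E402

SEED = 20180911


def main() -> None:
    results = {}
    results.update(type_one_error(SEED, n_rep=400))
    results["cox_hr_recovered_n2000"] = cox_recovery(SEED + 1)
    results["pipeline_median_hr_n500"] = pipeline_recovery(SEED + 2, n_seeds=50)
    out = ROOT / "results" / "calibration.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(results, indent=2) + "\n")
    print(json.dumps(results, indent=2))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
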