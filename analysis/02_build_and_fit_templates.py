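#!/usr/bin/env python
"""Build the per-side deformable templates and fit every subject mask.

Runs the template and fit stages over the cohort from 01, then summarizes
the modeling quality: Dice overlap of the voxelized fitted surfaces
against the input masks, and mean / maximum vertex-to-boundary distances.
The reference pipeline reports median Dice 0.96 and median mean distances
of 0.22-0.29 mm; the synthetic cohort should reproduce or beat those.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import CONFIG, RESULTS

from hippomorph.pipeline import PipelineRun


def main() -> None:
    logging.basicConfig(level=logging.INFO)
    runner = PipelineRun(CONFIG)
    runner.template()
    reports = runner.fit()

    ok = reports[~reports["failed"]]
    summary = (ok.groupby("side")[["dice", "mean_distance",
                                   "max_distance_fle"]]
               .median().round(4))
    summary.to_csv(RESULTS / "fit_quality_summary.csv")
    print("per-side medians over 50 subjects:")
    print(summary.to_string())
    print(f"\noverall median dice: {ok['dice'].median():.4f} "
          "(reference headline: 0.96)")
    print(f"overall median mean distance: {ok['mean_distance'].median():.4f}"
          " mm (reference worse side: 0.29 mm)")
    print(f"fits needing a ladder refit: {(ok['refit_count'] > 0).sum()}")
    print(f"wrote {RESULTS / 'fit_quality_summary.csv'}")


if __name__ == "__main__":
    main()
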