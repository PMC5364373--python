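#!/usr/bin/env python
"""Volumetry versus local morphometry on a purely local planted effect.

Companion analysis at the statistics level: on a 200-subject synthetic
cohort whose memory score depends only on a localized surface deformation
(never on total volume), the covariate-adjusted hippocampal-volume
regression should be null while the vertex-wise map recovers the planted
cluster — the mechanical demonstration of why surface-based morphometry
can see what volumetry cannot.  Also reports the volume models raw and
adjusted for brain size.
"""

import logging
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import RESULTS

from hippomorph.evaluation import morphology_vs_volumetry
from hippomorph.stats import volume_associations
from hippomorph.synth import make_cohort


def main() -> None:
    logging.basicConfig(level=logging.INFO)
    RESULTS.mkdir(exist_ok=True)
    out = morphology_vs_volumetry(n=200, seed=2)
    print("volume model (covariate-adjusted) for the planted score: "
          f"beta = {out['volume_beta']:+.3f}, p = {out['volume_p']:.3f}, "
          f"95% CI covers zero: {out['volume_ci_covers_zero']}")
    print(f"vertex-wise map: {out['n_clusters']} significant cluster(s); "
          f"planted cluster recovered: {out['cluster_recovered']}")

    cohort = make_cohort(200, seed=2, generate_masks=False)
    tables = []
    for adjust in (False, True):
        t = volume_associations(cohort.phenotypes,
                                ["planted_score", "age11_iq"],
                                adjust_for_brain_size=adjust)
        tables.append(t)
    full = pd.concat(tables, ignore_index=True)
    full.to_csv(RESULTS / "volume_associations.csv", index=False)
    print(full.round(4).to_string(index=False))
    print(f"wrote {RESULTS / 'volume_associations.csv'}")


if __name__ == "__main__":
    main()
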