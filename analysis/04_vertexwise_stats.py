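#!/usr/bin/env python
"""Vertex-wise association of cognition with hippocampal deformation.

Runs the stats stage: for each model (the planted memory score plus the
verbal-memory PCA composite and the spatial span sum), regress the score
on the signed deformation at each of the 4002 vertices with age, sex and
vascular risk as covariates, BH-correct across the map, and extract
sign-consistent significant clusters.  The planted cap should surface as
an FDR-significant cluster for the planted score on the left side; the
key check is whether a cluster peak falls inside the planted vertex set.
"""

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import CONFIG, RESULTS, RUN_DIR

from hippomorph.pipeline import PipelineRun


def main() -> None:
    logging.basicConfig(level=logging.INFO)
    runner = PipelineRun(CONFIG)
    runner.stats()

    # the truth cap is defined on the canonical shape; vertex ids are not
    # comparable across meshes, so transfer it geometrically onto the
    # cohort-built average template
    import trimesh

    from hippomorph.synth import (EffectSpec, ShapeParams, canonical_mesh,
                                  planted_cap_on_mesh)
    avg = trimesh.load(RUN_DIR / "average_template_left.ply", process=False)
    planted = set(planted_cap_on_mesh(
        avg, canonical_mesh(ShapeParams()), EffectSpec(),
        min_weight=0.2).tolist())
    with open(RUN_DIR / "clusters.json") as fh:
        clusters = json.load(fh)
    rows = []
    for key, cls in clusters.items():
        for c in cls:
            overlap = len(planted & set(c["vertex_ids"]))
            rows.append({"model_side": key, "cluster_id": c["cluster_id"],
                         "n_vertices": c["n_vertices"], "sign": c["sign"],
                         "peak_beta": round(c["peak_beta"], 4),
                         "peak_p": c["peak_p"],
                         "peak_in_planted": c["peak_vertex"] in planted,
                         "planted_overlap": overlap})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "cluster_table.csv", index=False)
    if len(table):
        print(table.to_string(index=False))
        hit = table[(table.model_side == "planted_score_left")
                    & table.peak_in_planted]
        print(f"\nplanted cap recovered for the planted score (left): "
              f"{'yes' if len(hit) else 'no'}")
    else:
        print("no FDR-significant clusters at q < "
              f"{CONFIG.q_threshold} in this run: n=50 is underpowered "
              "for a beta=0.3 effect under 4002-way FDR (see 05 for the "
              "n=200 recovery)")
    _report_ground_truth_recovery(sorted(planted))
    print(f"wrote {RESULTS / 'cluster_table.csv'}")


def _report_ground_truth_recovery(cap_ids) -> None:
    """Slope/correlation of cap-mean deformation against planted magnitude."""
    npz = np.load(RUN_DIR / "deformation_matrix_left.npz", allow_pickle=True)
    mat, ids = npz["signed_normal"], list(npz["subject_ids"])
    truth = (pd.read_csv(RUN_DIR / "truth.csv")
             .set_index("subject_id").loc[ids])
    m = truth.planted_magnitude_mm.to_numpy()
    capmean = mat[:, cap_ids].mean(axis=1)
    slope = float(np.polyfit(m, capmean, 1)[0])
    r = float(np.corrcoef(m, capmean)[0, 1])
    print(f"ground-truth recovery: cap-mean deformation vs planted "
          f"magnitude r = {r:.2f}, slope = {slope:.2f} mm/mm")


if __name__ == "__main__":
    main()
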