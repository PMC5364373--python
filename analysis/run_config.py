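"""Shared configuration for the numbered analysis scripts.

All drivers operate on one pipeline run directory under scratch/ (heavy
artifacts: masks, meshes, deformation matrices) and write small summary
tables under results/.
"""

from pathlib import Path

from hippomorph.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

CONFIG = PipelineConfig(output_dir=str(RUN_DIR), n_subjects=50, seed=1,
                        models=("planted_score", "verbal_memory",
                                "spatial_span_total"))
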