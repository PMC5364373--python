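"""End-to-end pipeline orchestration with manifests and stage gating.

Stages: simulate -> template -> fit -> deform -> stats -> report.  Each
stage reads its inputs from the output directory of the previous one, so
any stage can be re-run in isolation; a missing upstream artifact raises
an error naming the stage to run first.  A JSON manifest records every
artifact with a checksum plus the full config snapshot, making any run
regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .deform import align_cohort, average_mesh, compute_deformation
from .masks import VoxelMask
from .meshops import export_vtk_polydata
from .stats import (make_composites, significant_clusters,
                    vertexwise_regression, volume_associations)
from .synth import Cohort, EffectSpec, ShapeParams, make_cohort
from .template_fit import build_template, quality_gate_refit

log = logging.getLogger(__name__)

STAGES = ("simulate", "template", "fit", "deform", "stats", "report")


@dataclass
class PipelineConfig:
    output_dir: str = "hippomorph_run"
    n_subjects: int = 20
    seed: int = 1
    n_vertices: int = 4002
    smoothing_iterations: int = 10
    sides: tuple[str, ...] = ("left", "right")
    q_threshold: float = 0.05
    models: tuple[str, ...] = ("planted_score",)
    covariates: tuple[str, ...] = ("age_days", "sex", "vascular_risk_score")
    shape: dict = field(default_factory=dict)     # ShapeParams overrides
    effect: dict = field(default_factory=dict)    # EffectSpec overrides
    covariate_model: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sides", "models", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sides"] = list(self.sides)
        d["models"] = list(self.models)
        d["covariates"] = list(self.covariates)
        return d

    def shape_params(self) -> ShapeParams:
        allowed = {f.name for f in dataclasses.fields(ShapeParams)}
        bad = set(self.shape) - allowed
        if bad:
            raise ValueError(f"unknown shape keys: {sorted(bad)}")
        kw = dict(self.shape)
        for key in ("semiaxes", "voxel_size", "grid_shape"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return ShapeParams(**kw)

    def effect_spec(self) -> EffectSpec:
        return EffectSpec(**self.effect)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{produced_by}' stage first")
    return path


def _export_mesh(mesh: trimesh.Trimesh, path: Path) -> None:
    path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))


def _load_mesh(path: Path) -> trimesh.Trimesh:
    return trimesh.load(str(path), process=False)


class PipelineRun:
    """Stateful runner over one output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[Path] = []

    # -- helpers --------------------------------------------------------------
    def _track(self, path: Path) -> Path:
        self.artifacts.append(path)
        return path

    def _mask_path(self, sid: str, side: str) -> Path:
        return self.out / "masks" / f"{sid}_{side}.nii.gz"

    # -- stages ---------------------------------------------------------------
    def simulate(self) -> Cohort:
        cfg = self.config
        cohort = make_cohort(cfg.n_subjects, cfg.shape_params(),
                             cfg.effect_spec(), cfg.covariate_model,
                             seed=cfg.seed)
        (self.out / "masks").mkdir(exist_ok=True)
        for sid, sides in zip(cohort.phenotypes["subject_id"], cohort.masks):
            for side, mask in sides.items():
                mask.save(self._track(self._mask_path(sid, side)))
        cohort.phenotypes.to_csv(self._track(self.out / "phenotypes.csv"),
                                 index=False)
        cohort.truth.to_csv(self._track(self.out / "truth.csv"), index=False)
        np.savetxt(self._track(self.out / "cluster_vertices.txt"),
                   cohort.cluster_ids, fmt="%d",
                   header="planted cap vertex ids on the CANONICAL generator "
                          "mesh; not comparable to template vertex ids — use "
                          "planted_cap_on_mesh() to transfer geometrically")
        log.info("simulate: %d subjects written to %s", cfg.n_subjects, self.out)
        return cohort

    def _load_cohort_masks(self, side: str) -> tuple[list[str], list[VoxelMask]]:
        pheno = pd.read_csv(_require(self.out / "phenotypes.csv", "simulate"))
        ids = list(pheno["subject_id"])
        masks = [VoxelMask.load(_require(self._mask_path(s, side), "simulate"))
                 for s in ids]
        return ids, masks

    def template(self) -> dict[str, trimesh.Trimesh]:
        cfg = self.config
        out = {}
        for side in cfg.sides:
            _, masks = self._load_cohort_masks(side)
            tpl = build_template(masks, cfg.n_vertices, cfg.smoothing_iterations)
            _export_mesh(tpl, self._track(self.out / f"template_{side}.ply"))
            out[side] = tpl
            log.info("template %s: %d vertices", side, len(tpl.vertices))
        return out

    def fit(self) -> pd.DataFrame:
        cfg = self.config
        (self.out / "fitted").mkdir(exist_ok=True)
        rows = []
        for side in cfg.sides:
            tpl = _load_mesh(_require(self.out / f"template_{side}.ply",
                                      "template"))
            ids, masks = self._load_cohort_masks(side)
            for sid, mask in zip(ids, masks):
                t0 = time.perf_counter()
                try:
                    mesh, rep = quality_gate_refit(tpl, mask)
                except Exception:
                    log.exception("fit failed for %s/%s; subject excluded",
                                  sid, side)
                    rows.append({"subject_id": sid, "side": side,
                                 "failed": True})
                    continue
                _export_mesh(mesh, self._track(
                    self.out / "fitted" / f"{sid}_{side}.ply"))
                rows.append({"subject_id": sid, "side": side, "failed": False,
                             **rep.as_dict(),
                             "seconds": time.perf_counter() - t0})
                log.info("fit %s/%s: dice=%.3f mean_dist=%.3f mm (%.1fs)",
                         sid, side, rep.dice, rep.mean_distance,
                         rows[-1]["seconds"])
        reports = pd.DataFrame(rows)
        reports.to_csv(self._track(self.out / "fit_reports.csv"), index=False)
        n_failed = int(reports.get("failed", pd.Series(dtype=bool)).sum())
        if n_failed:
            log.warning("%d fits failed and were excluded", n_failed)
        return reports

    def deform(self) -> None:
        cfg = self.config
        pheno = pd.read_csv(_require(self.out / "phenotypes.csv", "simulate"))
        reports = pd.read_csv(_require(self.out / "fit_reports.csv", "fit"))
        (self.out / "deformations").mkdir(exist_ok=True)
        for side in cfg.sides:
            ok = reports[(reports["side"] == side) & (~reports["failed"])]
            ids = list(ok["subject_id"])
            meshes = [_load_mesh(_require(
                self.out / "fitted" / f"{sid}_{side}.ply", "fit"))
                for sid in ids]
            icvs = pheno.set_index("subject_id").loc[ids, "icv_mm3"].to_numpy()
            aligned, transforms = align_cohort(meshes, icvs)
            avg = average_mesh(aligned)
            _export_mesh(avg, self._track(
                self.out / f"average_template_{side}.ply"))
            mat = np.zeros((len(ids), len(avg.vertices)))
            for i, (sid, mesh, tf) in enumerate(zip(ids, meshes, transforms)):
                dm = compute_deformation(avg, mesh, tf, sid, side)
                dm.to_frame().to_csv(self._track(
                    self.out / "deformations" / f"{sid}_{side}.csv"),
                    index=False)
                mat[i] = dm.signed_normal
            np.savez_compressed(self._track(
                self.out / f"deformation_matrix_{side}.npz"),
                signed_normal=mat, subject_ids=np.array(ids))
            sidecar = {
                "format": "numpy .npz",
                "arrays": {
                    "signed_normal": {
                        "shape": list(mat.shape),
                        "dtype": str(mat.dtype),
                        "meaning": "outward-positive deformation (mm), "
                                   "rows = subjects, columns = template "
                                   "vertices"},
                    "subject_ids": {"shape": [len(ids)],
                                    "meaning": "row order of signed_normal"},
                },
            }
            with open(self._track(
                    self.out / f"deformation_matrix_{side}.json"), "w") as fh:
                json.dump(sidecar, fh, indent=2)
            log.info("deform %s: %d subjects, mean |deformation| %.3f mm",
                     side, len(ids), np.abs(mat).mean())

    def stats(self) -> None:
        cfg = self.config
        pheno = pd.read_csv(_require(self.out / "phenotypes.csv", "simulate"))
        pheno = pd.concat([pheno, make_composites(pheno)], axis=1)
        clusters_out = {}
        for side in cfg.sides:
            npz = np.load(_require(
                self.out / f"deformation_matrix_{side}.npz", "deform"),
                allow_pickle=True)
            mat = npz["signed_normal"]
            ids = list(npz["subject_ids"])
            avg = _load_mesh(_require(
                self.out / f"average_template_{side}.ply", "deform"))
            sub = pheno.set_index("subject_id").loc[ids]
            cov = sub[list(cfg.covariates)].to_numpy(dtype=float)
            for model in cfg.models:
                sm = vertexwise_regression(
                    mat, sub[model].to_numpy(dtype=float), cov,
                    model_id=f"{model}_{side}")
                sm.to_frame().to_csv(self._track(
                    self.out / f"stats_{model}_{side}.csv"), index=False)
                export_vtk_polydata(
                    avg, self._track(self.out / f"stats_{model}_{side}.vtk"),
                    {"beta_std": sm.beta_std, "p": sm.p, "q": sm.q})
                cl = significant_clusters(sm, avg, cfg.q_threshold)
                clusters_out[f"{model}_{side}"] = [c.to_dict() for c in cl]
                log.info("stats %s/%s: %d significant clusters",
                         model, side, len(cl))
        with open(self._track(self.out / "clusters.json"), "w") as fh:
            json.dump(clusters_out, fh, indent=2)
        vol = volume_associations(pheno.reset_index(), list(cfg.models))
        vol.to_csv(self._track(self.out / "volume_associations.csv"),
                   index=False)

    def report(self) -> dict:
        manifest = {
            "config": self.config.to_dict(),
            "artifacts": {},
        }
        for path in sorted(self.out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest["artifacts"][str(path.relative_to(self.out))] = \
                    _sha256(path)
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("report: %d artifacts in manifest",
                 len(manifest["artifacts"]))
        return manifest


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the final manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    runner = PipelineRun(config)
    manifest = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("=== stage %s ===", stage)
        result = getattr(runner, stage)()
        if stage == "report":
            manifest = result
    if "report" not in stages:
        manifest = runner.report()
    return manifest
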