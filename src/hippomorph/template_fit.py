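"""Deformable-template construction and progressive surface fitting.

Step 1 builds the side-specific deformable template: coregister the
cohort's binary masks, average them into a probabilistic atlas, extract
the 0.5 iso-surface, smooth it, and remesh to an exact vertex count.

Step 2 fits that template to each subject's mask by progressive
deformation: every iteration moves each vertex by a blend

    step = (1 - alpha) * external + alpha * internal

of an external force (toward the nearest mask boundary along the vertex
normal, with a distance-field-gradient fallback) and an internal
Laplacian restoring force that preserves the template's local point
distribution over a k-ring neighborhood.  The rigidity alpha and the
neighborhood level shrink stage by stage, so large-scale shape is
recovered first and local detail last.  A rotation/scale-invariant
regularization pass follows, and fits whose mean surface distance exceeds
half the voxel size are re-run down a ladder of more flexible schedules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy import ndimage

from .masks import (VoxelMask, signed_distance_field, sample_field,
                    sample_field_gradient, dice_coefficient,
                    surface_to_mask_distances)
from .meshops import as_mesh, mask_to_mesh, taubin_smooth, vertex_normals, voxelize
from .remesh import resample_to_count

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# step 1: atlas and template
# --------------------------------------------------------------------------

def build_probability_atlas(masks: list[VoxelMask]) -> tuple[np.ndarray, VoxelMask]:
    """Average coregistered masks into a voxel-wise occupancy fraction.

    Masks are translation-coregistered (center of mass to the first mask's,
    sub-voxel, linear interpolation) on the first mask's grid; the returned
    atlas value is the fraction of subjects covering each voxel.
    """
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0]
    target_com = ndimage.center_of_mass(ref.data)
    acc = np.zeros(ref.data.shape, dtype=float)
    for m in masks:
        if m.data.shape != ref.data.shape:
            raise ValueError("atlas masks must share a grid")
        shift = np.asarray(target_com) - np.asarray(ndimage.center_of_mass(m.data))
        acc += ndimage.shift(m.data.astype(float), shift, order=1,
                             mode="constant", cval=0.0)
    atlas = np.clip(acc / len(masks), 0.0, 1.0)
    return atlas, ref


def build_template(masks: list[VoxelMask], n_vertices: int = 4002,
                   smoothing_iterations: int = 10) -> trimesh.Trimesh:
    """Atlas -> marching cubes -> Taubin smoothing -> exact-count remesh."""
    atlas, ref = build_probability_atlas(masks)
    if not (atlas >= 0.5).any():
        raise ValueError("atlas has no voxel with occupancy >= 0.5")
    mesh = mask_to_mesh(ref, level=0.5, occupancy=atlas)
    mesh = taubin_smooth(mesh, iterations=smoothing_iterations)
    return resample_to_count(mesh, n_vertices, seed=0)


# --------------------------------------------------------------------------
# step 2: progressive fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitSchedule:
    """Stage ladder of the progressive deformation."""

    alpha_sequence: tuple[float, ...] = (0.9, 0.7, 0.5, 0.3, 0.1)
    neighborhood_levels: tuple[int, ...] = (3, 3, 2, 2, 1)
    step_cap: float = 0.5              # mm per iteration
    max_iterations_per_stage: int = 200
    stall_tolerance: float = 0.01      # mm
    ray_reach: float = 5.0             # mm searched along the normal
    sdf_smooth_sigma_vox: float = 0.5  # occupancy pre-smoothing (re-binarised)
    regularize_rings: int = 2
    regularize_blend: float = 0.5

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_sequence)
        if not (np.all(np.diff(a) < 0) and np.all(a > 0) and np.all(a <= 1)):
            raise ValueError("alpha_sequence must be strictly descending in (0, 1]")
        lv = np.asarray(self.neighborhood_levels)
        if len(lv) != len(a) or np.any(np.diff(lv) > 0) or np.any(lv < 1):
            raise ValueError("neighborhood_levels must be non-increasing, >= 1, "
                             "one per alpha")
        if self.step_cap <= 0:
            raise ValueError("step_cap must be positive")


#: Retry ladder for the half-voxel quality gate: progressively more
#: flexible (lower rigidity floor, longer stages, wider reach).
DEFAULT_SCHEDULE_LADDER = (
    FitSchedule(),
    FitSchedule(alpha_sequence=(0.7, 0.5, 0.3, 0.1, 0.05),
                neighborhood_levels=(3, 2, 2, 1, 1),
                max_iterations_per_stage=300, ray_reach=8.0),
    FitSchedule(alpha_sequence=(0.5, 0.3, 0.15, 0.05, 0.02),
                neighborhood_levels=(2, 2, 1, 1, 1),
                max_iterations_per_stage=400, step_cap=0.75, ray_reach=10.0),
)


@dataclass
class FitReport:
    dice: float = np.nan
    paper_overlap: float = np.nan
    mean_distance: float = np.nan
    max_distance_fle: float = np.nan
    iterations: int = 0
    stages_used: int = 0
    converged: bool = False
    refit_count: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def ring_operators(mesh: trimesh.Trimesh, max_level: int) -> dict[int, sp.csr_matrix]:
    """Row-normalized k-ring neighborhood averaging operators (self excluded)."""
    n = len(mesh.vertices)
    e = np.asarray(mesh.edges_unique)
    adj = sp.coo_matrix((np.ones(2 * len(e)),
                         (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                        shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    ops = {}
    reach = adj + sp.identity(n, format="csr")
    power = reach.copy()
    for k in range(1, max_level + 1):
        ring = power.copy()
        ring.data[:] = 1.0
        ring = ring - sp.identity(n, format="csr")
        ring.eliminate_zeros()
        ring.data[:] = 1.0
        deg = np.asarray(ring.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        ops[k] = sp.diags(1.0 / deg) @ ring
        if k < max_level:
            power = (power @ reach > 0).astype(float).tocsr()
    return ops


def _external_force(verts: np.ndarray, normals: np.ndarray, sdf: np.ndarray,
                    mask: VoxelMask, reach: float, n_samples: int = 21) -> np.ndarray:
    """Displacement toward the nearest boundary crossing along the normal.

    Samples the signed distance field along each vertex normal (both ways)
    and takes the nearest sign change; vertices whose rays miss a crossing
    fall back to a gradient-descent step on the distance field.
    """
    ts = np.linspace(-reach, reach, n_samples)
    pts = verts[:, None, :] + ts[None, :, None] * normals[:, None, :]
    vals = sample_field(sdf, mask, pts.reshape(-1, 3)).reshape(len(verts), n_samples)
    sign_change = vals[:, :-1] * vals[:, 1:] <= 0
    # pick the crossing interval nearest t = 0
    mid = (ts[:-1] + ts[1:]) / 2
    score = np.where(sign_change, np.abs(mid)[None, :], np.inf)
    best = np.argmin(score, axis=1)
    has = np.isfinite(score[np.arange(len(verts)), best])
    v0 = vals[np.arange(len(verts)), best]
    v1 = vals[np.arange(len(verts)), best + 1]
    denom = np.where(np.abs(v1 - v0) < 1e-12, 1.0, v1 - v0)
    t_cross = ts[best] + (ts[best + 1] - ts[best]) * (-v0 / denom)
    ext = t_cross[:, None] * normals
    if not has.all():
        miss = ~has
        g = sample_field_gradient(sdf, mask, verts[miss])
        gn = np.linalg.norm(g, axis=1, keepdims=True)
        gn[gn < 1e-9] = 1.0
        f = sample_field(sdf, mask, verts[miss])
        ext[miss] = -f[:, None] * g / gn
    return ext


def fit_progressive(template: trimesh.Trimesh, mask: VoxelMask,
                    schedule: FitSchedule | None = None,
                    initial_align: bool = True,
                    regularize: bool = True,
                    ) -> tuple[trimesh.Trimesh, FitReport]:
    """Fit the template mesh to a binary mask (correspondence-preserving).

    Returns a mesh with the template's vertex count and faces, plus a
    report of overlap and surface-distance quality metrics.
    """
    schedule = schedule or FitSchedule()
    if mask.is_empty:
        raise ValueError("cannot fit to an empty mask")
    faces = np.asarray(template.faces)
    verts = np.asarray(template.vertices, dtype=float).copy()

    if initial_align:
        verts = _initial_similarity(verts, faces, mask)

    sdf = signed_distance_field(mask, smooth_sigma_vox=schedule.sdf_smooth_sigma_vox)
    ops = ring_operators(template, max(schedule.neighborhood_levels))
    rest = {k: np.asarray(template.vertices) - ops[k] @ np.asarray(template.vertices)
            for k in set(schedule.neighborhood_levels)}

    report = FitReport()
    total_iters = 0
    for stage, (alpha, level) in enumerate(zip(schedule.alpha_sequence,
                                               schedule.neighborhood_levels)):
        op, delta = ops[level], rest[level]
        stalled = False
        for _ in range(schedule.max_iterations_per_stage):
            normals = vertex_normals(verts, faces)
            ext = _external_force(verts, normals, sdf, mask, schedule.ray_reach)
            internal = op @ verts + delta - verts
            step = (1.0 - alpha) * ext + alpha * internal
            norms = np.linalg.norm(step, axis=1, keepdims=True)
            over = norms[:, 0] > schedule.step_cap
            step[over] *= schedule.step_cap / norms[over]
            verts = verts + step
            total_iters += 1
            if np.linalg.norm(step, axis=1).max() < schedule.stall_tolerance:
                stalled = True
                break
        report.stages_used = stage + 1
        log.debug("stage %d (alpha=%.2f, ring=%d): %s", stage, alpha, level,
                  "stalled" if stalled else "iteration budget")
    report.iterations = total_iters
    report.converged = True

    if regularize and schedule.regularize_blend > 0:
        verts = similarity_regularize_vertices(
            np.asarray(template.vertices), verts, ops,
            rings=schedule.regularize_rings, blend=schedule.regularize_blend)

    fitted = as_mesh(verts, faces)
    _fill_metrics(fitted, mask, report)
    return fitted, report


def _initial_similarity(verts: np.ndarray, faces: np.ndarray,
                        mask: VoxelMask) -> np.ndarray:
    """Centroid + cube-root-volume initialization of the template pose.

    Masks are assumed grossly co-oriented (the pipeline's inputs are
    coregistered segmentations), so no initial rotation is estimated.
    """
    mesh = as_mesh(verts, faces)
    scale = (mask.volume_mm3 / max(mesh.volume, 1e-9)) ** (1.0 / 3.0)
    centroid = mesh.vertices.mean(axis=0)
    return (verts - centroid) * scale + mask.centroid_world()


def _fill_metrics(fitted: trimesh.Trimesh, mask: VoxelMask,
                  report: FitReport) -> None:
    vox = voxelize(fitted, mask)
    report.dice = dice_coefficient(vox, mask) if not vox.is_empty else 0.0
    domain = VoxelMask(np.ones(mask.data.shape, dtype=bool), mask.affine)
    from .masks import paper_overlap_index
    report.paper_overlap = paper_overlap_index(vox, mask, domain)
    report.mean_distance, report.max_distance_fle = \
        surface_to_mask_distances(fitted, mask)


# --------------------------------------------------------------------------
# similarity-invariant regularization
# --------------------------------------------------------------------------

def similarity_regularize_vertices(template_verts: np.ndarray,
                                   fitted_verts: np.ndarray,
                                   ops: dict[int, sp.csr_matrix],
                                   rings: int = 2, blend: float = 0.5,
                                   ) -> np.ndarray:
    """Pull each vertex toward its neighborhood's best similarity motion.

    For every vertex, a least-squares rotation+scale+translation is fit
    from the template neighborhood to the fitted neighborhood (vertex
    included); the vertex moves toward that transform's prediction of its
    own position with the given blend weight.  Exact on global similarity
    motions; local outliers are suppressed.
    """
    if blend == 0:
        return fitted_verts.copy()
    op = ops[rings]
    n = len(template_verts)
    out = fitted_verts.copy()
    indptr, indices = op.indptr, op.indices
    sizes = np.diff(indptr)
    # batch the per-vertex Umeyama fits by neighborhood size: each is a
    # 3x3 SVD, so stacking them is orders of magnitude faster than looping
    for k in np.unique(sizes):
        vs = np.where(sizes == k)[0]
        if k < 3:
            if k > 0:
                log.warning("%d vertices have degenerate neighborhoods; "
                            "left unchanged", len(vs))
            continue
        nbr = indices[np.add.outer(indptr[vs], np.arange(k))]   # (B, k)
        ids = np.concatenate([nbr, vs[:, None]], axis=1)        # (B, k+1)
        x = template_verts[ids]                                 # (B, m, 3)
        y = fitted_verts[ids]
        mu_x = x.mean(axis=1, keepdims=True)
        mu_y = y.mean(axis=1, keepdims=True)
        xc, yc = x - mu_x, y - mu_y
        var_x = (xc ** 2).sum(axis=(1, 2)) / x.shape[1]
        cov = np.einsum("bmi,bmj->bij", yc, xc) / x.shape[1]
        u, d, vt = np.linalg.svd(cov)
        flip = np.linalg.det(u) * np.linalg.det(vt) < 0
        s3 = np.ones((len(vs), 3))
        s3[flip, 2] = -1.0
        rot = np.einsum("bij,bj,bjk->bik", u, s3, vt)
        ok = var_x > 1e-18
        scale = np.where(ok, (d * s3).sum(axis=1) / np.where(ok, var_x, 1.0), 1.0)
        trans = mu_y[:, 0, :] - scale[:, None] * np.einsum(
            "bij,bj->bi", rot, mu_x[:, 0, :])
        pred = scale[:, None] * np.einsum(
            "bij,bj->bi", rot, template_verts[vs]) + trans
        good = ok & (scale > 0)
        sel = vs[good]
        out[sel] = (1 - blend) * fitted_verts[sel] + blend * pred[good]
    return out


def similarity_regularize(template: trimesh.Trimesh, fitted: trimesh.Trimesh,
                          rings: int = 2, blend: float = 0.5) -> trimesh.Trimesh:
    """Mesh-level wrapper of :func:`similarity_regularize_vertices`."""
    if len(template.vertices) != len(fitted.vertices):
        raise ValueError("template and fitted mesh must share connectivity")
    ops = ring_operators(template, rings)
    verts = similarity_regularize_vertices(
        np.asarray(template.vertices), np.asarray(fitted.vertices), ops,
        rings=rings, blend=blend)
    return as_mesh(verts, fitted.faces)


# --------------------------------------------------------------------------
# quality gate
# --------------------------------------------------------------------------

def quality_gate_refit(template: trimesh.Trimesh, mask: VoxelMask,
                       ladder: tuple[FitSchedule, ...] = DEFAULT_SCHEDULE_LADDER,
                       retry_budget: int | None = None,
                       ) -> tuple[trimesh.Trimesh, FitReport]:
    """Fit with the half-voxel quality gate and schedule-ladder refits.

    The fit is accepted when the mean vertex-to-boundary distance is at
    most half the largest voxel dimension; otherwise the next (more
    flexible) schedule on the ladder is tried.  Budget exhaustion is
    flagged (converged=False), never raised.
    """
    if retry_budget is None:
        retry_budget = len(ladder) - 1
    half_voxel = float(mask.voxel_size.max()) / 2.0
    best_mesh, best_report = None, None
    for attempt, schedule in enumerate(ladder[:retry_budget + 1]):
        mesh, report = fit_progressive(template, mask, schedule)
        report.refit_count = attempt
        if best_report is None or report.mean_distance < best_report.mean_distance:
            best_mesh, best_report = mesh, report
        if report.mean_distance <= half_voxel:
            best_mesh, best_report = mesh, report
            break
    else:
        if best_report.mean_distance > half_voxel:
            best_report.converged = False
            log.warning("quality gate not met after %d attempts "
                        "(mean distance %.3f mm > %.3f mm)",
                        best_report.refit_count + 1,
                        best_report.mean_distance, half_voxel)
    return best_mesh, best_report
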