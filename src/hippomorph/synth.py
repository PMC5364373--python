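"""Synthetic hippocampus-like cohorts with planted shape-cognition effects.

The generator stands in for an undeposited aging cohort: each subject gets
left/right hippocampus-shaped binary masks (a bent, tapered ellipsoid with
smooth per-subject variability), an intracranial volume, demographic and
vascular-risk covariates, and a battery of cognitive scores.  A localized
inward/outward surface deformation of known magnitude can be planted at a
chosen vertex cluster of the canonical shape, with one cognitive score tied
to it at a configurable standardized effect size — giving every downstream
stage (template fitting, deformation mapping, vertex-wise regression) a
ground truth to recover.

Volume calibration targets the reference means of 3333.80 mm^3 (left) and
3095.29 mm^3 (right); ages cluster tightly around 72.5 y (SD 0.71 y) as in
a single-year birth cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra
from scipy.special import sph_harm_y
from scipy.stats import norm as _norm

from .masks import VoxelMask, normalized_signed_distance, sample_field
from .meshops import mask_to_mesh, taubin_smooth
from .remesh import resample_to_count

LEFT_VOLUME_MM3 = 3333.80
RIGHT_VOLUME_MM3 = 3095.29
ICV_MEAN_MM3 = 1_450_000.0
TBV_MEAN_MM3 = 991_524.60
TBV_SD_MM3 = 89_528.66

#: Table-style prevalences for the vascular-risk items.  The reference
#: table pools "previous stroke (history or imaging)" at 17.9%; here the
#: self-reported stroke item and the imaging infarct item are drawn
#: separately at roughly half that rate each.
VASCULAR_PREVALENCE = {
    "hypertension": 0.4924,
    "diabetes": 0.1055,
    "hypercholesterolemia": 0.4205,
    "cardiovascular_disease": 0.2737,
    "stroke": 0.09,
    "infarct": 0.10,
}
SMOKING_PROBS = (0.4709, 0.4511, 0.0780)  # never, ex, current -> coded 0/1/2

#: (mean, SD) used to scale the synthetic cognitive subtests.
SUBTEST_SCALING = {
    "logical_memory_i": (37.45, 9.5),
    "logical_memory_ii": (37.45, 9.5),
    "verbal_paired_associates_i": (13.7, 5.1),
    "verbal_paired_associates_ii": (13.7, 5.1),
    "spatial_span_forward": (7.4, 1.7),
    "spatial_span_backward": (7.4, 1.7),
    "letter_number_sequencing": (11.03, 3.01),
    "digit_span_backward": (7.90, 2.31),
    "symbol_search": (24.6, 6.2),
    "digit_symbol": (56.5, 12.5),
    "matrix_reasoning": (13.4, 5.0),
    "block_design": (34.0, 10.1),
}
MEMORY_SUBTESTS = ["logical_memory_i", "logical_memory_ii",
                   "verbal_paired_associates_i", "verbal_paired_associates_ii"]
SPEED_SUBTESTS = ["symbol_search", "digit_symbol"]


@dataclass(frozen=True)
class ShapeParams:
    """Geometry of the canonical curved-ellipsoid hippocampus phantom."""

    semiaxes: tuple[float, float, float] = (8.0, 20.0, 5.0)  # mm; long axis = y
    bend_curvature: float = 0.015          # 1/mm, bowing of the long axis in x
    taper: float = 0.35                    # relative thinning toward the tail
    bump_amplitude: float = 0.4            # mm, localized surface bumps
    bump_count: int = 3
    smooth_variation: float = 0.03         # SD of low-order radial perturbation
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.3)  # mm
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    side: str = "left"
    target_volume_mm3: float = LEFT_VOLUME_MM3

    def __post_init__(self) -> None:
        if min(self.semiaxes) <= 0:
            raise ValueError("semiaxes must be positive")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be positive")
        if self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be >= 0")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def mirrored(self, target_volume_mm3: float | None = None) -> "ShapeParams":
        other = "right" if self.side == "left" else "left"
        if target_volume_mm3 is None:
            ratio = RIGHT_VOLUME_MM3 / LEFT_VOLUME_MM3
            target_volume_mm3 = self.target_volume_mm3 * (
                ratio if self.side == "left" else 1.0 / ratio)
        return replace(self, side=other, target_volume_mm3=target_volume_mm3)

    def affine(self) -> np.ndarray:
        """Voxel-to-world affine centering world origin at the grid center."""
        aff = np.diag([*self.voxel_size, 1.0])
        center = (np.asarray(self.grid_shape) - 1) / 2.0
        aff[:3, 3] = -center * np.asarray(self.voxel_size)
        return aff


@dataclass
class EffectSpec:
    """Planted local deformation and its link to a cognitive score."""

    cluster_center: int = 210              # vertex id on the canonical mesh
    cluster_radius: float = 5.0            # mm, geodesic on the canonical mesh
    effect_beta: float = 0.3               # standardized shape-score effect
    noise_sd: float | None = None          # None -> balance total variance to 1
    direction: str = "outward"
    magnitude_sd: float = 1.0              # mm, SD of per-subject magnitude

    def __post_init__(self) -> None:
        if not abs(self.effect_beta) < 1:
            raise ValueError("|effect_beta| must be < 1")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if self.direction not in ("inward", "outward"):
            raise ValueError("direction must be 'inward' or 'outward'")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


DEFAULT_COVARIATE_MODEL = {
    "age_mean_y": 72.50, "age_sd_y": 0.71,
    "sex_p": 0.5,
    "icv_mean_mm3": ICV_MEAN_MM3, "icv_log_sd": 0.09,
    "hippo_log_sd": 0.103,          # hippocampal volume scatter beyond ICV
    "side_log_sd": 0.03,            # independent left/right residual
    "age_weight": -0.10,            # covariate weights on the planted score
    "sex_weight": 0.05,
    "vascular_weight": -0.10,
    "plant_side": "left",
    "memory_loading": 0.85,         # loading of memory subtests on the factor
    "g_loading_speed": 0.80,
    "g_loading_fluid": 0.75,
    "g_loading_wm": 0.70,
    "g_share_of_score": 0.5,        # part of the score's noise shared with g
}


# --------------------------------------------------------------------------
# implicit shape
# --------------------------------------------------------------------------

def _real_sh_basis(direction: np.ndarray) -> np.ndarray:
    """Real degree-2 spherical harmonics (5 columns) of unit directions."""
    x, y, z = direction[:, 0], direction[:, 1], direction[:, 2]
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    cols = []
    for m in range(-2, 3):
        ylm = sph_harm_y(2, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2) * ylm.imag)
        elif m == 0:
            cols.append(ylm.real)
        else:
            cols.append(np.sqrt(2) * ylm.real)
    return np.stack(cols, axis=1)


def _implicit_inside(points: np.ndarray, params: ShapeParams, scale: float,
                     sh_coeffs: np.ndarray | None,
                     bumps: list[tuple[np.ndarray, float]] | None) -> np.ndarray:
    """Inside test for the bent, tapered, perturbed ellipsoid (world mm)."""
    a, b, c = (np.asarray(params.semiaxes) * scale)
    p = np.asarray(points, float).copy()
    if params.side == "right":
        p[:, 0] = -p[:, 0]
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    xb = x - params.bend_curvature * y ** 2 + params.bend_curvature * b ** 2 / 3.0
    t = np.clip(1.0 - params.taper * (y / b + 1.0) / 2.0, 0.2, None)
    u = np.stack([xb / (a * t), y / b, z / (c * t)], axis=1)
    r = np.linalg.norm(u, axis=1)
    eps = np.zeros(len(p))
    safe = r > 1e-9
    if (sh_coeffs is not None and len(sh_coeffs)) or bumps:
        d = np.zeros_like(u)
        d[safe] = u[safe] / r[safe, None]
        if sh_coeffs is not None and len(sh_coeffs):
            eps = eps + _real_sh_basis(d) @ sh_coeffs
        if bumps:
            mean_r = (a * b * c) ** (1.0 / 3.0)
            for center_dir, amp in bumps:
                ang = np.arccos(np.clip(d @ center_dir, -1, 1))
                eps = eps + (amp / mean_r) * np.exp(-(ang / 0.35) ** 2)
    return r <= 1.0 + eps


@lru_cache(maxsize=16)
def _calibration_scale(params: ShapeParams) -> float:
    """Radial scale making the noise-free phantom hit its target volume."""
    grid = _grid_points(params)
    scale = 1.0
    for _ in range(3):
        inside = _implicit_inside(grid, params, scale, None, None)
        vol = inside.sum() * float(np.prod(params.voxel_size))
        if vol == 0:
            raise ValueError("calibration shape vanished from the grid")
        scale *= (params.target_volume_mm3 / vol) ** (1.0 / 3.0)
    return scale


@lru_cache(maxsize=16)
def _grid_points(params: ShapeParams) -> np.ndarray:
    idx = np.indices(params.grid_shape).reshape(3, -1).T.astype(float)
    aff = params.affine()
    return idx @ aff[:3, :3].T + aff[:3, 3]


def make_hippocampus_mask(params: ShapeParams, subject_scale: float = 1.0,
                          seed: int = 0) -> VoxelMask:
    """Generate one hippocampus-like binary mask.

    `subject_scale` multiplies the calibrated radius (so volume scales with
    its cube); `seed` draws the subject's smooth shape variation and bumps.
    Deterministic given (params, subject_scale, seed); the result is a
    single 6-connected component.
    """
    rng = np.random.default_rng(seed)
    sh = rng.normal(0.0, params.smooth_variation, size=5)
    bumps = []
    for _ in range(params.bump_count):
        v = rng.normal(size=3)
        bumps.append((v / np.linalg.norm(v), params.bump_amplitude))
    scale = _calibration_scale(params) * subject_scale
    grid = _grid_points(params)
    inside = _implicit_inside(grid, params, scale, sh, bumps)
    data = inside.reshape(params.grid_shape)
    _check_margin(data, params)
    mask = VoxelMask(data, params.affine())
    if mask.is_empty:
        raise ValueError("generated mask is empty; check scale and grid")
    # keep only the largest 6-connected component (bumps cannot detach it,
    # but extreme perturbations could leave crumbs)
    lab, n = ndimage.label(mask.data)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        mask = VoxelMask(lab == (1 + int(np.argmax(sizes))), mask.affine)
    return mask


def _check_margin(data: np.ndarray, params: ShapeParams, margin: int = 2) -> None:
    axes_names = "xyz"
    for ax in range(3):
        other = tuple(i for i in range(3) if i != ax)
        occupied = np.where(data.any(axis=other))[0]
        if len(occupied) == 0:
            continue
        if occupied[0] < margin or occupied[-1] > data.shape[ax] - 1 - margin:
            raise ValueError(
                f"shape exceeds the grid margin along axis {axes_names[ax]}; "
                "enlarge grid_shape or reduce the shape scale")


@lru_cache(maxsize=8)
def canonical_mesh(params: ShapeParams, n_vertices: int = 4002) -> trimesh.Trimesh:
    """Noise-free unit-scale surface of the phantom, at exact vertex count."""
    noise_free = replace(params, smooth_variation=0.0, bump_count=0)
    mask = make_hippocampus_mask(noise_free, 1.0, seed=0)
    mesh = taubin_smooth(mask_to_mesh(mask), iterations=10)
    return resample_to_count(mesh, n_vertices, seed=0)


def cluster_vertices(mesh: trimesh.Trimesh, center: int, radius_mm: float) -> np.ndarray:
    """Vertex ids within a geodesic radius of `center` (graph distance)."""
    import scipy.sparse as sp

    v = np.asarray(mesh.vertices)
    e = np.asarray(mesh.edges_unique)
    w = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    n = len(v)
    g = sp.coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                     np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
    dist = dijkstra(g.tocsr(), indices=center)
    return np.where(dist <= radius_mm)[0]


# --------------------------------------------------------------------------
# planted deformation
# --------------------------------------------------------------------------

def _geodesic_from_center(canonical: trimesh.Trimesh, center: int) -> np.ndarray:
    import scipy.sparse as sp

    v = np.asarray(canonical.vertices)
    e = np.asarray(canonical.edges_unique)
    w = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    n = len(v)
    g = sp.coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                     np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
    return dijkstra(g.tocsr(), indices=center)


def _cap_weights(points: np.ndarray, canonical: trimesh.Trimesh,
                 spec: EffectSpec) -> np.ndarray:
    """Smooth cap falloff: 1 at the cap center, 0 beyond ~1.5 radius.

    The falloff runs over *geodesic* distance on the canonical surface
    (each query point inherits the weight of its nearest canonical vertex),
    so the weight a surface point sees does not change when the surface is
    displaced along its normal, and the cap stays a localized patch rather
    than a slab through the structure.  Points farther than 1.5 radius from
    the canonical surface get weight zero.
    """
    from scipy.spatial import cKDTree

    cache = getattr(canonical, "_cap_cache", None)
    if cache is None or cache[0] != spec.cluster_center:
        geo = _geodesic_from_center(canonical, spec.cluster_center)
        tree = cKDTree(np.asarray(canonical.vertices))
        canonical._cap_cache = cache = (spec.cluster_center, geo, tree)
    _, geo, tree = cache
    d3, nearest = tree.query(np.atleast_2d(points))
    w = np.exp(-(geo[nearest] / spec.cluster_radius) ** 2)
    w[(geo[nearest] > 1.5 * spec.cluster_radius)
      | (d3 > 1.5 * spec.cluster_radius)] = 0.0
    return w


def _mesh_distance_fn(mask: VoxelMask, n_samples: int = 30000):
    """Callable giving signed distance (mm, positive outside) to the mask's
    smoothed iso-surface.

    The surface is the Taubin-smoothed marching-cubes surface, which
    resolves sub-voxel geometry that the voxel-center EDT cannot; the sign
    comes from the EDT field.
    """
    from scipy.spatial import cKDTree

    surf = taubin_smooth(mask_to_mesh(mask), iterations=5)
    pts, _ = trimesh.sample.sample_surface(surf, n_samples, seed=0)
    cloud = np.vstack([np.asarray(pts), np.asarray(surf.vertices)])
    tree = cKDTree(cloud)
    nsd = normalized_signed_distance(mask)

    def signed(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        d = tree.query(points)[0]
        sign = np.where(sample_field(nsd, mask, points) >= 0, 1.0, -1.0)
        return sign * d

    return signed


def _mesh_signed_distance(mask: VoxelMask, points: np.ndarray) -> np.ndarray:
    return _mesh_distance_fn(mask)(points)


def planted_cap_on_mesh(mesh: trimesh.Trimesh, canonical: trimesh.Trimesh,
                        spec: EffectSpec, min_weight: float = 0.5) -> np.ndarray:
    """Vertex ids of `mesh` lying in the planted cap's world-space region.

    Vertex ids are not comparable between the canonical shape and a
    cohort-built template; the cap must be transferred geometrically, by
    evaluating the planting falloff at the mesh's vertex positions.
    """
    w = _cap_weights(np.asarray(mesh.vertices), canonical, spec)
    return np.where(w > min_weight)[0]


def plant_local_deformation(mask: VoxelMask, canonical: trimesh.Trimesh,
                            spec: EffectSpec, magnitude: float) -> VoxelMask:
    """Push the mask surface outward (+) or pull it inward (−) near the cap.

    Voxel centers in the cap's world-space neighborhood are re-classified
    against the `magnitude x weight(p)` level set of the signed distance to
    the mask's smoothed iso-surface, where the weight is a smooth falloff
    around the cap center.  Voxels outside the neighborhood never change; a
    deformation that would disconnect the mask raises.
    """
    if not np.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    if magnitude == 0.0:
        return VoxelMask(mask.data.copy(), mask.affine)
    idx = np.indices(mask.data.shape).reshape(3, -1).T.astype(float)
    world = mask.index_to_world(idx)
    w = _cap_weights(world, canonical, spec)
    active = w > 1e-3
    # classify by majority over a 2x2x2 sub-voxel sample: binary boundaries
    # lie exactly half a voxel from the nearest centers, and center-only
    # classification would coherently swallow sub-voxel displacements
    offsets = (np.stack(np.meshgrid(*[[-0.25, 0.25]] * 3, indexing="ij"),
                        axis=-1).reshape(-1, 3) @ mask.affine[:3, :3].T)
    sd_fn = _mesh_distance_fn(mask)
    votes = np.zeros(active.sum())
    for off in offsets:
        pts = world[active] + off
        votes += (sd_fn(pts) - magnitude * _cap_weights(pts, canonical, spec) < 0)
    new = mask.data.copy().reshape(-1)
    new[active] = votes >= len(offsets) / 2.0
    out = VoxelMask(new.reshape(mask.data.shape), mask.affine)
    if out.is_empty or out.n_components() != 1:
        raise ValueError("planted deformation disconnected or erased the mask")
    return out


def measure_planted_magnitude(before: VoxelMask, after: VoxelMask,
                              canonical: trimesh.Trimesh, spec: EffectSpec) -> float:
    """Recover the planted magnitude from the two masks' distance fields.

    Weighted least squares of the per-point boundary displacement against
    the planting falloff, restricted to the cap core (weight > 0.5): in the
    skirt the intended sub-voxel displacement falls below what a binary
    grid can represent, which would bias the estimate downward.
    """
    verts = np.asarray(canonical.vertices)
    w_v = _cap_weights(verts, canonical, spec)
    sel = w_v > 0.5
    pts = verts[sel]
    w = w_v[sel]
    delta = (_mesh_signed_distance(before, pts)
             - _mesh_signed_distance(after, pts))
    return float((w * delta).sum() / (w ** 2).sum())


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

PHENOTYPE_COLUMNS = (
    ["subject_id", "age_days", "sex", "icv_mm3", "total_brain_volume_mm3",
     "left_hippocampal_volume_mm3", "right_hippocampal_volume_mm3"]
    + list(VASCULAR_PREVALENCE) + ["smoking", "vascular_risk_score"]
    + list(SUBTEST_SCALING) + ["age11_iq", "planted_score"]
)
TRUTH_COLUMNS = ["subject_id", "planted_magnitude_mm", "measured_magnitude_mm",
                 "latent_score_z"]

#: SD of a standard normal truncated at +-2 (the planted-magnitude law):
#: sqrt(1 - 4 phi(2) / (2 Phi(2) - 1))
_TRUNC2_SD = float(np.sqrt(
    1.0 - 4.0 * _norm.pdf(2.0) / (2.0 * _norm.cdf(2.0) - 1.0)))



@dataclass
class Cohort:
    """Masks, phenotypes and ground truth of one synthetic sample."""

    masks: list[dict[str, VoxelMask]]
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    cluster_ids: np.ndarray
    params: ShapeParams
    spec: EffectSpec
    canonical: trimesh.Trimesh | None = None


def _subject_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Counter-scheme sub-seeding: stable under cohort-size changes."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(index, stream)))


def make_cohort(n: int, params: ShapeParams | None = None,
                spec: EffectSpec | None = None,
                covariate_model: dict | None = None,
                seed: int = 0, measure_truth: bool = False,
                generate_masks: bool = True) -> Cohort:
    """Generate a full synthetic cohort with a planted shape-score effect.

    With ``generate_masks=False`` only phenotypes and truth are produced
    (volumes become analytic rather than voxel counts); the random stream
    is identical either way, so the two modes agree on every phenotype.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    params = params or ShapeParams()
    spec = spec or EffectSpec()
    cm = dict(DEFAULT_COVARIATE_MODEL)
    cm.update(covariate_model or {})

    canon = canonical_mesh(params) if (n > 0 and generate_masks) else None
    cl_ids = (cluster_vertices(canon, spec.cluster_center, spec.cluster_radius)
              if canon is not None else np.array([], dtype=int))
    params_r = params.mirrored() if params.side == "left" else params
    params_l = params if params.side == "left" else params.mirrored()

    beta = spec.effect_beta
    w_age, w_sex, w_vasc = cm["age_weight"], cm["sex_weight"], cm["vascular_weight"]
    explained = beta ** 2 + w_age ** 2 + w_sex ** 2 + w_vasc ** 2
    noise_sd = spec.noise_sd if spec.noise_sd is not None else \
        float(np.sqrt(max(1.0 - explained, 0.05)))
    g_share = min(cm["g_share_of_score"] * noise_sd, noise_sd)
    uniq_sd = float(np.sqrt(noise_sd ** 2 - g_share ** 2))

    masks: list[dict[str, VoxelMask]] = []
    pheno_rows, truth_rows = [], []
    for i in range(n):
        rng = _subject_rng(seed, i)
        age_days = rng.normal(cm["age_mean_y"], cm["age_sd_y"]) * 365.25
        sex = int(rng.random() < cm["sex_p"])
        items = {k: int(rng.random() < p) for k, p in VASCULAR_PREVALENCE.items()}
        smoking = int(rng.choice(3, p=SMOKING_PROBS))
        vasc = sum(items.values()) + smoking
        icv = cm["icv_mean_mm3"] * np.exp(
            rng.normal(-cm["icv_log_sd"] ** 2 / 2, cm["icv_log_sd"]))
        hippo_factor = np.exp(rng.normal(0.0, cm["hippo_log_sd"]))
        tbv = TBV_MEAN_MM3 * (icv / cm["icv_mean_mm3"]) * np.exp(
            rng.normal(0.0, 0.035))

        # truncate at +-2 SD: a 1x1x1.3 mm grid cannot faithfully carry
        # larger local displacements, and deformations beyond ~2 mm are
        # implausible for the structure anyway
        m_mm = float(np.clip(rng.normal(0.0, spec.magnitude_sd),
                             -2 * spec.magnitude_sd, 2 * spec.magnitude_sd))
        signed_m = m_mm if spec.direction == "outward" else -m_mm
        z_m = m_mm / (spec.magnitude_sd * _TRUNC2_SD)

        g = rng.normal()
        eps = rng.normal()
        z_age = (age_days / 365.25 - cm["age_mean_y"]) / cm["age_sd_y"]
        z_vasc = (vasc - 2.2) / 1.3
        score = (beta * z_m + w_age * z_age + w_sex * (sex - 0.5) * 2
                 + w_vasc * z_vasc + g_share * g + uniq_sd * eps)

        side_masks: dict[str, VoxelMask] = {}
        side_volumes: dict[str, float] = {}
        for side, p_side in (("left", params_l), ("right", params_r)):
            vol_factor = (icv / cm["icv_mean_mm3"]) * hippo_factor * np.exp(
                rng.normal(0.0, cm["side_log_sd"]))
            sub_scale = vol_factor ** (1.0 / 3.0)
            mask_seed = int(rng.integers(2 ** 31))
            if not generate_masks:
                side_volumes[side] = p_side.target_volume_mm3 * vol_factor
                continue
            mask = make_hippocampus_mask(p_side, sub_scale, seed=mask_seed)
            if side == cm["plant_side"] and signed_m != 0.0 and canon is not None:
                planted = plant_local_deformation(mask, canon, spec, signed_m)
                if measure_truth:
                    measured = measure_planted_magnitude(mask, planted, canon, spec)
                else:
                    measured = np.nan
                mask = planted
            side_masks[side] = mask
            side_volumes[side] = mask.volume_mm3
        if generate_masks:
            masks.append(side_masks)

        subtests = _draw_subtests(rng, score, g, cm)
        age11 = 100.0 + 13.88 * (0.7 * g + np.sqrt(1 - 0.49) * rng.normal())
        row = {"subject_id": f"S{i:04d}", "age_days": age_days, "sex": sex,
               "icv_mm3": icv, "total_brain_volume_mm3": tbv,
               "left_hippocampal_volume_mm3": side_volumes["left"],
               "right_hippocampal_volume_mm3": side_volumes["right"],
               **items, "smoking": smoking, "vascular_risk_score": vasc,
               **subtests, "age11_iq": age11, "planted_score": score}
        pheno_rows.append(row)
        truth_rows.append({"subject_id": f"S{i:04d}", "planted_magnitude_mm": signed_m,
                           "measured_magnitude_mm": measured if (measure_truth and signed_m != 0) else np.nan,
                           "latent_score_z": z_m})

    phenotypes = pd.DataFrame(pheno_rows, columns=PHENOTYPE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return Cohort(masks, phenotypes, truth, cl_ids, params, spec, canon)


def _draw_subtests(rng: np.random.Generator, score: float, g: float,
                   cm: dict) -> dict[str, float]:
    """Battery of correlated subtests; memory carries the planted score."""
    lam = cm["memory_loading"]
    out: dict[str, float] = {}
    for name in MEMORY_SUBTESTS:
        z = lam * score + np.sqrt(1 - lam ** 2) * rng.normal()
        mu, sd = SUBTEST_SCALING[name]
        out[name] = mu + sd * z
    groups = {
        "spatial_span_forward": ("mix", 0.6), "spatial_span_backward": ("mix", 0.6),
        "letter_number_sequencing": ("g", cm["g_loading_wm"]),
        "digit_span_backward": ("g", cm["g_loading_wm"]),
        "symbol_search": ("g", cm["g_loading_speed"]),
        "digit_symbol": ("g", cm["g_loading_speed"]),
        "matrix_reasoning": ("g", cm["g_loading_fluid"]),
        "block_design": ("g", cm["g_loading_fluid"]),
    }
    for name, (kind, load) in groups.items():
        base = 0.5 * score + 0.5 * g if kind == "mix" else g
        z = load * base + np.sqrt(max(1 - load ** 2, 0.0)) * rng.normal()
        mu, sd = SUBTEST_SCALING[name]
        out[name] = mu + sd * z
    return out
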