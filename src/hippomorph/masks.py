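"""Binary voxel masks in world coordinates.

A :class:`VoxelMask` couples a binary 3-D grid with the affine mapping
voxel indices to world millimetres, the convention NIfTI uses.  Voxel
*centers* map through the affine; anisotropic voxel sizes (e.g. the
1 x 1 x 1.3 mm grids typical of coronal T1 acquisitions) are respected by
every distance computation via the affine's column norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class VoxelMask:
    """Binary 3-D volume plus voxel-to-world affine.

    Parameters
    ----------
    data:
        Boolean occupancy grid (i, j, k).
    affine:
        4x4 voxel-index -> world-mm transform (voxel centers).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        """Foreground voxel count times voxel volume."""
        return self.n_foreground * self.voxel_volume

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    # ---- coordinate helpers -------------------------------------------------
    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def centroid_world(self) -> np.ndarray:
        idx = np.argwhere(self.data)
        if idx.size == 0:
            raise ValueError("empty mask has no centroid")
        return self.index_to_world(idx.mean(axis=0))[0]

    def n_components(self, connectivity: int = 1) -> int:
        structure = ndimage.generate_binary_structure(3, connectivity)
        _, n = ndimage.label(self.data, structure=structure)
        return int(n)

    # ---- I/O ----------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VoxelMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0.5, img.affine)


def _check_same_grid(a: VoxelMask, b: VoxelMask) -> None:
    if a.data.shape != b.data.shape or not np.allclose(a.affine, b.affine):
        raise ValueError("masks are on different grids")


def dice_coefficient(a: VoxelMask, b: VoxelMask) -> float:
    """Standard Dice overlap 2|A∩B| / (|A| + |B|).

    Both masks must share grid and affine.  Returns 1.0 for identical
    nonempty masks and 0.0 for disjoint ones.
    """
    _check_same_grid(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        raise ValueError("both masks are empty")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def paper_overlap_index(a: VoxelMask, b: VoxelMask, domain: VoxelMask) -> float:
    """Voxel accuracy (TP + TN) / domain size over an explicit domain.

    This is the literal "true positives and negatives over all positives
    and negatives" formula sometimes quoted alongside Dice; it depends on
    the chosen domain and is reported next to Dice, never instead of it.
    """
    _check_same_grid(a, b)
    _check_same_grid(a, domain)
    union = np.logical_or(a.data, b.data)
    if not np.all(domain.data[union]):
        raise ValueError("domain must contain the union of both masks")
    n_dom = domain.n_foreground
    tp = int(np.logical_and(a.data, b.data).sum())
    tn = int(np.logical_and(domain.data, ~union).sum())
    return (tp + tn) / n_dom


def signed_distance_field(mask: VoxelMask, smooth_sigma_vox: float = 0.0) -> np.ndarray:
    """Signed Euclidean distance (mm, positive outside) on the mask grid.

    Computed as EDT(background) - EDT(foreground) with anisotropic voxel
    sampling; the zero level of the trilinearly interpolated field tracks
    the binary boundary.  An optional Gaussian pre-smoothing of the
    occupancy (re-binarised at 0.5) suppresses single-voxel staircase
    roughness before the transform.
    """
    occ = mask.data.astype(float)
    if smooth_sigma_vox > 0:
        occ = ndimage.gaussian_filter(occ, sigma=smooth_sigma_vox)
    binary = occ > 0.5
    if not binary.any():
        binary = mask.data  # smoothing must not erase a small mask
    sampling = mask.voxel_size
    d_out = ndimage.distance_transform_edt(~binary, sampling=sampling)
    d_in = ndimage.distance_transform_edt(binary, sampling=sampling)
    return d_out - d_in


def normalized_signed_distance(mask: VoxelMask,
                               sdf: np.ndarray | None = None) -> np.ndarray:
    """Grid signed distance (mm) to the mask *boundary*, bias-corrected.

    The raw EDT difference F has slope ~2 across the boundary (distances
    are measured center-to-center); dividing by |∇F| clipped to [1, 2]
    yields a field whose values near the boundary approximate the true
    signed distance to it, which is what sub-voxel surface edits need.
    """
    if sdf is None:
        sdf = signed_distance_field(mask)
    grads = np.gradient(sdf, *mask.voxel_size)
    g = np.sqrt(sum(gr ** 2 for gr in grads))
    return sdf / np.clip(g, 1.0, 2.0)


def sample_field(field: np.ndarray, mask: VoxelMask, points_world: np.ndarray,
                 order: int = 1) -> np.ndarray:
    """Trilinearly sample a grid-aligned scalar field at world-mm points."""
    idx = mask.world_to_index(points_world)
    return ndimage.map_coordinates(field, idx.T, order=order, mode="nearest")


def sample_field_gradient(field: np.ndarray, mask: VoxelMask,
                          points_world: np.ndarray) -> np.ndarray:
    """World-space gradient (per mm) of a grid field at world points."""
    vs = mask.voxel_size
    grads = np.gradient(field, *vs)  # central differences, mm spacing
    idx = mask.world_to_index(points_world).T
    g_vox = np.stack([ndimage.map_coordinates(g, idx, order=1, mode="nearest")
                      for g in grads], axis=1)
    # gradient axes follow voxel axes; rotate into world orientation
    directions = mask.affine[:3, :3] / vs  # unit columns
    return g_vox @ directions.T


def distance_to_boundary(mask: VoxelMask, points_world: np.ndarray,
                         sdf: np.ndarray | None = None) -> np.ndarray:
    """Unsigned distance (mm) from points to the mask's boundary surface.

    Near the boundary this is the Newton estimate |F| / |∇F| of the
    distance to the zero level of the signed field F: the center-to-center
    EDT difference has slope ~2 across the boundary, and dividing by the
    sampled gradient magnitude removes that bias exactly where precision
    matters.  Away from the boundary (|∇F| -> 1) the EDT measures distance
    to the nearest foreground voxel *center*, which overestimates the
    distance to the digitized surface by h/4 in expectation over the
    sub-voxel digitization phase; that offset is blended out by (2 - |∇F|).
    """
    if mask.is_empty:
        raise ValueError("empty mask has no boundary")
    if sdf is None:
        sdf = signed_distance_field(mask)
    # points beyond the grid: sample at the clamped location and add the
    # world-space excess (a lower bound that is exact for distant outliers)
    idx = mask.world_to_index(points_world)
    clamped = np.clip(idx, 0.0, np.asarray(mask.data.shape) - 1.0)
    excess = np.linalg.norm((idx - clamped) @ mask.affine[:3, :3].T, axis=1)
    inside_pts = mask.index_to_world(clamped)
    f = sample_field(sdf, mask, inside_pts)
    g = np.linalg.norm(sample_field_gradient(sdf, mask, inside_pts), axis=1)
    g = np.clip(g, 1.0, 2.0)
    h = float(np.mean(mask.voxel_size))
    return np.maximum(0.0, np.abs(f) - 0.25 * h * (2.0 - g)) / g + excess


def surface_to_mask_distances(mesh, mask: VoxelMask,
                              sdf: np.ndarray | None = None) -> tuple[float, float]:
    """(mean, max) unsigned vertex-to-mask-boundary distance in mm.

    The max over vertices is the fiducial localization error of the fit.
    """
    d = distance_to_boundary(mask, np.asarray(mesh.vertices), sdf=sdf)
    return float(d.mean()), float(d.max())
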