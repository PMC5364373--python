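"""Mesh extraction, smoothing, voxelization and mesh-level metrics.

Meshes live in world millimetres as :class:`trimesh.Trimesh` objects with
outward-oriented faces.  Extraction runs marching cubes on the occupancy
grid in index space and maps vertices through the mask affine, so
anisotropic voxels come out correctly scaled.
"""

from __future__ import annotations

import logging

import numpy as np
import trimesh
from skimage import measure

from .masks import VoxelMask

log = logging.getLogger(__name__)


def as_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Build a Trimesh without any automatic processing/merging."""
    return trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                           faces=np.asarray(faces, dtype=np.int64),
                           process=False)


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Fix winding so face normals point outward (positive volume)."""
    m = mesh.copy()
    trimesh.repair.fix_normals(m)
    if m.volume < 0:
        m.invert()
    return m


def mask_to_mesh(mask: VoxelMask, level: float = 0.5,
                 occupancy: np.ndarray | None = None) -> trimesh.Trimesh:
    """Extract the iso-surface of a binary mask (or occupancy field).

    Marching cubes at `level` on the occupancy grid, padded by one voxel so
    shapes touching the grid edge still close, then mapped to world mm.
    """
    occ = mask.data.astype(float) if occupancy is None else np.asarray(occupancy, float)
    if not (occ > level).any():
        raise ValueError("empty mask: no voxel above the iso-level")
    padded = np.pad(occ, 1, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(padded, level=level)
    verts = verts - 1.0  # undo padding offset, back to voxel-index space
    world = verts @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    mesh = as_mesh(world, faces)
    mesh = ensure_outward(mesh)
    if not mesh.is_watertight:
        mesh.process(validate=True)
        mesh = ensure_outward(mesh)
        if not mesh.is_watertight:
            raise ValueError("marching cubes produced a non-watertight surface")
    return mesh


def taubin_smooth(mesh: trimesh.Trimesh, iterations: int = 10,
                  lamb: float = 0.5, nu: float = 0.53) -> trimesh.Trimesh:
    """Taubin lambda/mu smoothing (volume-preserving, no shrinkage).

    Topology and vertex count are unchanged; iterations=0 is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    trimesh.smoothing.filter_taubin(out, lamb=lamb, nu=nu, iterations=iterations)
    return as_mesh(out.vertices, out.faces)


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted outward vertex normals (unit length)."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces)
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area weighted
    n = np.zeros_like(v)
    for c in range(3):
        np.add.at(n, f[:, c], fn)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def voxelize(mesh: trimesh.Trimesh, reference: VoxelMask) -> VoxelMask:
    """Scan-convert a closed mesh onto a reference grid.

    A voxel is foreground iff its center lies inside the surface, decided
    by parity of ray crossings along the k axis in index space.  Ray
    origins are jittered by a sub-micron irrational offset so rays cannot
    hit mesh edges or vertices exactly.
    """
    if not mesh.is_watertight:
        raise ValueError("voxelize requires a closed (watertight) mesh")
    inv = np.linalg.inv(reference.affine)
    verts = np.asarray(mesh.vertices) @ inv[:3, :3].T + inv[:3, 3]
    tri = verts[np.asarray(mesh.faces)]  # (F, 3, 3) in index space
    shape = reference.data.shape
    out = np.zeros(shape, dtype=bool)

    lo = np.floor(verts.min(axis=0)).astype(int)
    hi = np.ceil(verts.max(axis=0)).astype(int)
    if np.any(hi < 0) or np.any(lo > np.array(shape) - 1):
        log.warning("mesh lies entirely outside the reference grid")
        return VoxelMask(out, reference.affine)
    lo = np.clip(lo, 0, np.array(shape) - 1)
    hi = np.clip(hi, 0, np.array(shape) - 1)

    ii = np.arange(lo[0], hi[0] + 1)
    jj = np.arange(lo[1], hi[1] + 1)
    cols = np.stack(np.meshgrid(ii, jj, indexing="ij"), axis=-1).reshape(-1, 2)
    jit = np.array([np.sqrt(2) * 1e-4, np.sqrt(3) * 1e-4])
    q = cols.astype(float) + jit  # (P, 2) jittered ray origins in (i, j)

    # 2-D barycentric test of every column against every triangle, chunked
    p0, p1, p2 = tri[:, 0], tri[:, 1], tri[:, 2]
    crossings_col: list[np.ndarray] = []
    crossings_z: list[np.ndarray] = []
    chunk = 512
    for s in range(0, len(tri), chunk):
        a, b, c = p0[s:s + chunk], p1[s:s + chunk], p2[s:s + chunk]
        det = ((b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0])
               + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1]))  # (T,)
        ok = np.abs(det) > 1e-12
        if not ok.any():
            continue
        a, b, c, det = a[ok], b[ok], c[ok], det[ok]
        dx = q[:, None, 0] - c[None, :, 0]  # (P, T)
        dy = q[:, None, 1] - c[None, :, 1]
        w0 = ((b[:, 1] - c[:, 1])[None, :] * dx + (c[:, 0] - b[:, 0])[None, :] * dy) / det
        w1 = ((c[:, 1] - a[:, 1])[None, :] * dx + (a[:, 0] - c[:, 0])[None, :] * dy) / det
        w2 = 1.0 - w0 - w1
        inside = (w0 > 0) & (w1 > 0) & (w2 > 0)
        pi, ti = np.nonzero(inside)
        if len(pi):
            z = (w0[pi, ti] * a[ti, 2] + w1[pi, ti] * b[ti, 2] + w2[pi, ti] * c[ti, 2])
            crossings_col.append(pi)
            crossings_z.append(z)
    if not crossings_col:
        return VoxelMask(out, reference.affine)
    pi = np.concatenate(crossings_col)
    z = np.concatenate(crossings_z)
    order = np.lexsort((z, pi))
    pi, z = pi[order], z[order]
    starts = np.searchsorted(pi, np.arange(len(cols)))
    ends = np.searchsorted(pi, np.arange(len(cols)) + 1)
    kmax = shape[2] - 1
    for p, (s, e) in enumerate(zip(starts, ends)):
        zs = z[s:e]
        if len(zs) % 2:  # grazing numerical artifact; drop the odd crossing
            continue
        i, j = cols[p]
        for z0, z1 in zip(zs[0::2], zs[1::2]):
            k0 = max(int(np.ceil(z0)), 0)
            k1 = min(int(np.floor(z1)), kmax)
            if k1 >= k0:
                out[i, j, k0:k1 + 1] = True
    return VoxelMask(out, reference.affine)


def hausdorff_distance(a: trimesh.Trimesh, b: trimesh.Trimesh,
                       n_samples: int = 4000, seed: int = 0) -> float:
    """Symmetric surface-to-surface Hausdorff distance (sampled, mm)."""
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    pa = _surface_points(a, n_samples, rng)
    pb = _surface_points(b, n_samples, rng)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def _surface_points(mesh: trimesh.Trimesh, n: int, rng) -> np.ndarray:
    pts, _ = trimesh.sample.sample_surface(mesh, n, seed=int(rng.integers(2**31)))
    return np.vstack([np.asarray(pts), np.asarray(mesh.vertices)])


def euler_characteristic(mesh: trimesh.Trimesh) -> int:
    return int(len(mesh.vertices) - len(mesh.edges_unique) + len(mesh.faces))


def export_vtk_polydata(mesh: trimesh.Trimesh, path,
                        point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a legacy-ASCII VTK PolyData file with per-vertex scalars.

    Enough of the format for surface viewers (ParaView etc.) to render
    beta/p/q maps painted on the template.
    """
    v = np.asarray(mesh.vertices)
    f = np.asarray(mesh.faces)
    lines = ["# vtk DataFile Version 3.0", "surface map", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(v)} float"]
    lines += [" ".join(f"{x:.6f}" for x in p) for p in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in f]
    if point_data:
        lines.append(f"POINT_DATA {len(v)}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(v):
                raise ValueError(f"point data '{name}' length mismatch")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.8g}" for x in values]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
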