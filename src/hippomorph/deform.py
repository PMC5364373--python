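"""Cohort alignment, sample-average template, per-vertex deformation.

Steps 3 and 4 of the shape chain: fitted meshes (all sharing the
template's connectivity) are head-size-normalized by the cube root of the
ICV ratio, Procrustes-aligned to a reference, and averaged vertex-wise
into the sample-specific template.  That average is then mapped back into
each subject's native space to yield the per-vertex deformation: the
3-vector from template point to subject point and its signed projection
on the template's outward normal (outward positive), which is the scalar
the statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .align import SimilarityTransform, similarity_procrustes
from .meshops import as_mesh, vertex_normals


@dataclass
class DeformationMap:
    """Per-vertex deformation of one subject/side in native mm."""

    subject_id: str
    side: str
    vectors: np.ndarray            # (V, 3), subject minus mapped template
    signed_normal: np.ndarray      # (V,), outward-positive projection
    transform_to_template: SimilarityTransform

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vertex": np.arange(len(self.signed_normal)),
            "dx_mm": self.vectors[:, 0], "dy_mm": self.vectors[:, 1],
            "dz_mm": self.vectors[:, 2], "signed_normal_mm": self.signed_normal,
        })


def align_cohort(fitted: list[trimesh.Trimesh], icvs: list[float],
                 reference_index: int = 0,
                 ) -> tuple[list[trimesh.Trimesh], list[SimilarityTransform]]:
    """ICV-scale and Procrustes-align fitted meshes to a reference subject.

    Each mesh is first scaled isotropically about its centroid by
    (ICV_ref / ICV_subject)^(1/3), then rigidly aligned (rotation and
    translation; scale is already accounted for) to the reference mesh
    using the shared vertex correspondence.  Returns the aligned meshes
    and, for each subject, the similarity transform mapping the subject's
    *native* mesh into the aligned space.
    """
    if not fitted:
        raise ValueError("empty cohort")
    n_ref = len(fitted[reference_index].vertices)
    icvs = np.asarray(icvs, dtype=float)
    if len(icvs) != len(fitted) or np.any(icvs <= 0):
        raise ValueError("need one positive ICV per mesh")

    scaled = []
    pre = []
    for mesh, icv in zip(fitted, icvs):
        if len(mesh.vertices) != n_ref:
            raise ValueError("all meshes must share the template connectivity")
        s = (icvs[reference_index] / icv) ** (1.0 / 3.0)
        centroid = np.asarray(mesh.vertices).mean(axis=0)
        verts = (np.asarray(mesh.vertices) - centroid) * s + centroid
        scaled.append(verts)
        pre.append(SimilarityTransform(np.eye(3), s, centroid * (1.0 - s)))

    ref_verts = scaled[reference_index]
    aligned, transforms = [], []
    for verts, pre_tf, mesh in zip(scaled, pre, fitted):
        tf_rigid, _ = similarity_procrustes(verts, ref_verts, allow_scale=False)
        aligned_verts = tf_rigid.apply(verts)
        aligned.append(as_mesh(aligned_verts, fitted[reference_index].faces))
        transforms.append(tf_rigid.compose(pre_tf))
    return aligned, transforms


def average_mesh(aligned: list[trimesh.Trimesh]) -> trimesh.Trimesh:
    """Vertex-wise arithmetic mean; connectivity taken from the first mesh."""
    if not aligned:
        raise ValueError("empty mesh list")
    n = len(aligned[0].vertices)
    if any(len(m.vertices) != n for m in aligned):
        raise ValueError("meshes must share connectivity")
    verts = np.mean([np.asarray(m.vertices) for m in aligned], axis=0)
    return as_mesh(verts, aligned[0].faces)


def compute_deformation(average_template: trimesh.Trimesh,
                        subject_mesh_native: trimesh.Trimesh,
                        subject_transform: SimilarityTransform,
                        subject_id: str = "", side: str = "left",
                        ) -> DeformationMap:
    """Deformation of a subject's surface from the sample-average template.

    The average template is mapped through the inverse subject transform
    into native space; vectors are subject minus mapped-template vertex,
    and the signed scalar is the projection on the mapped template's
    outward vertex normal.
    """
    if len(average_template.vertices) != len(subject_mesh_native.vertices):
        raise ValueError("template and subject mesh must share connectivity")
    inv = subject_transform.inverse()
    mapped = inv.apply(np.asarray(average_template.vertices))
    vectors = np.asarray(subject_mesh_native.vertices) - mapped
    normals = vertex_normals(mapped, np.asarray(average_template.faces))
    signed = np.einsum("ij,ij->i", vectors, normals)
    return DeformationMap(subject_id, side, vectors, signed,
                          subject_transform)


def deformation_matrix(maps: list[DeformationMap]) -> np.ndarray:
    """Stack signed-normal scalars into an (n_subjects, V) matrix."""
    return np.vstack([m.signed_normal for m in maps])
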