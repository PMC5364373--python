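"""Cohort alignment, mesh averaging, and per-vertex deformation maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hippomorph.align import SimilarityTransform
from hippomorph.deform import (align_cohort, average_mesh,
                               compute_deformation)
from hippomorph.meshops import as_mesh, vertex_normals


@pytest.fixture(scope="module")
def tpl(canonical):
    return canonical


def _perturbed_copies(mesh, n, scale=0.2, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        v = np.asarray(mesh.vertices) + rng.normal(0, scale,
                                                   (len(mesh.vertices), 3))
        out.append(as_mesh(v, mesh.faces))
    return out


class TestAlignCohort:
    def test_single_mesh_gets_identity(self, tpl):
        aligned, tfs = align_cohort([tpl], [1.4e6])
        assert np.allclose(aligned[0].vertices, tpl.vertices)
        assert tfs[0].scale == pytest.approx(1.0)
        assert np.allclose(tfs[0].rotation, np.eye(3), atol=1e-9)

    def test_icv_scaling_equalizes_icv_proportional_volumes(self, tpl):
        # a subject whose hippocampus is exactly ICV-proportional to the
        # reference's must land on the reference volume after cube-root
        # ICV normalization
        icvs = [1.2e6, 1.5e6]
        s = (icvs[1] / icvs[0]) ** (1.0 / 3.0)
        bigger = as_mesh(np.asarray(tpl.vertices) * s, tpl.faces)
        aligned, _ = align_cohort([tpl.copy(), bigger], icvs)
        assert aligned[0].volume == pytest.approx(aligned[1].volume,
                                                  rel=1e-6)

    def test_rotation_is_recovered(self, tpl):
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        rotated = as_mesh(np.asarray(tpl.vertices) @ rot.T, tpl.faces)
        aligned, _ = align_cohort([tpl, rotated], [1.4e6, 1.4e6])
        rms = np.sqrt(((np.asarray(aligned[1].vertices)
                        - np.asarray(tpl.vertices)) ** 2).sum(1).mean())
        assert rms < 1e-6

    def test_transform_maps_native_to_aligned(self, tpl):
        rot = Rotation.from_euler("y", 20, degrees=True).as_matrix()
        native = as_mesh(1.1 * np.asarray(tpl.vertices) @ rot.T + 3.0,
                         tpl.faces)
        aligned, tfs = align_cohort([tpl, native], [1.4e6, 1.4e6])
        assert np.allclose(tfs[1].apply(np.asarray(native.vertices)),
                           np.asarray(aligned[1].vertices), atol=1e-9)

    def test_connectivity_mismatch_rejected(self, tpl):
        import trimesh
        other = trimesh.creation.icosphere(2)
        with pytest.raises(ValueError, match="connectivity"):
            align_cohort([tpl, other], [1.0e6, 1.0e6])


class TestAverageMesh:
    def test_identical_inputs_average_to_themselves(self, tpl):
        avg = average_mesh([tpl, tpl.copy()])
        assert np.allclose(avg.vertices, tpl.vertices)
        assert len(avg.vertices) == len(tpl.vertices)

    def test_symmetric_pair_averages_to_midpoint(self, tpl):
        delta = np.random.default_rng(1).normal(0, 0.5,
                                                np.asarray(tpl.vertices).shape)
        plus = as_mesh(np.asarray(tpl.vertices) + delta, tpl.faces)
        minus = as_mesh(np.asarray(tpl.vertices) - delta, tpl.faces)
        avg = average_mesh([plus, minus])
        assert np.allclose(avg.vertices, tpl.vertices, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_mesh([])


class TestComputeDeformation:
    def test_identity_subject_has_zero_deformation(self, tpl):
        tf = SimilarityTransform.identity()
        dm = compute_deformation(tpl, tpl, tf)
        assert np.abs(dm.vectors).max() < 1e-12
        assert np.abs(dm.signed_normal).max() < 1e-12

    def test_uniform_inflation_is_positive_one(self, tpl):
        normals = vertex_normals(np.asarray(tpl.vertices),
                                 np.asarray(tpl.faces))
        inflated = as_mesh(np.asarray(tpl.vertices) + normals, tpl.faces)
        dm = compute_deformation(tpl, inflated,
                                 SimilarityTransform.identity())
        assert 0.9 <= dm.signed_normal.mean() <= 1.1

    def test_erosion_is_negative(self, tpl):
        normals = vertex_normals(np.asarray(tpl.vertices),
                                 np.asarray(tpl.faces))
        eroded = as_mesh(np.asarray(tpl.vertices) - 0.8 * normals, tpl.faces)
        dm = compute_deformation(tpl, eroded, SimilarityTransform.identity())
        assert dm.signed_normal.mean() < -0.6

    def test_signed_scalar_is_projection_of_vector(self, tpl):
        meshes = _perturbed_copies(tpl, 1, scale=0.4)[0]
        dm = compute_deformation(tpl, meshes, SimilarityTransform.identity())
        inv_mapped = np.asarray(tpl.vertices)
        normals = vertex_normals(inv_mapped, np.asarray(tpl.faces))
        assert np.allclose(dm.signed_normal,
                           np.einsum("ij,ij->i", dm.vectors, normals),
                           atol=1e-9)

    def test_rigid_motion_invariance_of_signed_normal(self, tpl):
        subject = _perturbed_copies(tpl, 1, scale=0.3, seed=5)[0]
        tf0 = SimilarityTransform.identity()
        dm0 = compute_deformation(tpl, subject, tf0)
        rot = Rotation.from_euler("xyz", [12, 33, -8], degrees=True).as_matrix()
        trans = np.array([4.0, -2.0, 9.0])
        moved = as_mesh(np.asarray(subject.vertices) @ rot.T + trans,
                        subject.faces)
        motion = SimilarityTransform(rot, 1.0, trans)
        # native mesh moved rigidly; its transform to template space gains
        # the inverse motion
        tf1 = tf0.compose(motion.inverse())
        dm1 = compute_deformation(tpl, moved, tf1)
        assert np.allclose(dm0.signed_normal, dm1.signed_normal, atol=1e-9)

    def test_planted_outward_cap_recovered_through_the_fit_chain(
            self, left_template, canonical, default_params):
        """A +1 mm planted cap survives mask digitization and fitting."""
        from hippomorph.synth import (EffectSpec, make_hippocampus_mask,
                                      plant_local_deformation,
                                      planted_cap_on_mesh)
        from hippomorph.template_fit import quality_gate_refit
        spec = EffectSpec()
        base = make_hippocampus_mask(default_params, 1.0, seed=1)
        planted = plant_local_deformation(base, canonical, spec, 1.0)
        f0, _ = quality_gate_refit(left_template, base)
        f1, _ = quality_gate_refit(left_template, planted)
        normals = vertex_normals(np.asarray(f0.vertices),
                                 np.asarray(f0.faces))
        diff = np.einsum("ij,ij->i",
                         np.asarray(f1.vertices) - np.asarray(f0.vertices),
                         normals)
        cap = planted_cap_on_mesh(f0, canonical, spec, min_weight=0.8)
        touched = planted_cap_on_mesh(f0, canonical, spec, min_weight=1e-6)
        off = np.setdiff1d(np.arange(len(diff)), touched)
        assert 0.6 <= diff[cap].mean() <= 1.3
        assert abs(diff[off].mean()) <= 0.2

    def test_cohort_mean_deformation_is_zero_against_average(self, tpl):
        meshes = _perturbed_copies(tpl, 8, scale=0.3, seed=2)
        aligned, tfs = align_cohort(meshes, [1.4e6] * 8)
        avg = average_mesh(aligned)
        vecs = np.zeros((8, len(avg.vertices), 3))
        for i, (mesh, tf) in enumerate(zip(meshes, tfs)):
            vecs[i] = compute_deformation(avg, mesh, tf).vectors
        # deformations live in native spaces, but each subject's alignment is
        # near-identity here, so the vertex-wise mean must vanish
        assert np.abs(vecs.mean(axis=0)).max() < 0.05
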