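"""Atlas averaging, template construction, progressive fitting, refit gate."""

import numpy as np
import pytest
from scipy import ndimage

from hippomorph.masks import VoxelMask, dice_coefficient
from hippomorph.meshops import euler_characteristic, voxelize
from hippomorph.template_fit import (FitSchedule, build_probability_atlas,
                                     build_template, fit_progressive,
                                     quality_gate_refit, ring_operators,
                                     similarity_regularize)


class TestProbabilityAtlas:
    def test_identical_masks_reproduce_the_mask(self, left_masks):
        atlas, ref = build_probability_atlas([left_masks[0]] * 3)
        assert set(np.unique(np.round(atlas, 6))) <= {0.0, 1.0}
        assert np.array_equal(atlas > 0.5, left_masks[0].data)

    def test_translation_is_recovered_by_coregistration(self, left_masks):
        m = left_masks[0]
        shifted = VoxelMask(np.roll(m.data, (3, 2, 1), axis=(0, 1, 2)),
                            m.affine)
        atlas, _ = build_probability_atlas([m, shifted])
        inside = ndimage.binary_erosion(m.data, iterations=2)
        assert atlas[inside].min() >= 0.95

    def test_values_within_unit_interval(self, left_masks):
        atlas, _ = build_probability_atlas(left_masks)
        assert atlas.min() >= 0.0 and atlas.max() <= 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_probability_atlas([])


class TestBuildTemplate:
    def test_exact_default_vertex_count(self, left_template):
        assert len(left_template.vertices) == 4002

    def test_genus_zero(self, left_template):
        assert euler_characteristic(left_template) == 2
        assert left_template.is_watertight

    def test_single_mask_cohort_round_trip(self, left_masks):
        tpl = build_template([left_masks[0]])
        vox = voxelize(tpl, left_masks[0])
        assert dice_coefficient(vox, left_masks[0]) >= 0.95


class TestFitSchedule:
    def test_alpha_must_descend(self):
        with pytest.raises(ValueError, match="descending"):
            FitSchedule(alpha_sequence=(0.5, 0.7),
                        neighborhood_levels=(2, 1))

    def test_levels_must_match_and_not_increase(self):
        with pytest.raises(ValueError, match="neighborhood"):
            FitSchedule(alpha_sequence=(0.9, 0.5),
                        neighborhood_levels=(1, 2))


class TestRingOperators:
    def test_first_ring_matches_edge_adjacency(self, left_template):
        ops = ring_operators(left_template, 2)
        row = ops[1][0].toarray().ravel()
        neighbors = set(left_template.vertex_neighbors[0])
        assert set(np.nonzero(row)[0]) == neighbors
        assert row.sum() == pytest.approx(1.0)

    def test_rings_grow(self, left_template):
        ops = ring_operators(left_template, 3)
        n1 = (ops[1][10].toarray() > 0).sum()
        n3 = (ops[3][10].toarray() > 0).sum()
        assert n3 > n1


class TestFitProgressive:
    def test_self_fit_is_near_identity(self, left_template, left_masks):
        tvox = voxelize(left_template, left_masks[0])
        fitted, rep = fit_progressive(left_template, tvox,
                                      initial_align=False)
        assert rep.mean_distance < 0.2
        disp = np.linalg.norm(np.asarray(fitted.vertices)
                              - np.asarray(left_template.vertices), axis=1)
        assert (disp < 0.65).mean() >= 0.99

    def test_correspondence_preserved(self, left_template, left_masks):
        fitted, _ = fit_progressive(left_template, left_masks[1])
        assert len(fitted.vertices) == len(left_template.vertices)
        assert np.array_equal(fitted.faces, left_template.faces)

    def test_dilated_mask_pulls_surface_outward(self, left_template,
                                                left_masks):
        from hippomorph.meshops import vertex_normals
        mask = left_masks[0]
        dilated = VoxelMask(ndimage.binary_dilation(mask.data), mask.affine)
        f0, _ = fit_progressive(left_template, mask)
        f1, _ = fit_progressive(left_template, dilated)
        normals = vertex_normals(np.asarray(f0.vertices),
                                 np.asarray(f0.faces))
        signed = np.einsum("ij,ij->i",
                           np.asarray(f1.vertices) - np.asarray(f0.vertices),
                           normals)
        assert signed.mean() > 0.1

    def test_empty_mask_rejected(self, left_template):
        empty = VoxelMask(np.zeros((8, 8, 8), dtype=bool), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            fit_progressive(left_template, empty)


class TestSimilarityRegularize:
    def test_exact_on_global_similarity_motion(self, left_template):
        from hippomorph.meshops import as_mesh
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [15, -10, 40], degrees=True)
        verts = 1.25 * np.asarray(left_template.vertices) @ rot.as_matrix().T
        moved = as_mesh(verts + [2.0, -1.0, 4.0], left_template.faces)
        reg = similarity_regularize(left_template, moved, rings=2, blend=1.0)
        resid = np.abs(np.asarray(reg.vertices) - np.asarray(moved.vertices))
        assert resid.max() < 1e-6

    def test_single_outlier_is_suppressed(self, left_template):
        from hippomorph.meshops import as_mesh
        verts = np.asarray(left_template.vertices).copy()
        verts[50] += np.array([3.0, 0.0, 0.0])
        reg = similarity_regularize(left_template,
                                    as_mesh(verts, left_template.faces),
                                    rings=2, blend=0.5)
        moved = np.linalg.norm(np.asarray(reg.vertices)
                               - np.asarray(left_template.vertices), axis=1)
        assert moved[50] < 3.0
        assert np.delete(moved, 50).max() < 3.0

    def test_zero_blend_is_identity(self, left_template):
        from hippomorph.meshops import as_mesh
        verts = np.asarray(left_template.vertices) + 0.3
        moved = as_mesh(verts, left_template.faces)
        reg = similarity_regularize(left_template, moved, rings=2, blend=0.0)
        assert np.array_equal(np.asarray(reg.vertices), verts)


@pytest.fixture(scope="module")
def hard_mask(left_masks):
    # anisotropic dilation produces a shape the initial similarity
    # placement cannot match, so a one-iteration fit fails the gate
    m = left_masks[1]
    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[:, 1, 1] = True
    return VoxelMask(ndimage.binary_dilation(m.data, structure=struct,
                                             iterations=4), m.affine)


class TestQualityGate:
    def test_good_fit_needs_no_refit(self, left_template, left_masks):
        _, rep = quality_gate_refit(left_template, left_masks[0])
        assert rep.refit_count == 0
        assert rep.mean_distance <= 0.65
        assert rep.converged

    def test_crippled_first_schedule_triggers_refit(self, left_template,
                                                    hard_mask):
        bad = FitSchedule(alpha_sequence=(0.999,), neighborhood_levels=(3,),
                          max_iterations_per_stage=1)
        good = FitSchedule()
        _, rep0 = fit_progressive(left_template, hard_mask, bad)
        assert rep0.mean_distance > 0.65
        _, rep = quality_gate_refit(left_template, hard_mask,
                                    ladder=(bad, good))
        assert rep.refit_count == 1
        assert rep.mean_distance < rep0.mean_distance
        assert rep.mean_distance <= 0.65

    def test_exhausted_budget_is_flagged_not_raised(self, left_template,
                                                    hard_mask):
        bad = FitSchedule(alpha_sequence=(0.999,), neighborhood_levels=(3,),
                          max_iterations_per_stage=1)
        _, rep = quality_gate_refit(left_template, hard_mask,
                                    ladder=(bad,), retry_budget=0)
        assert not rep.converged
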