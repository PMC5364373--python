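"""Composites, vertex-wise GLM, FDR, clusters, volume associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hippomorph.stats import (G_MEMORY_TESTS, VERBAL_MEMORY_TESTS,
                              VertexStatsMap, bh_fdr, first_component_scores,
                              make_composites, significant_clusters,
                              vascular_risk_score, vertexwise_regression,
                              volume_associations)
from hippomorph.synth import make_cohort


def _ols_oracle(y, X):
    """Closed-form normal equations with classic OLS inference."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    return beta, se, p


class TestVascularRiskScore:
    def _rec(self, **kw):
        base = dict(hypertension=0, diabetes=0, hypercholesterolemia=0,
                    cardiovascular_disease=0, stroke=0, infarct=0, smoking=0)
        base.update(kw)
        return base

    def test_all_absent_is_zero(self):
        assert vascular_risk_score(self._rec()) == 0

    def test_hypertension_current_smoker_infarct_is_four(self):
        rec = self._rec(hypertension=1, smoking=2, infarct=1)
        assert vascular_risk_score(rec) == 4

    def test_maximum_is_eight(self):
        rec = self._rec(hypertension=1, diabetes=1, hypercholesterolemia=1,
                        cardiovascular_disease=1, stroke=1, infarct=1,
                        smoking=2)
        assert vascular_risk_score(rec) == 8

    @pytest.mark.parametrize("bad", [dict(smoking=3), dict(hypertension=2)])
    def test_out_of_range_coding_rejected(self, bad):
        with pytest.raises(ValueError):
            vascular_risk_score(self._rec(**bad))


class TestFirstComponent:
    def test_identical_columns_explain_everything(self):
        col = np.random.default_rng(0).normal(size=50)
        scores, loadings, ve = first_component_scores(
            np.column_stack([col, col, col]))
        assert ve == pytest.approx(100.0)
        assert np.allclose(loadings, loadings[0])

    def test_two_columns_with_known_correlation(self):
        # construct exact sample correlation r = 0.6; leading eigenvalue of
        # the 2x2 correlation matrix is 1 + r, so 80% variance explained
        rng = np.random.default_rng(1)
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        b -= np.polyval(np.polyfit(a, b, 1), a)  # exactly decorrelated
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        x2 = 0.6 * a + np.sqrt(1 - 0.36) * b
        _, _, ve = first_component_scores(np.column_stack([a, x2]))
        assert ve == pytest.approx(80.0, abs=1e-6)

    def test_planted_one_factor_structure(self):
        rng = np.random.default_rng(2)
        k, n, lam = 4, 3000, 0.8
        f = rng.normal(size=n)
        x = lam * f[:, None] + np.sqrt(1 - lam ** 2) * rng.normal(size=(n, k))
        _, loadings, ve = first_component_scores(x)
        expected = 100 * (lam ** 2 + (1 - lam ** 2) / k)
        assert abs(ve - expected) < 5.0
        assert (loadings > 0.7).all()

    def test_sign_convention_first_column_positive(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100, 3))
        x[:, 1] = x[:, 0] + 0.1 * x[:, 1]
        _, l1, _ = first_component_scores(x)
        _, l2, _ = first_component_scores(-x)
        assert l1[0] > 0 and l2[0] > 0

    def test_constant_column_rejected(self):
        x = np.random.default_rng(4).normal(size=(30, 2))
        x[:, 1] = 2.5
        with pytest.raises(ValueError, match="constant"):
            first_component_scores(x)


class TestComposites:
    def test_spatial_span_is_a_plain_sum(self):
        coh = make_cohort(20, seed=4, generate_masks=False)
        df = coh.phenotypes.copy()
        df.loc[0, "spatial_span_forward"] = 8.0
        df.loc[0, "spatial_span_backward"] = 7.0
        comp = make_composites(df)
        assert comp.loc[0, "spatial_span_total"] == 15.0

    def test_perfectly_correlated_battery_loads_fully(self):
        coh = make_cohort(30, seed=5, generate_masks=False)
        df = coh.phenotypes.copy()
        for c in VERBAL_MEMORY_TESTS[1:]:
            df[c] = df[VERBAL_MEMORY_TESTS[0]]
        _, loadings, _ = first_component_scores(
            df[VERBAL_MEMORY_TESTS].to_numpy())
        assert np.allclose(loadings, 1.0)

    def test_missing_column_named_in_error(self):
        coh = make_cohort(10, seed=6, generate_masks=False)
        df = coh.phenotypes.drop(columns=["digit_symbol"])
        with pytest.raises(ValueError, match="digit_symbol"):
            make_composites(df)

    def test_synthetic_memory_battery_has_high_loadings(self):
        coh = make_cohort(300, seed=7, generate_masks=False)
        _, loadings, ve = first_component_scores(
            coh.phenotypes[VERBAL_MEMORY_TESTS].to_numpy())
        assert (loadings > 0.75).all()
        assert ve > 60.0


class TestVertexwiseRegression:
    def test_perfect_predictor_gives_unit_standardized_beta(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(40, 10))
        m = vertexwise_regression(d, d[:, 3].copy(), None)
        assert m.beta_std[3] == pytest.approx(1.0)
        assert m.p[3] < 1e-30

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n, V, c = 50, 12, 3
            d = rng.normal(size=(n, V))
            cov = rng.normal(size=(n, c))
            y = rng.normal(size=n)
            m = vertexwise_regression(d, y, cov)
            sd_y = y.std(ddof=1)
            for v in range(V):
                X = np.column_stack([np.ones(n), cov, d[:, v]])
                beta, se, p = _ols_oracle(y, X)
                scale = d[:, v].std(ddof=1) / sd_y
                assert m.beta_std[v] == pytest.approx(beta[-1] * scale,
                                                      abs=1e-8)
                assert m.se[v] == pytest.approx(se[-1] * scale, abs=1e-8)
                assert m.p[v] == pytest.approx(p[-1], abs=1e-8)

    def test_null_response_false_positive_rate(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=(200, 1000))
        y = rng.normal(size=200)
        m = vertexwise_regression(d, y, None)
        assert 0.03 <= (m.p < 0.05).mean() <= 0.07

    def test_direction_swap_preserves_t_and_p(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=(60, 30))
        y = 0.4 * d[:, 0] + rng.normal(size=60)
        m1 = vertexwise_regression(d, y, None, "deformation_as_predictor")
        m2 = vertexwise_regression(d, y, None, "deformation_as_response")
        np.testing.assert_allclose(m1.p, m2.p, atol=1e-12)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(10)
        d = rng.normal(size=(30, 5))
        cov = rng.normal(size=(30, 2))
        cov = np.column_stack([cov, cov[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear|rank"):
            vertexwise_regression(d, rng.normal(size=30), cov)

    def test_listwise_deletion_reported_in_n(self):
        rng = np.random.default_rng(11)
        d = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        y[3] = np.nan
        m = vertexwise_regression(d, y, None)
        assert m.n == 39


class TestBhFdr:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_bruteforce_step_up(self):
        def brute(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                q[i] = running
            return q

        rng = np.random.default_rng(13)
        for _ in range(200):
            p = rng.random(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)

    def test_never_decreases_p(self):
        rng = np.random.default_rng(14)
        p = rng.random(500)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestClusters:
    def _stats_map(self, canonical, beta, p):
        q = bh_fdr(p)
        return VertexStatsMap("m", "deformation_as_predictor",
                              beta, np.ones_like(beta), p, q, n=100)

    def test_no_significant_vertices_gives_empty_list(self, canonical):
        nv = len(canonical.vertices)
        m = self._stats_map(canonical, np.zeros(nv), np.ones(nv) * 0.9)
        assert significant_clusters(m, canonical) == []

    def test_single_cap_forms_one_cluster_containing_center(self, canonical):
        from hippomorph.synth import cluster_vertices
        nv = len(canonical.vertices)
        cap = cluster_vertices(canonical, 210, 4.0)
        beta = np.zeros(nv)
        p = np.ones(nv) * 0.8
        beta[cap] = 0.3
        p[cap] = 1e-8
        cl = significant_clusters(self._stats_map(canonical, beta, p),
                                  canonical)
        assert len(cl) == 1
        assert 210 in cl[0].vertex_ids
        assert cl[0].sign == "outward"
        assert cl[0].surface_area_mm2 > 0

    def test_opposite_signed_caps_split_into_two_clusters(self, canonical):
        from hippomorph.synth import cluster_vertices
        verts = np.asarray(canonical.vertices)
        far = int(np.argmax(np.linalg.norm(verts - verts[210], axis=1)))
        cap1 = cluster_vertices(canonical, 210, 4.0)
        cap2 = cluster_vertices(canonical, far, 4.0)
        nv = len(verts)
        beta, p = np.zeros(nv), np.ones(nv) * 0.8
        beta[cap1], p[cap1] = 0.3, 1e-8
        beta[cap2], p[cap2] = -0.4, 1e-9
        cl = significant_clusters(self._stats_map(canonical, beta, p),
                                  canonical)
        assert len(cl) == 2
        assert {c.sign for c in cl} == {"inward", "outward"}
        assert cl[0].peak_beta == pytest.approx(-0.4)  # ordered by |beta|


@pytest.fixture(scope="module")
def pheno():
    return make_cohort(150, seed=15, generate_masks=False).phenotypes


class TestVolumeAssociations:
    def test_scaled_copy_correlates_perfectly(self, pheno):
        df = pheno.copy()
        df["fake"] = df["left_hippocampal_volume_mm3"] * 0.001 + 5
        out = volume_associations(df, ["fake"])
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)

    def test_residualized_volume_orthogonal_to_brain_size(self, pheno):
        vol = pheno["left_hippocampal_volume_mm3"].to_numpy()
        tbv = pheno["total_brain_volume_mm3"].to_numpy()
        X = np.column_stack([np.ones(len(tbv)), tbv])
        resid = vol - X @ np.linalg.lstsq(X, vol, rcond=None)[0]
        assert abs(np.corrcoef(resid, tbv)[0, 1]) < 1e-10

    def test_reports_one_row_per_phenotype(self, pheno):
        out = volume_associations(pheno, ["planted_score", "age11_iq"],
                                  adjust_for_brain_size=True)
        assert list(out["phenotype"]) == ["planted_score", "age11_iq"]
        assert out["brain_size_adjusted"].all()
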