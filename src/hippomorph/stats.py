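"""Vertex-wise shape statistics, cognitive composites, FDR and clusters.

The central operation regresses, at every template vertex, a cognitive
score on the signed surface deformation (or the reverse, e.g. when
childhood ability is the predictor of late-life shape), always adjusting
for age in days, sex, and the aggregate vascular-risk score.  Effect
sizes are standardized betas (coefficient x SD(predictor)/SD(response));
p-values are Benjamini-Hochberg adjusted across the vertices of one map,
and FDR-significant vertices are grouped into sign-consistent connected
clusters on the template mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SMOKING_CODES = (0, 1, 2)  # never, ex, current
VASCULAR_BINARY_ITEMS = ("hypertension", "diabetes", "hypercholesterolemia",
                         "cardiovascular_disease", "stroke")

#: default column sets for the domain composites
VERBAL_MEMORY_TESTS = ["logical_memory_i", "logical_memory_ii",
                       "verbal_paired_associates_i", "verbal_paired_associates_ii"]
G_MEMORY_TESTS = VERBAL_MEMORY_TESTS + ["spatial_span_forward",
                                        "spatial_span_backward"]
G_SPEED_TESTS = ["symbol_search", "digit_symbol"]
G_TESTS = ["symbol_search", "digit_symbol", "matrix_reasoning",
           "letter_number_sequencing", "digit_span_backward", "block_design"]


# --------------------------------------------------------------------------
# phenotype derivations
# --------------------------------------------------------------------------

def vascular_risk_score(record) -> int:
    """Aggregate vascular risk in [0, 8]: five self-reported binaries
    (hypertension, diabetes, high cholesterol, cardiovascular disease,
    previous stroke) + smoking status (never/ex/current = 0/1/2) + presence
    of an old infarct on imaging (0/1).

    Accepts a mapping/Series with the item columns; raises if any item is
    outside its coding range.
    """
    total = 0
    for item in VASCULAR_BINARY_ITEMS + ("infarct",):
        v = int(record[item])
        if v not in (0, 1):
            raise ValueError(f"{item} must be coded 0/1, got {v}")
        total += v
    smoking = int(record["smoking"])
    if smoking not in SMOKING_CODES:
        raise ValueError(f"smoking must be coded 0/1/2, got {smoking}")
    return total + smoking


def first_component_scores(score_matrix,
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """First unrotated principal component of a correlation-matrix PCA.

    Columns are standardized internally; returns per-row scores scaled to
    SD 1, the loadings (correlations of each column with the component,
    sign-oriented so the first column loads positively), and the percent
    of variance the component explains.
    """
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    if np.isnan(x).any():
        raise ValueError("missing values; apply listwise deletion first")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        raise ValueError("constant column in PCA input")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    lam = evals[-1]
    if lead[0] < 0:
        lead = -lead
    raw = z @ lead
    scores = raw / raw.std(ddof=1)
    loadings = lead * np.sqrt(lam)
    variance_explained = 100.0 * lam / x.shape[1]
    return scores, loadings, float(variance_explained)


def make_composites(records: pd.DataFrame,
                    verbal_memory_tests: list[str] | None = None,
                    g_tests: list[str] | None = None,
                    g_speed_tests: list[str] | None = None,
                    g_memory_tests: list[str] | None = None) -> pd.DataFrame:
    """Cognitive composites: spatial span sum plus PCA-based domain scores.

    spatial = spatial span forward + backward (a plain sum); the verbal
    memory composite and the g / g-speed / g-memory domain scores are first
    unrotated PCA components over their configured test batteries.
    """
    need = ["spatial_span_forward", "spatial_span_backward"]
    for col in need:
        if col not in records.columns:
            raise ValueError(f"missing required column: {col}")
    out = pd.DataFrame(index=records.index)
    out["spatial_span_total"] = (records["spatial_span_forward"]
                                 + records["spatial_span_backward"])
    batteries = {
        "verbal_memory": verbal_memory_tests or VERBAL_MEMORY_TESTS,
        "g": g_tests or G_TESTS,
        "g_speed": g_speed_tests or G_SPEED_TESTS,
        "g_memory": g_memory_tests or G_MEMORY_TESTS,
    }
    for name, cols in batteries.items():
        missing = [c for c in cols if c not in records.columns]
        if missing:
            raise ValueError(f"missing required column: {missing[0]}")
        scores, _, _ = first_component_scores(records[cols].to_numpy())
        out[name] = scores
    return out


# --------------------------------------------------------------------------
# vertex-wise regression
# --------------------------------------------------------------------------

@dataclass
class VertexStatsMap:
    """Per-vertex GLM results for one model and one direction."""

    model_id: str
    direction: str                # deformation_as_predictor | _as_response
    beta_std: np.ndarray
    se: np.ndarray
    p: np.ndarray
    q: np.ndarray = field(default=None)
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"vertex": np.arange(len(self.beta_std)),
                             "beta_std": self.beta_std, "se": self.se,
                             "p": self.p, "q": self.q})


def vertexwise_regression(deformations: np.ndarray, phenotype: np.ndarray,
                          covariates: np.ndarray | None = None,
                          direction: str = "deformation_as_predictor",
                          model_id: str = "model",
                          fdr: bool = True) -> VertexStatsMap:
    """OLS at every vertex with covariate adjustment.

    With deformation as predictor, the phenotype is regressed on
    [intercept, covariates, deformation_v]; the reversed direction swaps
    predictor and response.  Estimation uses Frisch-Waugh-Lovell
    residualization on the shared covariate block, which is algebraically
    identical to the full per-vertex OLS but runs vectorized across all
    vertices.  Standardized betas are coefficient x SD(x)/SD(y); p-values
    are two-sided t tests; q-values are BH-adjusted across the map.
    """
    d = np.asarray(deformations, dtype=float)
    y0 = np.asarray(phenotype, dtype=float)
    if d.ndim != 2 or len(y0) != d.shape[0]:
        raise ValueError("deformations must be (n, V) matching phenotype length")
    if direction not in ("deformation_as_predictor", "deformation_as_response"):
        raise ValueError(f"unknown direction: {direction}")
    n = d.shape[0]
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
    keep = ~(np.isnan(y0) | np.isnan(d).any(axis=1) | np.isnan(c).any(axis=1))
    d, y0, c = d[keep], y0[keep], c[keep]
    n = len(y0)
    n_cov = c.shape[1]
    if n <= n_cov + 2:
        raise ValueError("too few complete observations for the design")

    design = np.column_stack([np.ones(n), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate design (collinear columns)")
    # residualize both sides on [1, covariates]
    coef_d, *_ = np.linalg.lstsq(design, d, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y0, rcond=None)
    d_res = d - design @ coef_d
    y_res = y0 - design @ coef_y

    if direction == "deformation_as_predictor":
        x_res, resp_res = d_res, y_res[:, None]
        sd_x = d.std(axis=0, ddof=1)
        sd_y = np.full(d.shape[1], y0.std(ddof=1))
    else:
        x_res, resp_res = y_res[:, None], d_res
        sd_x = np.full(d.shape[1], y0.std(ddof=1))
        sd_y = d.std(axis=0, ddof=1)

    sxx = (x_res ** 2).sum(axis=0)
    sxy = (x_res * resp_res).sum(axis=0)
    sxx, sxy = np.broadcast_arrays(sxx, sxy)
    bad = sxx < 1e-24
    sxx_safe = np.where(bad, 1.0, sxx)
    b = sxy / sxx_safe
    resid = resp_res - x_res * b
    df = n - n_cov - 2
    sigma2 = (resid ** 2).sum(axis=0) / df
    se_raw = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_raw > 0, b / se_raw, np.inf * np.sign(b))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    sd_y_safe = np.where(sd_y < 1e-24, 1.0, sd_y)
    beta_std = b * sd_x / sd_y_safe
    se_std = se_raw * sd_x / sd_y_safe
    beta_std[bad] = np.nan
    p[bad] = 1.0
    out = VertexStatsMap(model_id, direction, beta_std, se_std, p, n=n)
    out.q = bh_fdr(np.nan_to_num(p, nan=1.0)) if fdr else None
    return out


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


# --------------------------------------------------------------------------
# clusters
# --------------------------------------------------------------------------

@dataclass
class ClusterReport:
    cluster_id: int
    vertex_ids: np.ndarray
    peak_vertex: int
    peak_beta: float
    peak_p: float
    peak_q: float
    sign: str                      # inward | outward
    surface_area_mm2: float

    def to_dict(self) -> dict:
        return {"cluster_id": self.cluster_id,
                "n_vertices": int(len(self.vertex_ids)),
                "vertex_ids": [int(v) for v in self.vertex_ids],
                "peak_vertex": int(self.peak_vertex),
                "peak_beta": float(self.peak_beta),
                "peak_p": float(self.peak_p), "peak_q": float(self.peak_q),
                "sign": self.sign,
                "surface_area_mm2": float(self.surface_area_mm2)}


def significant_clusters(stats_map: VertexStatsMap, template: trimesh.Trimesh,
                         q_threshold: float = 0.05) -> list[ClusterReport]:
    """Sign-consistent connected components of FDR-significant vertices.

    Components are taken over the template's edge adjacency, separately
    for positive (outward) and negative (inward) betas; the peak is the
    vertex of maximum |beta|, ties broken by smaller p then lower id.
    Clusters are ordered by decreasing |peak beta|.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    nv = len(template.vertices)
    if len(stats_map.beta_std) != nv:
        raise ValueError("stats map and template vertex counts differ")
    if stats_map.q is None:
        raise ValueError("stats map carries no q-values")
    sig = stats_map.q < q_threshold
    reports: list[ClusterReport] = []
    vert_area = np.zeros(nv)
    fa = template.area_faces
    faces = np.asarray(template.faces)
    for c in range(3):
        np.add.at(vert_area, faces[:, c], fa / 3.0)
    e = np.asarray(template.edges_unique)
    for sign_label, sel in (("outward", sig & (stats_map.beta_std > 0)),
                            ("inward", sig & (stats_map.beta_std < 0))):
        if not sel.any():
            continue
        keep_e = e[sel[e[:, 0]] & sel[e[:, 1]]]
        adj = sp.coo_matrix((np.ones(2 * len(keep_e)),
                             (np.r_[keep_e[:, 0], keep_e[:, 1]],
                              np.r_[keep_e[:, 1], keep_e[:, 0]])),
                            shape=(nv, nv)).tocsr()
        n_comp, labels = connected_components(adj, directed=False)
        for lab in np.unique(labels[sel]):
            ids = np.where((labels == lab) & sel)[0]
            order = sorted(ids, key=lambda v: (-abs(stats_map.beta_std[v]),
                                               stats_map.p[v], v))
            peak = order[0]
            reports.append(ClusterReport(
                cluster_id=-1, vertex_ids=ids, peak_vertex=peak,
                peak_beta=stats_map.beta_std[peak], peak_p=stats_map.p[peak],
                peak_q=stats_map.q[peak], sign=sign_label,
                surface_area_mm2=vert_area[ids].sum()))
    reports.sort(key=lambda r: -abs(r.peak_beta))
    for i, r in enumerate(reports):
        r.cluster_id = i
    return reports


# --------------------------------------------------------------------------
# volumetric associations
# --------------------------------------------------------------------------

def volume_associations(records: pd.DataFrame, phenotypes: list[str],
                        volume_col: str = "left_hippocampal_volume_mm3",
                        brain_col: str = "total_brain_volume_mm3",
                        covariate_cols: tuple[str, ...] = (
                            "age_days", "sex", "vascular_risk_score"),
                        adjust_for_brain_size: bool = False) -> pd.DataFrame:
    """Correlation and covariate-adjusted regression of volume on phenotypes.

    With brain-size adjustment, the hippocampal volume is residualized on
    total brain volume before modeling.  Returns one row per phenotype
    with Pearson r, standardized beta, SE, p and n.
    """
    vol = records[volume_col].to_numpy(dtype=float)
    if adjust_for_brain_size:
        tbv = records[brain_col].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(tbv)), tbv])
        coef, *_ = np.linalg.lstsq(design, vol, rcond=None)
        vol = vol - design @ coef
    cov = records[list(covariate_cols)].to_numpy(dtype=float)
    rows = []
    for ph in phenotypes:
        y = records[ph].to_numpy(dtype=float)
        keep = ~(np.isnan(y) | np.isnan(vol) | np.isnan(cov).any(axis=1))
        r, r_p = sps.pearsonr(vol[keep], y[keep])
        m = vertexwise_regression(vol[keep, None], y[keep], cov[keep],
                                  model_id=ph, fdr=False)
        rows.append({"phenotype": ph, "pearson_r": r, "pearson_p": r_p,
                     "beta_std": m.beta_std[0], "se": m.se[0], "p": m.p[0],
                     "n": int(keep.sum()),
                     "brain_size_adjusted": adjust_for_brain_size})
    return pd.DataFrame(rows)
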