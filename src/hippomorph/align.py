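"""Similarity (rotation + isotropic scale + translation) alignment.

Closed-form least-squares estimation from corresponding point sets
(Umeyama's SVD solution), with reflections explicitly disallowed: shape
correspondence must never be mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation, no reflection."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must not contain a reflection")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return SimilarityTransform(r_inv, s_inv, -s_inv * r_inv @ self.translation)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying `other` first, then self."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * other.scale,
            self.scale * self.rotation @ other.translation + self.translation,
        )

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m


def similarity_procrustes(source: np.ndarray, target: np.ndarray,
                          allow_scale: bool = True,
                          ) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity transform mapping source onto target.

    Points must be in correspondence.  Returns the transform and the RMS
    residual after alignment.  The rotation is constrained to det = +1; a
    mirrored target therefore keeps a nonzero residual instead of flipping.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (N, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    xs, xt = src - mu_s, tgt - mu_t
    var_s = (xs ** 2).sum() / n
    if var_s < 1e-24:
        raise ValueError("degenerate source points (coincident)")
    cov = xt.T @ xs / n
    u, d, vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov, tol=1e-10 * max(d[0], 1e-30)) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    s = np.eye(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s[2, 2] = -1.0
    rot = u @ s @ vt
    scale = float(np.trace(np.diag(d) @ s) / var_s) if allow_scale else 1.0
    if scale <= 0:
        raise ValueError("degenerate configuration: non-positive scale")
    trans = mu_t - scale * rot @ mu_s
    tf = SimilarityTransform(rot, scale, trans)
    rms = float(np.sqrt(((tf.apply(src) - tgt) ** 2).sum(axis=1).mean()))
    return tf, rms
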