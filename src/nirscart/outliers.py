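"""Non-contact spectrum rejection via a minimum volume enclosing ellipsoid.

In-vitro spectra are always acquired with verified probe contact, so their
first three principal-component scores define the region of plausible
measurements.  In-vivo spectra are projected into that score space and
classified against the minimum volume enclosing ellipsoid (MVEE) of the
in-vitro scores, with the ellipsoid radii uniformly scaled by a relative
radius (100% = fitted boundary; the pipeline default is 105%).

The MVEE is computed with Khachiyan's first-order algorithm on the lifted
point set; the shape matrix is rescaled after convergence so every fitting
point satisfies the quadratic inequality at radius 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .core import AlignmentError, NirscartError


class InsufficientDataError(NirscartError, ValueError):
    pass


class DegenerateGeometryError(NirscartError, ValueError):
    pass


N_COMPONENTS = 3


@dataclass
class PCAModel:
    """Mean vector plus three orthonormal loadings fitted on in-vitro spectra."""

    mean: np.ndarray
    components: np.ndarray               # (3, n_features), rows orthonormal
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=float
        )


def fit_pca(matrix: np.ndarray) -> PCAModel:
    """Mean-centered PCA keeping the first three components.

    Sign convention: each loading's largest-magnitude element is made
    positive, so refits are bit-reproducible.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise InsufficientDataError("PCA needs at least 4 spectra")
    pca = _SKPCA(n_components=N_COMPONENTS, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(pca.mean_, comps, pca.explained_variance_ratio_)


def project(pca: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Scores of spectra in the fitted 3-D space: (x - mean) . loadings."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != pca.mean.size:
        raise AlignmentError(
            f"spectra have {X.shape[1]} features, PCA was fitted on {pca.mean.size}"
        )
    return (X - pca.mean) @ pca.components.T


@dataclass
class Ellipsoid:
    """Inlier region {x : (x - c)^T A (x - c) <= r^2} in score space."""

    center: np.ndarray
    shape: np.ndarray  # symmetric positive definite

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)
        if not np.allclose(self.shape, self.shape.T, atol=1e-10):
            raise DegenerateGeometryError("shape matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(self.shape) <= 0):
            raise DegenerateGeometryError("shape matrix must be positive definite")

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, self.shape, d)

    @property
    def volume(self) -> float:
        import math

        d = self.center.size
        unit = math.pi ** (d / 2) / math.gamma(d / 2 + 1)
        return float(unit / math.sqrt(np.linalg.det(self.shape)))

    def to_json(self, path: str | Path, **extra) -> None:
        Path(path).write_text(
            json.dumps(
                {"center": self.center.tolist(), "shape": self.shape.tolist()} | extra,
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Ellipsoid":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["center"]), np.array(d["shape"]))


def fit_mvee(
    points: np.ndarray, tolerance: float = 1e-6, max_iter: int = 10_000
) -> Ellipsoid:
    """Minimum volume enclosing ellipsoid via Khachiyan's algorithm.

    Iteratively reweights the lifted points until the relative change in the
    weight vector drops below ``tolerance``; afterwards the shape matrix is
    rescaled so the farthest fitting point lies exactly on the unit-radius
    boundary (every fitting point is inside at radius 1).
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2:
        raise DegenerateGeometryError("points must be a 2-D array")
    n, d = P.shape
    if n < d + 1:
        raise DegenerateGeometryError(
            f"need at least {d + 1} points in {d}-D; got {n}"
        )
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(P).max())) < d:
        raise DegenerateGeometryError(
            "points are affinely dependent (flat set); add jitter or reduce "
            "the dimension before fitting"
        )
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ (u[:, None] * Q.T)
        try:
            M = np.einsum("ji,jk,ki->i", Q, np.linalg.inv(X), Q)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise DegenerateGeometryError("degenerate point configuration") from exc
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        err = float(np.linalg.norm(new_u - u))
        u = new_u
        if err < tolerance:
            break
    center = P.T @ u
    cov = P.T @ (u[:, None] * P) - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    A = (A + A.T) / 2.0
    ell = Ellipsoid(center, A)
    worst = float(ell.mahalanobis_sq(P).max())
    if worst > 0:
        ell = Ellipsoid(center, A / worst)
    return ell


def classify(
    ellipsoid: Ellipsoid, scores: np.ndarray, radius_pct: float = 105.0
) -> np.ndarray:
    """Boolean inlier flags at a relative radius given in percent."""
    if radius_pct <= 0:
        raise ValueError("radius_pct must be positive")
    return ellipsoid.mahalanobis_sq(scores) <= (radius_pct / 100.0) ** 2


@dataclass
class OutlierReport:
    """Inlier flags at the chosen radius plus the radius-sweep outlier counts."""

    inlier: np.ndarray
    counts: dict[float, int]
    chosen_radius_pct: float

    @property
    def n_outliers(self) -> int:
        return int((~self.inlier).sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"radius_pct": list(self.counts), "n_outliers": list(self.counts.values())}
        )


def radius_sweep(
    ellipsoid: Ellipsoid,
    scores: np.ndarray,
    radii_pct: Sequence[float],
    chosen_radius_pct: float = 105.0,
) -> OutlierReport:
    """Outlier counts over a grid of relative radii, flags at the chosen one."""
    radii = list(radii_pct)
    if not radii:
        raise ValueError("radii list must be non-empty")
    m = np.asarray(ellipsoid.mahalanobis_sq(scores))
    counts = {float(r): int((m > (r / 100.0) ** 2).sum()) for r in radii}
    return OutlierReport(
        inlier=m <= (chosen_radius_pct / 100.0) ** 2,
        counts=counts,
        chosen_radius_pct=float(chosen_radius_pct),
    )
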