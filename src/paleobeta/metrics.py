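"""Community-composition statistics.

Two statistics summarise each time bin's taxon-by-locality matrix:

* **beta diversity** — multivariate dispersion sensu Anderson: Jaccard
  dissimilarities among localities are embedded by principal coordinates
  analysis (PCoA) and beta diversity is the mean Euclidean distance from
  localities to their centroid in that (partly imaginary) space. Larger
  mean distance = greater spatial turnover of community composition.
* **latitudinal turnover gradient (LTG) strength** — the first
  correspondence-analysis axis orders localities along the dominant
  compositional gradient; the R^2 of an OLS regression of those axis-1
  scores on latitude measures how much of the compositional gradient is
  latitudinal.

Both are exposed as sklearn-style estimators (`PCoA`,
`MultivariateDispersion`, `CorrespondenceAnalysis`) plus thin functional
wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .occio import OccurrenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "DispersionResult",
    "GradientResult",
    "PCoA",
    "MultivariateDispersion",
    "CorrespondenceAnalysis",
    "jaccard_matrix",
    "pcoa",
    "multivariate_dispersion",
    "beta_diversity",
    "ca_axis1",
    "ltg_strength",
    "ltg",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among localities."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(str(i) for i in df.index), values=df.to_numpy(dtype=float))


def _as_binary_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, OccurrenceMatrix):
        return matrix.data
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix)
    return pd.DataFrame(arr, index=[f"r{i}" for i in range(arr.shape[0])],
                        columns=[f"c{j}" for j in range(arr.shape[1])])


def jaccard_matrix(matrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity, d = 1 - |A&B| / |A|B|, among localities."""
    df = _as_binary_frame(matrix)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 localities")
    X = df.to_numpy().astype(bool)
    if (X.sum(axis=1) == 0).any():
        empty = list(df.index[X.sum(axis=1) == 0])
        raise ValueError(f"localities with zero taxa: {empty}")
    d = squareform(pdist(X, metric="jaccard"))
    return DistanceMatrix(ids=tuple(str(i) for i in df.index), values=d)


# ---------------------------------------------------------------------------
# PCoA and multivariate dispersion

class PCoA(BaseEstimator):
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    Gower double-centering of -d^2/2 followed by eigendecomposition. Axes
    with positive eigenvalues span the real part of the embedding; negative
    eigenvalues (non-Euclidean dissimilarities such as Jaccard) span an
    imaginary part kept separately, as both contribute to Anderson's
    dispersion. Coordinates are scaled by sqrt(|eigenvalue|).

    Attributes
    ----------
    eigenvalues_ : all eigenvalues, descending.
    coordinates_ : (n, n_pos) real-axis coordinates.
    imag_coordinates_ : (n, n_neg) imaginary-axis coordinates.
    """

    def __init__(self, eig_tol: float = 1e-9):
        self.eig_tol = eig_tol

    def fit(self, D):
        if isinstance(D, DistanceMatrix):
            d = D.values
        else:
            d = np.asarray(D, dtype=float)
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError("distance matrix must be square")
            if not np.allclose(d, d.T, atol=1e-10):
                raise ValueError("distance matrix must be symmetric")
        n = d.shape[0]
        A = -0.5 * d**2
        J = np.eye(n) - np.ones((n, n)) / n
        B = J @ A @ J
        B = (B + B.T) / 2.0
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        scale = max(abs(evals).max(), 1.0) if n else 1.0
        tol = self.eig_tol * scale
        pos = evals > tol
        neg = evals < -tol
        self.eigenvalues_ = evals
        self.coordinates_ = evecs[:, pos] * np.sqrt(evals[pos])
        self.imag_coordinates_ = evecs[:, neg] * np.sqrt(-evals[neg])
        self.trace_ = float(np.trace(B))
        return self

    def fit_transform(self, D) -> np.ndarray:
        return self.fit(D).coordinates_


def pcoa(D) -> PCoA:
    return PCoA().fit(D)


@dataclass(frozen=True)
class DispersionResult:
    ids: tuple[str, ...]
    distances: np.ndarray           # z_i >= 0
    beta: float                     # mean z_i
    eigenvalues: np.ndarray
    n_clamped: int


class MultivariateDispersion(BaseEstimator):
    """Distance to the multivariate centroid in PCoA space (Anderson).

    For each locality, the squared distance to the centroid on real axes
    minus the squared distance on imaginary axes gives z_i^2; small negative
    values (possible when imaginary axes dominate) are clamped to zero and
    counted. The mean of z_i is the bin's beta diversity.

    Attributes: ``distances_``, ``beta_``, ``eigenvalues_``, ``n_clamped_``.
    """

    def __init__(self, eig_tol: float = 1e-9):
        self.eig_tol = eig_tol

    def fit(self, D):
        ids = D.ids if isinstance(D, DistanceMatrix) else tuple(
            f"r{i}" for i in range(np.asarray(D).shape[0])
        )
        emb = PCoA(eig_tol=self.eig_tol).fit(D)
        real, imag = emb.coordinates_, emb.imag_coordinates_
        dr = ((real - real.mean(axis=0)) ** 2).sum(axis=1) if real.size else np.zeros(len(ids))
        di = ((imag - imag.mean(axis=0)) ** 2).sum(axis=1) if imag.size else np.zeros(len(ids))
        z2 = dr - di
        n_clamped = int((z2 < 0).sum())
        if n_clamped:
            logger.info("dispersion: clamped %d negative squared distances", n_clamped)
        self.ids_ = ids
        self.distances_ = np.sqrt(np.clip(z2, 0.0, None))
        self.beta_ = float(self.distances_.mean())
        self.eigenvalues_ = emb.eigenvalues_
        self.n_clamped_ = n_clamped
        return self

    def result_(self) -> DispersionResult:
        return DispersionResult(self.ids_, self.distances_, self.beta_,
                                self.eigenvalues_, self.n_clamped_)


def multivariate_dispersion(D) -> DispersionResult:
    return MultivariateDispersion().fit(D).result_()


def beta_diversity(matrix) -> float:
    """Beta diversity of one bin: mean distance-to-centroid of the Jaccard PCoA."""
    return multivariate_dispersion(jaccard_matrix(matrix)).beta


# ---------------------------------------------------------------------------
# Correspondence analysis axis 1

def _check_connected(X: np.ndarray) -> None:
    n, m = X.shape
    graph = csr_matrix(
        np.block([[np.zeros((n, n)), X > 0], [(X > 0).T, np.zeros((m, m))]])
    )
    ncomp, _ = connected_components(graph, directed=False)
    if ncomp > 1:
        warnings.warn(
            "incidence structure is disconnected; CA axis 1 may separate blocks degenerately",
            stacklevel=3,
        )


class CorrespondenceAnalysis(BaseEstimator):
    """First correspondence-analysis axis of a sites-by-species matrix.

    Site scores are computed either by reciprocal averaging (iterated
    weighted averaging of site and species scores to convergence) or from
    the SVD of the chi-square standardized residual matrix; the two agree
    to numerical precision up to sign. Scores are in standard coordinates:
    weighted (by row mass) mean 0 and variance 1.

    Optional Hill-style nonlinear rescaling deforms the axis so the local
    within-site dispersion of species scores is approximately constant
    along it (segment-based, order-preserving). Detrending of higher axes
    is out of scope: only axis 1 is computed and detrending cannot change
    its ordering.

    Attributes
    ----------
    site_scores_ : pandas Series of axis-1 site scores (rescaled if enabled).
    raw_site_scores_ : scores before rescaling.
    species_scores_ : species scores (weighted averages of site scores).
    eigenvalue_ : the first CA eigenvalue.
    n_iter_ : reciprocal-averaging iterations (0 for the svd method).
    """

    def __init__(self, method: str = "svd", rescale: bool = True, segments: int = 26,
                 tol: float = 1e-10, max_iter: int = 10000):
        self.method = method
        self.rescale = rescale
        self.segments = segments
        self.tol = tol
        self.max_iter = max_iter

    # -- core algorithms ----------------------------------------------------
    @staticmethod
    def _standardize(x: np.ndarray, r: np.ndarray) -> np.ndarray:
        mu = float(np.sum(r * x))
        x = x - mu
        var = float(np.sum(r * x**2))
        return x / np.sqrt(var)

    def _svd_axis(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        P = X / X.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        # first singular triplet beyond the trivial one (sv ~ 0 trivial is
        # removed by construction since S excludes the rank-1 expectation)
        scores = U[:, 0] / np.sqrt(r)
        return self._standardize(scores, r), float(sv[0] ** 2)

    def _ra_axis(self, X: np.ndarray) -> tuple[np.ndarray, float, int]:
        rowsum = X.sum(axis=1).astype(float)
        colsum = X.sum(axis=0).astype(float)
        r = rowsum / rowsum.sum()
        x = self._standardize(np.arange(X.shape[0], dtype=float), r)
        ev = 0.0
        for it in range(1, self.max_iter + 1):
            y = (X.T @ x) / colsum
            x_new = (X @ y) / rowsum
            x_new = x_new - float(np.sum(r * x_new))
            ev = float(np.sqrt(np.sum(r * x_new**2)))  # contraction = eigenvalue
            x_new = x_new / ev
            if np.max(np.abs(x_new - x)) < self.tol:
                x = x_new
                break
            x = x_new
        return x, ev, it

    # -- Hill-style rescaling ----------------------------------------------
    def _rescale_axis(self, x: np.ndarray, X: np.ndarray, iterations: int = 2) -> np.ndarray:
        """Order-preserving piecewise-linear deformation equalizing the local
        within-site dispersion of species scores along the axis."""
        rowsum = X.sum(axis=1).astype(float)
        colsum = X.sum(axis=0).astype(float)
        for _ in range(iterations):
            y = (X.T @ x) / colsum                     # species scores
            cent = (X @ y) / rowsum                    # per-site species centroid
            disp = (X @ (y**2)) / rowsum - cent**2     # within-site variance
            disp = np.clip(disp, 1e-12, None)
            lo, hi = float(x.min()), float(x.max())
            if hi - lo < 1e-12:
                return x
            edges = np.linspace(lo, hi, self.segments + 1)
            idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, self.segments - 1)
            local = np.full(self.segments, np.nan)
            for k in range(self.segments):
                w = rowsum[idx == k]
                if w.sum() > 0:
                    local[k] = np.average(disp[idx == k], weights=w)
            # fill empty segments by interpolation from occupied neighbours
            occupied = np.flatnonzero(~np.isnan(local))
            local = np.interp(np.arange(self.segments), occupied, local[occupied])
            widths = np.diff(edges) * np.sqrt(local)
            new_edges = np.concatenate([[0.0], np.cumsum(widths)])
            x = np.interp(x, edges, new_edges)
        # express in sd units: average within-site dispersion ~ 1
        y = (X.T @ x) / colsum
        cent = (X @ y) / rowsum
        disp = (X @ (y**2)) / rowsum - cent**2
        mean_disp = float(np.average(np.clip(disp, 0, None), weights=rowsum))
        if mean_disp > 0:
            x = (x - x.min()) / np.sqrt(mean_disp)
        return x

    # -- sklearn surface ----------------------------------------------------
    def fit(self, matrix):
        df = _as_binary_frame(matrix)
        X = df.to_numpy(dtype=float)
        if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
            raise ValueError("matrix has empty rows or columns")
        _check_connected(X)
        if self.method == "svd":
            raw, ev = self._svd_axis(X)
            n_iter = 0
        elif self.method == "reciprocal":
            raw, ev, n_iter = self._ra_axis(X)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        scores = self._rescale_axis(raw.copy(), X) if self.rescale else raw
        self.raw_site_scores_ = pd.Series(raw, index=df.index, name="ca1_raw")
        self.site_scores_ = pd.Series(scores, index=df.index, name="ca1")
        colsum = X.sum(axis=0)
        self.species_scores_ = pd.Series((X.T @ scores) / colsum, index=df.columns)
        self.eigenvalue_ = ev
        self.n_iter_ = n_iter
        return self

    def fit_transform(self, matrix) -> np.ndarray:
        return self.fit(matrix).site_scores_.to_numpy()


def ca_axis1(matrix, method: str = "svd", rescale: bool = True, segments: int = 26) -> pd.Series:
    """Axis-1 site scores of correspondence analysis."""
    return CorrespondenceAnalysis(method=method, rescale=rescale, segments=segments).fit(matrix).site_scores_


# ---------------------------------------------------------------------------
# LTG strength

@dataclass(frozen=True)
class GradientResult:
    slope: float
    intercept: float
    r_squared: float        # LTG strength
    n: int
    scores: np.ndarray
    latitudes: np.ndarray

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("R^2 must lie in [0, 1]")


def ltg_strength(scores, latitudes) -> GradientResult:
    """LTG strength: R^2 of OLS of CA axis-1 site scores on latitude."""
    scores = np.asarray(scores, dtype=float)
    latitudes = np.asarray(latitudes, dtype=float)
    if scores.shape != latitudes.shape:
        raise ValueError("scores and latitudes must have equal length")
    if len(scores) < 3:
        raise ValueError("need at least 3 localities")
    if np.ptp(latitudes) == 0:
        raise ValueError("latitude has zero variance")
    if np.ptp(scores) == 0:
        return GradientResult(0.0, float(scores[0]), 0.0, len(scores), scores, latitudes)
    fit = stats.linregress(latitudes, scores)
    return GradientResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(scores),
        scores=scores,
        latitudes=latitudes,
    )


def ltg(matrix: OccurrenceMatrix, rescale: bool = True) -> GradientResult:
    """LTG strength of one bin's occurrence matrix."""
    scores = ca_axis1(matrix, rescale=rescale)
    return ltg_strength(scores.to_numpy(), matrix.latitudes)
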