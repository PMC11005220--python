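"""Unsupervised ordination of metabolic profiles: PCoA and non-metric MDS.

Both methods start from a pairwise distance matrix (Euclidean on z-scored
features by default).  PCoA is classical scaling — double-centre the squared
distances and eigendecompose; NMDS minimises Kruskal stress-1 with isotonic
regression on distance ranks and Guttman (SMACOF) configuration updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression


@dataclass
class DistanceMatrix:
    values: np.ndarray          # n x n, symmetric, zero diagonal
    metric: str = "euclidean"
    standardized: bool = True
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.values, float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.max(np.abs(d - d.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class OrdinationResult:
    coordinates: np.ndarray            # n x d
    eigenvalues: np.ndarray | None = None   # PCoA only (all, incl. negative)
    proportion_explained: np.ndarray | None = None
    stress: float | None = None        # NMDS only, Kruskal stress-1
    stress_trajectory: np.ndarray | None = None
    converged: bool = True
    ids: list[str] | None = None
    warnings: list[str] = field(default_factory=list)


def distance_matrix(
    table, metric: str = "euclidean", standardize: bool = True
) -> DistanceMatrix:
    """Pairwise distances between rows; z-scores columns first by default.

    Zero-variance columns cannot be z-scored and are dropped with a warning.
    Accepts a DataFrame (numeric columns are used) or a 2-D array.
    """
    ids = None
    if isinstance(table, pd.DataFrame):
        X = table.select_dtypes("number").to_numpy(float)
        ids = [str(i) for i in table.index]
    else:
        X = np.asarray(table, float)
    if np.isnan(X).any():
        raise ValueError("distance_matrix requires complete data")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {np.sum(~keep)} zero-variance column(s) "
                "under standardization"
            )
            X = X[:, keep]
            sd = sd[keep]
        X = (X - X.mean(axis=0)) / sd
    d = squareform(pdist(X, metric=metric))
    return DistanceMatrix(d, metric=metric, standardized=standardize, ids=ids)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make the first nonzero entry of each axis positive (plot stability)."""
    out = coords.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def pcoa(d: DistanceMatrix, dims: int = 2) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centering of -D²/2 followed by eigendecomposition; axes are
    eigenvectors scaled by sqrt(eigenvalue), ordered by decreasing
    eigenvalue.  Negative eigenvalues (non-Euclidean input) are reported and
    no axes are returned for them; if ``dims`` exceeds the number of
    positive eigenvalues the result is truncated with a warning.
    """
    n = d.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 points")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-9 * max(1.0, float(np.abs(eigval).max()))
    n_pos = int(np.sum(eigval > tol))
    warns = []
    if dims > n_pos:
        warns.append(
            f"requested {dims} axes but only {n_pos} positive eigenvalues; "
            "truncating"
        )
    k = min(dims, n_pos)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else np.zeros((n, 0))
    pos_sum = float(eigval[eigval > tol].sum())
    prop = eigval[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(
        coordinates=_fix_signs(coords),
        eigenvalues=eigval,
        proportion_explained=prop,
        ids=d.ids,
        warnings=warns,
    )


def _stress1(dist: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disparities) ** 2) / denom))


def _guttman_update(X: np.ndarray, disparities: np.ndarray) -> np.ndarray:
    """One SMACOF majorization step toward the current disparities."""
    n = X.shape[0]
    dist = squareform(pdist(X))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, disparities / dist, 0.0)
    B = -ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def nmds(
    d: DistanceMatrix,
    dims: int = 2,
    restarts: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS by Kruskal stress-1 minimisation.

    Alternates isotonic regression of configuration distances on the ranks of
    the input dissimilarities with Guttman configuration updates.  The first
    start is the PCoA configuration; the remaining ``restarts - 1`` are
    random.  An update that fails to reduce stress terminates that start, so
    the recorded stress trajectory is non-increasing by construction.  The
    best start's configuration, final stress-1 and trajectory are returned;
    ``converged`` is False when the iteration cap was hit.
    """
    n = d.n
    if n < dims + 1:
        raise ValueError(f"NMDS with {dims} dims needs at least {dims + 1} points")
    rng = np.random.default_rng(seed)
    triu = np.triu_indices(n, k=1)
    diss = d.values[triu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)

    inits = [pcoa(d, dims=dims).coordinates]
    if inits[0].shape[1] < dims:  # degenerate cloud: pad with zeros
        pad = np.zeros((n, dims - inits[0].shape[1]))
        inits[0] = np.hstack([inits[0], pad])
    scale = max(float(diss.max()), 1.0)
    for _ in range(max(restarts - 1, 0)):
        inits.append(rng.normal(0.0, scale, size=(n, dims)))

    best = None
    for X in inits:
        X = X.copy()
        traj = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            dist = squareform(pdist(X))[triu]
            disp = np.empty_like(dist)
            disp[order] = iso.fit_transform(np.arange(diss.size), dist[order])
            s = _stress1(dist, disp)
            if s >= prev - tol:
                converged = s <= prev  # stopped by lack of progress, not cap
                if s < prev:
                    traj.append(s)
                    prev = s
                break
            traj.append(s)
            prev = s
            full_disp = squareform(disp)
            X = _guttman_update(X, full_disp)
        result = (prev, X, np.asarray(traj), converged)
        if best is None or result[0] < best[0]:
            best = result

    stress, X, traj, converged = best
    return OrdinationResult(
        coordinates=_fix_signs(X - X.mean(axis=0)),
        stress=float(stress),
        stress_trajectory=traj,
        converged=bool(converged),
        ids=d.ids,
    )
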