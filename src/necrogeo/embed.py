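"""Ordination of sample similarity/dissimilarity matrices.

Two methods are provided:

``pca_rows`` (default)
    Treat each row of the similarity matrix as that sample's feature
    vector, column-center, and project onto principal axes — the
    ordination obtained by running a standard PCA routine directly on the
    imported similarity matrix.

``torgerson``
    Classical metric MDS: convert similarities to dissimilarities
    (d = 1 - S) unless a dissimilarity matrix is supplied, double-center
    B = -1/2 * J D^2 J, eigendecompose, and scale eigenvectors by the
    square root of the positive eigenvalues.

Both report explained-variance shares per axis and fix the sign of each
axis so that its largest-magnitude loading (or coordinate, for
torgerson) is positive — ordinations are otherwise sign-ambiguous and
downstream fits must be reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sketch import SimilarityMatrix

__all__ = ["Embedding", "embed"]

_SYM_TOL = 1e-10
_RANK_TOL = 1e-12


@dataclass
class Embedding:
    """Per-sample ordination coordinates.

    Attributes
    ----------
    sample_ids : list of str
    X : ndarray, shape (n, m)
        Coordinates; columns ordered by decreasing explained variance
        and mutually orthogonal.
    explained_variance : ndarray, shape (m,)
        Non-negative variance shares summing to <= 1.
    method : {"pca_rows", "torgerson"}
    """

    sample_ids: list[str]
    X: np.ndarray
    explained_variance: np.ndarray
    method: str

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]


def _fix_signs_by_loadings(coords: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Flip axes so the largest-|.| loading of each axis is positive."""
    for j in range(coords.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -coords[:, j]
            loadings[:, j] = -loadings[:, j]
    return coords


def _embed_pca_rows(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xc = S - S.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > _RANK_TOL * max(s[0], 1.0) if s.size else np.zeros(0, bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    coords = U * s
    total = float(np.sum(s**2))
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    coords = _fix_signs_by_loadings(coords, Vt.T.copy())
    return coords, explained


def _embed_torgerson(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > _RANK_TOL * max(abs(eigvals).max(), 1.0)
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    coords = eigvecs * np.sqrt(eigvals)
    total = float(eigvals.sum())
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)
    # for MDS the coordinates are the loadings; same sign convention
    coords = _fix_signs_by_loadings(coords, coords)
    return coords, explained


def embed(
    S: SimilarityMatrix,
    method: str = "pca_rows",
    distance: np.ndarray | None = None,
) -> Embedding:
    """Ordinate samples from a similarity matrix.

    Parameters
    ----------
    S : SimilarityMatrix
        Symmetric pairwise similarities.
    method : {"pca_rows", "torgerson"}
    distance : ndarray, optional
        Pre-computed dissimilarity matrix overriding ``1 - S`` for the
        torgerson method (e.g. Jaccard distances from taxa tables).

    Raises
    ------
    ValueError
        If the input matrix is not symmetric or the method is unknown.
    """
    M = np.asarray(S.values, dtype=np.float64)
    if not np.allclose(M, M.T, atol=_SYM_TOL):
        raise ValueError("similarity matrix must be symmetric")
    if method == "pca_rows":
        coords, explained = _embed_pca_rows(M)
    elif method == "torgerson":
        D = np.asarray(distance, dtype=np.float64) if distance is not None else 1.0 - M
        if not np.allclose(D, D.T, atol=_SYM_TOL):
            raise ValueError("distance matrix must be symmetric")
        coords, explained = _embed_torgerson(D)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    if coords.shape[1] == 0:
        warnings.warn("input has zero variance; embedding is empty")
    return Embedding(
        sample_ids=list(S.sample_ids),
        X=coords,
        explained_variance=explained,
        method=method,
    )
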