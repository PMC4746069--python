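"""Principal component analysis of Procrustes shape coordinates.

Covariance PCA (never correlation PCA) on flattened aligned coordinates,
following standard geometric-morphometrics practice: shape variables are
commensurate, so rescaling them would distort the Procrustes metric. PCA
may be run on a whole aligned sample, or separately on the symmetric and
asymmetric components of an object-symmetry decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .procrustes_core import AlignedSample

__all__ = ["PCAResult", "fit_pca", "variance_explained", "specimen_mean_matrix"]


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the shape covariance matrix.

    ``eigenvalues`` are non-increasing and non-negative;
    ``variance_fraction`` sums to 1 over the retained rank; ``scores`` is
    N x m; ``loadings`` is m x p with unit-norm rows whose sign is fixed so
    the largest-magnitude loading of each component is positive;
    ``mean_shape`` is the centering vector reshaped to (L, D) when the
    input carried shape structure, else flat.
    """

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    mean_shape: np.ndarray

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)

    def reconstruct(self) -> np.ndarray:
        """Mean + scores @ loadings: reproduces the (flattened) input data."""
        return self.mean_shape.reshape(1, -1) + self.scores @ self.loadings

    def scores_frame(self, index=None) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.rank)]
        return pd.DataFrame(self.scores, columns=cols, index=index)


def fit_pca(data, center: bool = True) -> PCAResult:
    """PCA of aligned shape coordinates (or any observations x variables matrix).

    Accepts an :class:`AlignedSample` (flattened internally) or a 2-D array;
    for component matrices from an object-symmetry decomposition pass
    ``component.reshape(N, -1)``. Needs at least 3 observations. Retained
    rank is ``min(N - 1, p)`` (zero eigenvalues kept so variance fractions
    always sum to 1 over the retained set).
    """
    shape_hint = None
    if isinstance(data, AlignedSample):
        shape_hint = data.procrustes_coords.shape[1:]
        X = data.flattened()
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 3:
            shape_hint = X.shape[1:]
            X = X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D data matrix, got shape {X.shape}")
    N, p = X.shape
    if N < 3:
        raise DesignError(f"PCA needs at least 3 observations, got {N}")
    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    # SVD route: eigenvalues of the covariance are s^2 / (N - 1).
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = min(N - 1, p)
    svals = svals[:m]
    Vt = Vt[:m]
    eigenvalues = svals**2 / (N - 1)
    # Deterministic signs: largest-|loading| entry of each PC made positive.
    for i in range(m):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    scores = Xc @ Vt.T
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    mean_shape = mean.reshape(shape_hint) if shape_hint is not None else mean
    return PCAResult(
        eigenvalues=eigenvalues,
        variance_fraction=fractions,
        scores=scores,
        loadings=Vt,
        mean_shape=mean_shape,
    )


def variance_explained(result: PCAResult, first_m: int) -> float:
    """Cumulative variance fraction of the first ``first_m`` components."""
    if not (1 <= first_m <= result.rank):
        raise ValueError(f"first_m must be in [1, {result.rank}], got {first_m}")
    return float(result.variance_fraction[:first_m].sum())


def specimen_mean_matrix(aligned: AlignedSample) -> tuple[list[str], np.ndarray]:
    """Average replicate observations per specimen (labels required).

    Returns ``(specimen_ids, matrix)`` with one flattened mean configuration
    per specimen, specimens in first-appearance order. Used to run the
    sample-wide PCA at specimen level rather than replicate level.
    """
    if not aligned.labels:
        raise ValueError("AlignedSample has no labels; cannot group replicates")
    ids: list[str] = []
    for sid, _rep in aligned.labels:
        if sid not in ids:
            ids.append(sid)
    flat = aligned.flattened()
    out = np.stack(
        [
            flat[[i for i, (s, _) in enumerate(aligned.labels) if s == sid]].mean(axis=0)
            for sid in ids
        ]
    )
    return ids, out
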