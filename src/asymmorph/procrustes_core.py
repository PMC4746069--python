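"""Ordinary and generalized Procrustes superimposition.

The superimposition removes location, scale and orientation from landmark
configurations: each shape is translated to the origin, rescaled to unit
centroid size, and rotated to a least-squares best fit. Rotations are solved
by cross-covariance SVD with a determinant correction so that improper
rotations (reflections) are excluded unless explicitly requested.

Generalized Procrustes analysis (GPA) iterates rotation of all observations
to a running consensus (the mean shape, itself rescaled to unit centroid
size) until the consensus stabilises. Aligned shapes keep unit centroid size
throughout, matching the convention of rescaling every specimen to unit
centroid size before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConvergenceError, DegenerateConfigurationError
from .landmark_io import LandmarkConfiguration

__all__ = [
    "AlignedSample",
    "centroid_size",
    "opa_align",
    "gpa_align",
    "procrustes_distance",
]


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    This is the size measure removed by Procrustes scaling.

    Raises
    ------
    DegenerateConfigurationError
        If all landmarks coincide (size is zero up to round-off).
    """
    X = _as_coords(config)
    centered = X - X.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    scale = float(np.abs(X).max()) or 1.0
    if cs <= 1e-12 * scale:
        raise DegenerateConfigurationError("all landmarks coincide: centroid size is zero")
    return cs


def _optimal_rotation(H: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation R maximizing tr(R^T H); proper (det +1) unless reflections allowed."""
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U = U.copy()
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def _batch_rotations(X: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Per-observation rotations aligning each X[i] onto ``target`` (batched SVD)."""
    H = np.einsum("nld,le->nde", X, target)
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection:
        neg = np.linalg.det(R) < 0
        if np.any(neg):
            U = U.copy()
            U[neg, :, -1] *= -1.0
            R = U @ Vt
    return R


def _principal_axis_rotation(C: np.ndarray) -> np.ndarray:
    """Proper rotation taking shape C to its principal-axis frame.

    Axes are ordered by variance; signs are fixed by making the coordinate
    of largest magnitude along each axis positive (with a determinant
    correction on the last axis to stay a proper rotation). Used to give
    GPA output an orientation that depends only on the shapes themselves,
    not on how the input happened to be oriented.
    """
    _, _, Wt = np.linalg.svd(C, full_matrices=False)
    W = Wt.T
    if np.linalg.det(W) < 0:
        W[:, -1] *= -1.0
    C2 = C @ W
    signs = np.ones(C.shape[1])
    for d in range(C.shape[1]):
        j = int(np.argmax(np.abs(C2[:, d])))
        if C2[j, d] < 0:
            signs[d] = -1.0
    if np.prod(signs) < 0:
        signs[-1] *= -1.0
    return W * signs


def opa_align(moving, target, allow_reflection: bool = False):
    """Ordinary Procrustes superimposition of ``moving`` onto a fixed ``target``.

    Finds the least-squares optimal translation, scaling and rotation of the
    moving configuration; returns ``(aligned_coords, distance)`` where
    ``distance`` is the root summed squared landmark deviation after the fit.
    """
    A = _as_coords(moving)
    B = _as_coords(target)
    if A.shape != B.shape:
        raise DegenerateConfigurationError(
            f"configurations not congruent: {A.shape} vs {B.shape}"
        )
    centroid_size(A)  # degenerate check
    centroid_size(B)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    if np.linalg.matrix_rank(H) == 0:
        raise DegenerateConfigurationError("rank-deficient cross-covariance; cannot align")
    U, S, Vt = np.linalg.svd(H)
    d = np.ones(len(S))
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        d[-1] = -1.0
    R = (U * d) @ Vt
    beta = float((S * d).sum() / (Ac**2).sum())
    aligned = beta * (Ac @ R) + B.mean(axis=0)
    distance = float(np.sqrt(((aligned - B) ** 2).sum()))
    return aligned, distance


def procrustes_distance(x, y, allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two shapes.

    Both configurations are centred and scaled to unit centroid size, then
    optimally rotated; the distance is the remaining root summed squared
    deviation. On the unit pre-shape sphere this is symmetric in its
    arguments and satisfies the triangle inequality.
    """
    A = _as_coords(x)
    B = _as_coords(y)
    A = (A - A.mean(axis=0)) / centroid_size(A)
    B = (B - B.mean(axis=0)) / centroid_size(B)
    R = _optimal_rotation(A.T @ B, allow_reflection)
    return float(np.sqrt(((A @ R - B) ** 2).sum()))


@dataclass(frozen=True)
class AlignedSample:
    """Result of a generalized Procrustes fit.

    Attributes
    ----------
    procrustes_coords : (N, L, D) array
        Aligned configurations, each centred at the origin with centroid
        size 1.
    centroid_sizes : (N,) array
        Original centroid sizes (the size information removed by the fit).
    consensus : (L, D) array
        Mean shape, unit centroid size.
    iterations : int
        Number of consensus updates performed.
    converged : bool
    labels : tuple
        Optional (specimen_id, replicate) labels, one per observation.
    """

    procrustes_coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    converged: bool
    labels: tuple = ()

    @property
    def n_observations(self) -> int:
        return self.procrustes_coords.shape[0]

    def flattened(self) -> np.ndarray:
        """(N, L*D) matrix of aligned coordinates for multivariate analyses."""
        N = self.procrustes_coords.shape[0]
        return self.procrustes_coords.reshape(N, -1)


def gpa_align(
    sample: Sequence,
    allow_reflection: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
    consensus_hook: Callable[[np.ndarray], np.ndarray] | None = None,
    labels: Sequence | None = None,
) -> AlignedSample:
    """Generalized Procrustes superimposition of two or more configurations.

    Iterative scheme: centre and rescale all configurations to unit centroid
    size, rotate each onto the current consensus, recompute the consensus
    (re-centred and re-scaled to unit centroid size), and repeat until the
    root-mean-square change of the consensus falls below ``tol``. The initial
    consensus is the first observation; after convergence the solution is
    rotated into the consensus principal-axis frame, so the output depends
    only on the shapes, not on how the inputs were oriented.

    ``consensus_hook``, if given, is applied to the consensus at every
    update before rescaling (used by the object-symmetry machinery to keep
    the consensus perfectly symmetric).
    """
    coords = [_as_coords(c) for c in sample]
    if len(coords) < 2:
        raise DegenerateConfigurationError("GPA needs at least 2 configurations")
    shapes = {c.shape for c in coords}
    if len(shapes) != 1:
        raise DegenerateConfigurationError(f"configurations not congruent: {sorted(shapes)}")
    sizes = np.array([centroid_size(c) for c in coords])
    X = np.stack([(c - c.mean(axis=0)) / s for c, s in zip(coords, sizes)])
    L = X.shape[1]

    def _normalise(C: np.ndarray) -> np.ndarray:
        C = C - C.mean(axis=0)
        return C / np.sqrt((C**2).sum())

    consensus = X[0].copy()
    if consensus_hook is not None:
        consensus = _normalise(consensus_hook(consensus))
    aligned = X
    change = np.inf
    for iteration in range(1, max_iter + 1):
        R = _batch_rotations(X, consensus, allow_reflection)
        aligned = np.einsum("nld,nde->nle", X, R)
        new_consensus = _normalise(aligned.mean(axis=0))
        if consensus_hook is not None:
            new_consensus = _normalise(consensus_hook(new_consensus))
        change = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last consensus RMS change "
            f"{change:.3e})",
            residual=change,
        )
    if consensus_hook is None:
        # Canonical orientation: principal axes of the consensus, so the
        # result is invariant to how the inputs were positioned. With a
        # consensus hook (object symmetry) the hook's frame is kept, since
        # reorienting would move the mirror plane off axis 0.
        Q = _principal_axis_rotation(consensus)
        consensus = consensus @ Q
        aligned = aligned @ Q
    if labels is None and sample and isinstance(sample[0], LandmarkConfiguration):
        labels = tuple((c.specimen_id, c.replicate) for c in sample)
    return AlignedSample(
        procrustes_coords=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=iteration,
        converged=True,
        labels=tuple(labels) if labels is not None else (),
    )
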