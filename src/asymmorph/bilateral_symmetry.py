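"""Object-symmetry machinery for bilaterally symmetric structures.

A structure with *object symmetry* (the midline runs through the object
itself) is analysed by superimposing each configuration jointly with its
reflected-and-relabeled copy. The average of an aligned original and its
aligned mirror is the observation's *symmetric* shape component; half their
difference is its *asymmetric* component. Individual variation lives in the
symmetric subspace; directional and fluctuating asymmetry live in the
asymmetric subspace.

The mirror plane is the coordinate plane orthogonal to the first axis
(axis 0 is negated). Since the joint Procrustes fit re-rotates everything,
the choice of plane is immaterial; fixing it makes outputs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SymmetryMapError
from .landmark_io import (
    LandmarkConfiguration,
    StudySample,
    SymmetryMap,
    validate_symmetry_map,
)
from .procrustes_core import AlignedSample, gpa_align

__all__ = [
    "SymmetryDecomposition",
    "reflect_relabel",
    "reflection_operator",
    "symmetry_subspace_dims",
    "decompose_symmetry",
    "individual_fa_scores",
]


def _relabel_permutation(smap: SymmetryMap, n_landmarks: int) -> np.ndarray:
    perm = np.arange(n_landmarks)
    for a, b in smap.pairs:
        perm[a], perm[b] = b, a
    return perm


def reflect_relabel(coords: np.ndarray, smap: SymmetryMap, _perm: np.ndarray | None = None) -> np.ndarray:
    """Mirror a configuration across the plane x0 = 0, then swap paired labels.

    Median landmarks keep their labels. Applying the operation twice returns
    the original exactly (it is an involution).
    """
    coords = np.asarray(coords, dtype=float)
    if _perm is None:
        validate_symmetry_map(smap, coords.shape[-2])
        _perm = _relabel_permutation(smap, coords.shape[-2])
    out = coords.copy()
    out[..., 0] = -out[..., 0]
    return out[..., _perm, :]


def reflection_operator(smap: SymmetryMap, n_landmarks: int, n_dims: int) -> np.ndarray:
    """The reflect-relabel map as an (L*D, L*D) orthogonal involution matrix.

    Useful for building projectors onto the symmetric ((I+R)/2) and
    asymmetric ((I-R)/2) subspaces of flattened shape space.
    """
    validate_symmetry_map(smap, n_landmarks)
    perm = _relabel_permutation(smap, n_landmarks)
    R = np.zeros((n_landmarks * n_dims, n_landmarks * n_dims))
    for l in range(n_landmarks):
        for d in range(n_dims):
            sign = -1.0 if d == 0 else 1.0
            R[perm[l] * n_dims + d, l * n_dims + d] = sign
    return R


def symmetry_subspace_dims(smap: SymmetryMap, n_dims: int) -> tuple[int, int]:
    """Dimensions (s, a) of the symmetric and asymmetric shape subspaces.

    For k landmark pairs and u median landmarks after removal of location,
    scale and orientation:

    * D = 2:  s = 2k + u - 2,   a = 2k + u - 2
    * D = 3:  s = 3k + 2u - 4,  a = 3k + u - 3

    These are the degrees of freedom entering the Procrustes ANOVA strata.
    """
    k, u = smap.k, smap.u
    if n_dims == 2:
        return 2 * k + u - 2, 2 * k + u - 2
    if n_dims == 3:
        return 3 * k + 2 * u - 4, 3 * k + u - 3
    raise ValueError(f"unsupported dimension {n_dims}")


@dataclass(frozen=True)
class SymmetryDecomposition:
    """Per-observation symmetric and asymmetric Procrustes components.

    ``symmetric[i] + asymmetric[i]`` reconstructs the aligned original
    observation; the consensus is perfectly symmetric under
    :func:`reflect_relabel`. ``dims`` holds the (s, a) subspace dimensions
    from :func:`symmetry_subspace_dims`.
    """

    specimen_ids: tuple[str, ...]
    replicates: tuple[int, ...]
    symmetric: np.ndarray  # (N_obs, L, D)
    asymmetric: np.ndarray  # (N_obs, L, D)
    consensus: np.ndarray  # (L, D)
    map: SymmetryMap
    dims: tuple[int, int]
    aligned: AlignedSample | None = None

    @property
    def n_observations(self) -> int:
        return self.symmetric.shape[0]

    def specimen_means(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Replicate-averaged (symmetric, asymmetric) components per specimen.

        Returns ``(ids, sym_means, asym_means)`` with arrays of shape
        (n_specimens, L, D), specimens in first-appearance order.
        """
        ids: list[str] = []
        for sid in self.specimen_ids:
            if sid not in ids:
                ids.append(sid)
        sym = np.stack(
            [
                self.symmetric[[i for i, s in enumerate(self.specimen_ids) if s == sid]].mean(0)
                for sid in ids
            ]
        )
        asym = np.stack(
            [
                self.asymmetric[[i for i, s in enumerate(self.specimen_ids) if s == sid]].mean(0)
                for sid in ids
            ]
        )
        return ids, sym, asym


def decompose_symmetry(
    sample: StudySample | list,
    smap: SymmetryMap,
    allow_reflection: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> SymmetryDecomposition:
    """Decompose every observation into symmetric and asymmetric components.

    The 2N set {originals} ∪ {reflected-relabeled copies} is jointly
    superimposed by GPA with reflection-free rotations; the consensus is
    symmetrised at every iteration, so it is an exactly symmetric shape. For
    each observation, the symmetric component is the average of its aligned
    original and aligned mirror, and the asymmetric component is half their
    difference.
    """
    if isinstance(sample, StudySample):
        configs = list(sample.configurations)
    else:
        configs = list(sample)
    if len(configs) < 2:
        raise SymmetryMapError("object-symmetry decomposition needs at least 2 observations")
    coords = [
        c.coords if isinstance(c, LandmarkConfiguration) else np.asarray(c, float)
        for c in configs
    ]
    L, D = coords[0].shape
    validate_symmetry_map(smap, L)
    if smap.k == 0:
        raise SymmetryMapError("object symmetry is undefined without at least one landmark pair")
    perm = _relabel_permutation(smap, L)
    mirrored = [reflect_relabel(c, smap, _perm=perm) for c in coords]

    def _symmetrise(C: np.ndarray) -> np.ndarray:
        return 0.5 * (C + reflect_relabel(C, smap, _perm=perm))

    if isinstance(configs[0], LandmarkConfiguration):
        ids = tuple(c.specimen_id for c in configs)
        reps = tuple(c.replicate for c in configs)
    else:
        ids = tuple(f"obs{i + 1}" for i in range(len(configs)))
        reps = tuple(1 for _ in configs)

    aligned = gpa_align(
        coords + mirrored,
        allow_reflection=allow_reflection,
        tol=tol,
        max_iter=max_iter,
        consensus_hook=_symmetrise,
        labels=tuple(zip(ids + ids, reps + reps)),
    )
    N = len(coords)
    A = aligned.procrustes_coords[:N]
    Am = aligned.procrustes_coords[N:]
    return SymmetryDecomposition(
        specimen_ids=ids,
        replicates=reps,
        symmetric=0.5 * (A + Am),
        asymmetric=0.5 * (A - Am),
        consensus=aligned.consensus,
        map=smap,
        dims=symmetry_subspace_dims(smap, D),
        aligned=AlignedSample(
            procrustes_coords=A,
            centroid_sizes=aligned.centroid_sizes[:N],
            consensus=aligned.consensus,
            iterations=aligned.iterations,
            converged=aligned.converged,
            labels=tuple(zip(ids, reps)),
        ),
    )


def individual_fa_scores(dec: SymmetryDecomposition, correct_da: bool = True) -> pd.Series:
    """Scalar fluctuating-asymmetry score per specimen.

    Asymmetric components are averaged over replicates per specimen; the
    score is the Procrustes (Euclidean) norm of the specimen's mean
    asymmetric component, after subtracting the sample mean asymmetry
    (directional asymmetry) when ``correct_da`` is on (the default). With
    the correction, a sample whose asymmetry is purely directional scores
    zero for every specimen.
    """
    ids, _, asym = dec.specimen_means()
    if correct_da:
        asym = asym - asym.mean(axis=0)
    scores = np.sqrt((asym**2).sum(axis=(1, 2)))
    return pd.Series(scores, index=pd.Index(ids, name="specimen_id"), name="fa_score")
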