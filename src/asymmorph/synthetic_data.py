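"""Synthetic landmark and meristic data with known ground truth.

The generators mirror the variance structure the downstream analyses
assume, so every pipeline stage has a recoverable target:

* landmark observations = symmetric template
  + per-individual symmetric deviation (sigma_individual)
  + fixed directional-asymmetry field (da)
  + per-individual antisymmetric deviation (sigma_fa)
  + per-replicate digitising noise (sigma_me);
* bilateral counts = allometric mean count (R+L)/2 growing with body size,
  split across sides by a directional shift plus a per-individual normal
  fluctuating-asymmetry deviate.

Symmetric perturbations are generated exactly symmetric (projection through
the reflect-relabel operator) and asymmetric perturbations exactly
antisymmetric, so they live in the corresponding shape subspaces by
construction. All noise is isotropic Gaussian per landmark coordinate.
Identical parameters and seed give identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bilateral_symmetry import reflect_relabel
from .errors import DesignError, SymmetryMapError
from .landmark_io import (
    LandmarkConfiguration,
    MeristicRecord,
    StudySample,
    SymmetryMap,
    validate_symmetry_map,
)

__all__ = [
    "LandmarkSimParams",
    "MeristicSimParams",
    "echinoid_oral_template",
    "directional_asymmetry_field",
    "simulate_landmarks",
    "simulate_meristic",
]


# --------------------------------------------------------------------------- #
# Built-in template
# --------------------------------------------------------------------------- #

_TEMPLATE_POINTS: list[tuple[str, float, float]] = [
    # medians on the x = 0 midline (oral view, anterior up)
    ("peristome_anterior", 0.0, 0.35),
    ("labrum_tip", 0.0, 0.10),
    ("plastron_posterior", 0.0, -0.85),
    # paired landmarks: stored as the left-side (x < 0) member
    ("anterior_petal_tip", -0.52, 0.72),
    ("anterior_petal_base", -0.18, 0.48),
    ("posterior_petal_tip", -0.68, -0.12),
    ("posterior_petal_base", -0.20, 0.12),
    ("plastron_anterior_corner", -0.16, -0.05),
    ("plastron_widest", -0.30, -0.50),
    ("periplastronal_anterior", -0.33, -0.18),
    ("periplastronal_posterior", -0.38, -0.62),
    ("ambitus_widest", -0.95, -0.02),
]


def echinoid_oral_template() -> tuple[np.ndarray, SymmetryMap, tuple[str, ...]]:
    """Built-in 21-landmark 2D template: 9 pairs + 3 median landmarks.

    A stylised oral view of a spatangoid echinoid test (petals, plastron,
    periplastronal plates, ambitus), exactly bilaterally symmetric with the
    midline at x = 0, centred at the origin and scaled to unit centroid
    size. Returns ``(coords, symmetry_map, landmark_names)``.
    """
    coords: list[list[float]] = []
    names: list[str] = []
    pairs: list[tuple[int, int]] = []
    medians: list[int] = []
    for name, x, y in _TEMPLATE_POINTS:
        if x == 0.0:
            medians.append(len(coords))
            coords.append([0.0, y])
            names.append(name)
        else:
            left = len(coords)
            coords.append([x, y])
            names.append(f"{name}_L")
            coords.append([-x, y])
            names.append(f"{name}_R")
            pairs.append((left, left + 1))
    T = np.asarray(coords, dtype=float)
    T = T - T.mean(axis=0)  # centroid x is exactly 0, so symmetry survives
    T = T / np.sqrt((T**2).sum())
    return T, SymmetryMap(pairs=tuple(pairs), medians=tuple(medians)), tuple(names)


# --------------------------------------------------------------------------- #
# Landmark simulation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class LandmarkSimParams:
    """Parameters of the landmark generator.

    Sigmas are per-coordinate standard deviations in shape units on the
    unit-centroid-size template. Defaults reflect a modest fossil sample:
    symmetric individual variation an order of magnitude above FA, FA a few
    times above digitising noise, two digitising replicates per specimen.
    ``da_magnitude`` is the Procrustes norm of the directional-asymmetry
    field after projection onto the asymmetric tangent subspace (so the
    mean asymmetric component recovers it one-to-one); alternatively a raw
    ``da_vector`` (L x D) may be supplied, whose antisymmetric tangent part
    is used.
    """

    template: np.ndarray | None = None
    symmetry_map: SymmetryMap | None = None
    landmark_names: tuple[str, ...] = ()
    n_individuals: int = 33
    replicates: int = 2
    sigma_individual: float = 0.03
    sigma_fa: float = 0.01
    sigma_me: float = 0.003
    da_magnitude: float = 0.02
    da_vector: np.ndarray | None = None
    population: str = "synthetic"
    seed: int = 0

    def resolve(self) -> "LandmarkSimParams":
        """Fill in the built-in echinoid-oral template where unspecified."""
        if self.template is None or self.symmetry_map is None:
            T, smap, names = echinoid_oral_template()
            return replace(
                self,
                template=T if self.template is None else self.template,
                symmetry_map=smap if self.symmetry_map is None else self.symmetry_map,
                landmark_names=self.landmark_names or names,
            )
        return self

    def validate(self) -> "LandmarkSimParams":
        p = self.resolve()
        T, smap = p.template, p.symmetry_map
        validate_symmetry_map(smap, T.shape[0])
        if not np.allclose(T, reflect_relabel(T, smap), atol=1e-12):
            raise SymmetryMapError(
                "template is not symmetric under reflect_relabel; the generator "
                "requires an exactly symmetric template"
            )
        for name in ("sigma_individual", "sigma_fa", "sigma_me", "da_magnitude"):
            if getattr(p, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if p.n_individuals < 2 or p.replicates < 1:
            raise DesignError("need n_individuals >= 2 and replicates >= 1")
        return p


def _similarity_fields(T: np.ndarray) -> np.ndarray:
    """Tangent fields of translation, rotation and scale at template T (rows)."""
    L, D = T.shape
    fields = []
    for d in range(D):  # translations
        f = np.zeros((L, D))
        f[:, d] = 1.0
        fields.append(f)
    if D == 2:
        rots = [np.array([[0.0, -1.0], [1.0, 0.0]])]
    else:
        rots = [
            np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
            np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]], float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
        ]
    for G in rots:
        fields.append(T @ G.T)
    fields.append(T.copy())  # scale
    return np.stack([f.reshape(-1) for f in fields])


def directional_asymmetry_field(params: LandmarkSimParams) -> np.ndarray:
    """Ground-truth DA field (L x D) injected by :func:`simulate_landmarks`.

    The raw field (user-supplied ``da_vector``, or by default a displacement
    of the first landmark pair along the second axis) is antisymmetrised,
    orthogonalised against the antisymmetric similarity-transform directions
    (which a Procrustes fit would absorb), and scaled. With a raw
    ``da_vector`` the antisymmetric tangent part is used as-is; otherwise
    the field is normalised to ``da_magnitude``.
    """
    p = params.validate()
    T, smap = p.template, p.symmetry_map
    if p.da_vector is not None:
        raw = np.asarray(p.da_vector, dtype=float)
        if raw.shape != T.shape:
            raise DesignError(f"da_vector shape {raw.shape} != template shape {T.shape}")
        normalise = False
    else:
        if p.da_magnitude == 0.0:
            return np.zeros_like(T)
        raw = np.zeros_like(T)
        a, b = smap.pairs[0]
        raw[a, 1] = 1.0
        raw[b, 1] = -1.0
        normalise = True
    anti = 0.5 * (raw - reflect_relabel(raw, smap))
    flat = anti.reshape(-1)
    # Remove components a similarity fit would absorb (antisymmetric parts
    # of the translation/rotation/scale tangent fields).
    sim = _similarity_fields(T)
    sim_anti = np.stack(
        [
            0.5 * (f.reshape(T.shape) - reflect_relabel(f.reshape(T.shape), smap)).reshape(-1)
            for f in sim
        ]
    )
    keep = np.linalg.norm(sim_anti, axis=1) > 1e-12
    if keep.any():
        Q, _ = np.linalg.qr(sim_anti[keep].T)
        flat = flat - Q @ (Q.T @ flat)
    norm = np.linalg.norm(flat)
    if normalise:
        if norm < 1e-12:
            raise DesignError("default DA direction degenerate for this template")
        flat = flat / norm * p.da_magnitude
    return flat.reshape(T.shape)


def simulate_landmarks(params: LandmarkSimParams) -> StudySample:
    """Generate a replicated landmark sample with known variance components.

    observation(i, rep) = template + sym_i + da + fa_i + noise_{i,rep}

    with sym_i the symmetric projection of isotropic N(0, sigma_individual^2)
    noise, fa_i the antisymmetric projection of N(0, sigma_fa^2) noise, da
    the fixed field of :func:`directional_asymmetry_field`, and noise_{i,rep}
    raw N(0, sigma_me^2) digitising error.
    """
    p = params.validate()
    T, smap = p.template, p.symmetry_map
    rng = np.random.default_rng(p.seed)
    da = directional_asymmetry_field(p)
    configs: list[LandmarkConfiguration] = []
    width = len(str(p.n_individuals))
    for i in range(p.n_individuals):
        eps_sym = rng.normal(0.0, 1.0, size=T.shape) * p.sigma_individual
        sym_i = 0.5 * (eps_sym + reflect_relabel(eps_sym, smap))
        eps_fa = rng.normal(0.0, 1.0, size=T.shape) * p.sigma_fa
        fa_i = 0.5 * (eps_fa - reflect_relabel(eps_fa, smap))
        base = T + sym_i + da + fa_i
        for rep in range(1, p.replicates + 1):
            noise = rng.normal(0.0, 1.0, size=T.shape) * p.sigma_me
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"sim{i + 1:0{width}d}",
                    replicate=rep,
                    coords=base + noise,
                    landmark_names=p.landmark_names,
                )
            )
    return StudySample(
        population=p.population,
        configurations=tuple(configs),
        replicate_count=p.replicates,
    )


# --------------------------------------------------------------------------- #
# Meristic simulation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class MeristicSimParams:
    """Parameters of the bilateral-count generator.

    Defaults emulate pore-pair counts of an anterior paired petal against
    test length in mm: sizes uniform on 30-60 mm, mean count rising ~0.9
    pore pairs per mm, a directional shift of ~0.6 pore pairs and an FA
    standard deviation of ~1.45 (so FA4a ~ 1.16), on the scale of the
    weaker-asymmetry study population. Counts are rounded to integers after
    side-splitting, which attenuates FA realistically at small sigma.
    """

    n: int = 35
    base_count: float = 5.0
    allometry_slope: float = 0.9
    size_range: tuple[float, float] = (30.0, 60.0)
    da_shift: float = 0.57
    sigma_fa_count: float = 1.45
    rounding: bool = True
    log_linear: bool = False
    trait: str = "anterior_petals"
    population: str = "synthetic"
    seed: int = 0


def simulate_meristic(params: MeristicSimParams) -> list[MeristicRecord]:
    """Generate paired counts with allometric size dependence plus DA and FA.

    size_i ~ Uniform(size_range); mean count mu_i = base + slope * size_i
    (or log10-linear with ``log_linear``); the side split is
    R = mu + (da + e_i)/2, L = mu - (da + e_i)/2 with e_i ~ N(0,
    sigma_fa_count^2), optionally rounded to integers. Parameters whose
    expected counts go negative are rejected.
    """
    p = params
    if p.n < 3:
        raise DesignError(f"need n >= 3, got {p.n}")
    lo, hi = p.size_range
    if not (0 < lo <= hi):
        raise DesignError(f"invalid size_range {p.size_range}")
    if p.sigma_fa_count < 0:
        raise DesignError("sigma_fa_count must be >= 0")
    mu_lo = (
        p.base_count * (lo / 1.0) ** p.allometry_slope
        if p.log_linear
        else p.base_count + p.allometry_slope * lo
    )
    if mu_lo - abs(p.da_shift) / 2.0 < 0:
        raise DesignError(
            f"expected counts negative at the lower size bound (mu={mu_lo:.2f}, "
            f"da_shift={p.da_shift}); adjust base_count/allometry_slope"
        )
    rng = np.random.default_rng(p.seed)
    sizes = rng.uniform(lo, hi, size=p.n)
    records: list[MeristicRecord] = []
    width = len(str(p.n))
    for i, size in enumerate(sizes):
        mu = (
            p.base_count * size**p.allometry_slope
            if p.log_linear
            else p.base_count + p.allometry_slope * size
        )
        e = rng.normal(0.0, p.sigma_fa_count) if p.sigma_fa_count > 0 else 0.0
        half = 0.5 * (p.da_shift + e)
        right, left = mu + half, mu - half
        if p.rounding:
            right, left = round(right), round(left)
        if right < 0 or left < 0:
            raise DesignError(
                f"realised negative count for specimen {i + 1}; parameters place "
                f"counts too close to zero for the noise level"
            )
        records.append(
            MeristicRecord(
                specimen_id=f"sim{i + 1:0{width}d}",
                population=p.population,
                trait=p.trait,
                right_count=int(right) if p.rounding else right,
                left_count=int(left) if p.rounding else left,
                size=float(size),
            )
        )
    return records
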