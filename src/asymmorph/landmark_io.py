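"""Reading, writing and validating landmark and bilateral-trait data.

Supported inputs
----------------
* MeshLab PickPoints XML (``.pp``) — one digitising session per file.
* Long-format CSV landmark tables (``specimen_id, replicate, landmark, x, y[, z]``).
* TPS files (``LM=`` / ``ID=`` blocks, 2D), with the replicate number encoded
  in the ID as a ``__rep<k>`` suffix.
* Counts CSV (``specimen_id, population, trait, right_count, left_count, size``)
  for meristic (countable) bilateral traits.
* States CSV (``specimen_id, population, trait, state``) for categorical traits.

Landmark indices are 0-based everywhere inside the package; file formats and
user-facing symmetry-map files are 1-based (matching the conventional figure
numbering of landmark maps) and are converted at this boundary only.
"""

from __future__ import annotations

import csv
import io
import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CongruenceError,
    LandmarkFormatError,
    SymmetryMapError,
)

__all__ = [
    "LandmarkConfiguration",
    "SymmetryMap",
    "StudySample",
    "MeristicRecord",
    "CategoricalTraitRecord",
    "TRAIT_VOCABULARIES",
    "read_pickpoints",
    "read_landmark_table",
    "write_landmark_table",
    "read_counts_csv",
    "write_counts_csv",
    "read_states_csv",
    "validate_symmetry_map",
    "read_symmetry_map",
    "write_symmetry_map",
    "group_into_sample",
]


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True, eq=False)
class LandmarkConfiguration:
    """One specimen x replicate landmark set: an L x D coordinate matrix.

    Parameters
    ----------
    specimen_id : str
        Specimen label (e.g. a collection number).
    replicate : int
        Digitising-session number, >= 1. Replicates of the same specimen are
        what the measurement-error stratum of the Procrustes ANOVA sees.
    coords : (L, D) float array
        Cartesian landmark coordinates, D in {2, 3}; all values finite.
    landmark_names : tuple of str
        One label per landmark, in row order.
    """

    specimen_id: str
    replicate: int
    coords: np.ndarray
    landmark_names: tuple[str, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise LandmarkFormatError(
                f"{self.specimen_id}: coordinates must be a 2-D matrix, got shape {coords.shape}"
            )
        L, D = coords.shape
        if D not in (2, 3):
            raise LandmarkFormatError(f"{self.specimen_id}: dimension must be 2 or 3, got {D}")
        if L < 3:
            raise LandmarkFormatError(f"{self.specimen_id}: need at least 3 landmarks, got {L}")
        if not np.all(np.isfinite(coords)):
            bad = np.argwhere(~np.isfinite(coords))[0]
            raise LandmarkFormatError(
                f"{self.specimen_id} (replicate {self.replicate}): non-finite coordinate "
                f"at landmark {bad[0] + 1}, axis {bad[1]}"
            )
        if int(self.replicate) < 1:
            raise LandmarkFormatError(f"{self.specimen_id}: replicate must be >= 1")
        names = tuple(self.landmark_names) or tuple(f"lm{i + 1}" for i in range(L))
        if len(names) != L:
            raise LandmarkFormatError(
                f"{self.specimen_id}: {len(names)} landmark names for {L} landmarks"
            )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "replicate", int(self.replicate))
        object.__setattr__(self, "landmark_names", names)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def __eq__(self, other):
        if not isinstance(other, LandmarkConfiguration):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.replicate == other.replicate
            and self.landmark_names == other.landmark_names
            and np.array_equal(self.coords, other.coords)
        )


@dataclass(frozen=True)
class SymmetryMap:
    """Paired-landmark declaration for object symmetry.

    ``pairs`` holds 0-based ``(left_index, right_index)`` tuples; ``medians``
    holds the indices of unpaired landmarks lying on the midline.
    """

    pairs: tuple[tuple[int, int], ...]
    medians: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs)
        )
        object.__setattr__(self, "medians", tuple(int(m) for m in self.medians))

    @property
    def k(self) -> int:
        """Number of landmark pairs."""
        return len(self.pairs)

    @property
    def u(self) -> int:
        """Number of median (unpaired) landmarks."""
        return len(self.medians)

    def all_indices(self) -> list[int]:
        return [i for p in self.pairs for i in p] + list(self.medians)


@dataclass(frozen=True)
class StudySample:
    """A population's replicated landmark configurations.

    Every specimen must carry exactly ``replicate_count`` replicates and all
    configurations must be dimensionally congruent (same L, D and landmark
    label order). Incompletely replicated or incongruent input is a hard
    error: the analyses downstream assume a balanced design.
    """

    population: str
    configurations: tuple[LandmarkConfiguration, ...]
    replicate_count: int

    def __post_init__(self):
        configs = tuple(self.configurations)
        if not configs:
            raise CongruenceError(f"population {self.population!r}: empty sample")
        ref = configs[0]
        offenders = [
            c.specimen_id
            for c in configs
            if c.coords.shape != ref.coords.shape or c.landmark_names != ref.landmark_names
        ]
        if offenders:
            raise CongruenceError(
                f"population {self.population!r}: configurations not congruent with "
                f"{ref.specimen_id!r} (L={ref.n_landmarks}, D={ref.n_dims}): {sorted(set(offenders))}"
            )
        counts: dict[str, int] = {}
        for c in configs:
            counts[c.specimen_id] = counts.get(c.specimen_id, 0) + 1
        bad = {s: n for s, n in counts.items() if n != self.replicate_count}
        if bad:
            raise CongruenceError(
                f"population {self.population!r}: expected {self.replicate_count} replicates "
                f"per specimen, offenders: {bad}"
            )
        object.__setattr__(self, "configurations", configs)
        object.__setattr__(self, "replicate_count", int(self.replicate_count))

    @property
    def specimen_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.configurations:
            if c.specimen_id not in seen:
                seen.append(c.specimen_id)
        return seen

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_landmarks(self) -> int:
        return self.configurations[0].n_landmarks

    @property
    def n_dims(self) -> int:
        return self.configurations[0].n_dims

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an (N_obs, L, D) array (file order)."""
        return np.stack([c.coords for c in self.configurations])


@dataclass(frozen=True)
class MeristicRecord:
    """Bilateral count of one meristic trait with the specimen's body size.

    ``size`` is the size covariate (for spatangoid pore-pair counts, the
    test length in mm); counts are exact non-negative integers.
    """

    specimen_id: str
    population: str
    trait: str
    right_count: int | float
    left_count: int | float
    size: float

    def __post_init__(self):
        # Real counts are exact non-negative integers; unrounded (continuous)
        # counts are tolerated so the synthetic generator can bypass the
        # integer-rounding attenuation of FA when asked to.
        for side, v in (("right", self.right_count), ("left", self.left_count)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.specimen_id}: {side}_count must be a non-negative number, got {v!r}"
                )
        if not (self.size > 0):
            raise ValueError(f"{self.specimen_id}: size must be positive, got {self.size!r}")
        coerce = lambda v: int(v) if float(v).is_integer() else float(v)
        object.__setattr__(self, "right_count", coerce(self.right_count))
        object.__setattr__(self, "left_count", coerce(self.left_count))
        object.__setattr__(self, "size", float(self.size))

    @property
    def signed_diff(self) -> int:
        """Right minus left count (R - L)."""
        return self.right_count - self.left_count

    @property
    def mean_count(self) -> float:
        """(R + L) / 2, the per-specimen trait size used as allometry response."""
        return 0.5 * (self.right_count + self.left_count)


#: Declared ordered vocabularies for the categorical traits of the study
#: system (subanal fasciole development and labral projection of a spatangoid
#: echinoid test). Users may register additional traits by passing their own
#: vocabulary mapping to :func:`asymmorph.meristic_fa.tabulate_states`.
TRAIT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "subanal_fasciole": (
        "absent",
        "incomplete",
        "protofasciole",
        "parafasciole",
        "orthofasciole",
    ),
    "labrum_projection": ("open", "covered", "exceeding"),
}


@dataclass(frozen=True)
class CategoricalTraitRecord:
    """One specimen's state for an ordered categorical trait."""

    specimen_id: str
    population: str
    trait: str
    state: str

    def __post_init__(self):
        vocab = TRAIT_VOCABULARIES.get(self.trait)
        if vocab is not None and self.state not in vocab:
            raise ValueError(
                f"{self.specimen_id}: state {self.state!r} not in vocabulary of trait "
                f"{self.trait!r} {vocab}"
            )


# --------------------------------------------------------------------------- #
# Symmetry map validation and (de)serialisation
# --------------------------------------------------------------------------- #

def validate_symmetry_map(smap: SymmetryMap, n_landmarks: int) -> SymmetryMap:
    """Check a symmetry map against a configuration of ``n_landmarks``.

    Indices must be in range, pairwise distinct and disjoint between pairs
    and medians. Returns the map unchanged on success.

    Raises
    ------
    SymmetryMapError
        Naming the offending (1-based) index.
    """
    seen: set[int] = set()
    for idx in smap.all_indices():
        if not (0 <= idx < n_landmarks):
            raise SymmetryMapError(
                f"landmark index {idx + 1} out of range for L={n_landmarks}"
            )
        if idx in seen:
            raise SymmetryMapError(f"landmark index {idx + 1} declared more than once")
        seen.add(idx)
    for a, b in smap.pairs:
        if a == b:
            raise SymmetryMapError(f"pair maps landmark {a + 1} to itself")
    return smap


def read_symmetry_map(path: str | Path) -> SymmetryMap:
    """Read a JSON symmetry map. Indices in the file are 1-based."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        pairs = tuple((int(a) - 1, int(b) - 1) for a, b in data["pairs"])
        medians = tuple(int(m) - 1 for m in data.get("medians", ()))
    except (KeyError, TypeError, ValueError) as exc:
        raise LandmarkFormatError(f"{path}: invalid symmetry map file: {exc}") from exc
    return SymmetryMap(pairs=pairs, medians=medians)


def write_symmetry_map(smap: SymmetryMap, path: str | Path) -> None:
    """Write a symmetry map as JSON with 1-based indices."""
    data = {
        "pairs": [[a + 1, b + 1] for a, b in smap.pairs],
        "medians": [m + 1 for m in smap.medians],
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


# --------------------------------------------------------------------------- #
# MeshLab PickPoints
# --------------------------------------------------------------------------- #

def read_pickpoints(
    path: str | Path,
    specimen_id: str | None = None,
    replicate: int = 1,
) -> LandmarkConfiguration:
    """Read a MeshLab PickPoints (``.pp``) XML file.

    One ``.pp`` file holds one digitising session; the replicate number
    therefore comes from the caller (the study manifest), not from the XML.
    Points are returned in file order. A point flagged inactive is rejected
    outright rather than silently dropped, since silently shrinking L would
    break congruence with the rest of the study.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise LandmarkFormatError(
            f"{path}: malformed XML at line {line}, column {col}: {exc}"
        ) from exc
    root = tree.getroot()
    coords: list[list[float]] = []
    names: list[str] = []
    points = list(root.iter("point"))
    if not points:
        raise LandmarkFormatError(f"{path}: no <point> elements found")
    for i, pt in enumerate(points):
        name = pt.get("name", f"lm{i + 1}")
        active = pt.get("active", "1").strip().lower()
        if active in ("0", "false"):
            raise LandmarkFormatError(
                f"{path}: point {name!r} is flagged inactive; remove or re-pick it in "
                f"MeshLab and re-export before loading"
            )
        row = []
        for axis in ("x", "y", "z"):
            raw = pt.get(axis)
            if raw is None:
                raise LandmarkFormatError(
                    f"{path}: point {name!r} is missing coordinate attribute {axis!r}"
                )
            try:
                row.append(float(raw))
            except ValueError as exc:
                raise LandmarkFormatError(
                    f"{path}: point {name!r} has non-numeric {axis!r}: {raw!r}"
                ) from exc
        coords.append(row)
        names.append(name)
    return LandmarkConfiguration(
        specimen_id=specimen_id or path.stem,
        replicate=replicate,
        coords=np.asarray(coords, dtype=float),
        landmark_names=tuple(names),
    )


# --------------------------------------------------------------------------- #
# CSV / TPS landmark tables
# --------------------------------------------------------------------------- #

_CSV_REQUIRED = ("specimen_id", "replicate", "landmark", "x", "y")


def read_landmark_table(path: str | Path, dialect: str = "csv") -> list[LandmarkConfiguration]:
    """Read a multi-specimen landmark table (``csv`` or ``tps`` dialect).

    Configurations are grouped by (specimen, replicate) in file order and
    checked for congruence of landmark count, dimension and label order.
    """
    if dialect == "csv":
        return _read_csv_table(Path(path))
    if dialect == "tps":
        return _read_tps(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tps'")


def _read_csv_table(path: Path) -> list[LandmarkConfiguration]:
    try:
        # round_trip parsing so write->read reproduces coordinates exactly
        df = pd.read_csv(
            path,
            dtype={"specimen_id": str, "landmark": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LandmarkFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise LandmarkFormatError(f"{path}: missing required columns {missing}")
    axes = ["x", "y"] + (["z"] if "z" in df.columns else [])
    if df[axes].isna().any().any() or not np.all(np.isfinite(df[axes].to_numpy(float))):
        raise LandmarkFormatError(f"{path}: non-finite or missing coordinate values")
    configs: list[LandmarkConfiguration] = []
    shapes: dict[tuple[str, int], tuple[int, tuple[str, ...]]] = {}
    for (sid, rep), grp in df.groupby(["specimen_id", "replicate"], sort=False):
        names = tuple(grp["landmark"].tolist())
        shapes[(str(sid), int(rep))] = (len(grp), names)
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(sid),
                replicate=int(rep),
                coords=grp[axes].to_numpy(dtype=float),
                landmark_names=names,
            )
        )
    ref_L, ref_names = next(iter(shapes.values()))
    offenders = [key for key, val in shapes.items() if val != (ref_L, ref_names)]
    if offenders:
        raise CongruenceError(
            f"{path}: configurations disagree in landmark count/order; offenders "
            f"(specimen, replicate): {offenders}"
        )
    return configs


_REP_SUFFIX = re.compile(r"^(?P<sid>.*?)__rep(?P<rep>\d+)$")


def _read_tps(path: Path) -> list[LandmarkConfiguration]:
    """Minimal TPS reader: LM= blocks of 2D coordinate lines plus ID= records."""
    configs: list[LandmarkConfiguration] = []
    lines = Path(path).read_text().splitlines()
    i, block_no = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise LandmarkFormatError(f"{path}: line {i + 1}: expected 'LM=', got {line!r}")
        try:
            L = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise LandmarkFormatError(f"{path}: line {i + 1}: bad LM count {line!r}") from exc
        i += 1
        coords = []
        for _ in range(L):
            if i >= len(lines):
                raise LandmarkFormatError(f"{path}: unexpected end of file inside LM block")
            parts = lines[i].split()
            if len(parts) != 2:
                raise LandmarkFormatError(
                    f"{path}: line {i + 1}: expected 2 coordinates, got {lines[i]!r}"
                )
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        block_no += 1
        sid, rep = f"block{block_no}", 1
        # optional trailing keyword records until next LM=
        while i < len(lines) and not lines[i].strip().upper().startswith("LM="):
            rec = lines[i].strip()
            if rec.upper().startswith("ID="):
                raw = rec.split("=", 1)[1].strip()
                m = _REP_SUFFIX.match(raw)
                if m:
                    sid, rep = m.group("sid"), int(m.group("rep"))
                else:
                    sid = raw
            i += 1
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid, replicate=rep, coords=np.asarray(coords, dtype=float)
            )
        )
    if not configs:
        raise LandmarkFormatError(f"{path}: no LM= blocks found")
    ref = configs[0]
    offenders = [
        (c.specimen_id, c.replicate)
        for c in configs
        if c.coords.shape != ref.coords.shape
    ]
    if offenders:
        raise CongruenceError(f"{path}: ragged landmark counts; offenders: {offenders}")
    return configs


def write_landmark_table(
    configs: Iterable[LandmarkConfiguration] | StudySample, path: str | Path
) -> None:
    """Write configurations as a long-format CSV landmark table."""
    if isinstance(configs, StudySample):
        configs = configs.configurations
    rows = []
    for c in configs:
        axes = ["x", "y", "z"][: c.n_dims]
        for name, xyz in zip(c.landmark_names, c.coords):
            row = {"specimen_id": c.specimen_id, "replicate": c.replicate, "landmark": name}
            row.update({a: repr(float(v)) for a, v in zip(axes, xyz)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def group_into_sample(
    configs: Sequence[LandmarkConfiguration],
    population: str,
    replicate_count: int | None = None,
) -> StudySample:
    """Bundle configurations into a validated :class:`StudySample`.

    If ``replicate_count`` is omitted it is inferred from the first specimen
    and then enforced on all others.
    """
    if replicate_count is None:
        first = configs[0].specimen_id
        replicate_count = sum(1 for c in configs if c.specimen_id == first)
    return StudySample(
        population=population,
        configurations=tuple(configs),
        replicate_count=replicate_count,
    )


# --------------------------------------------------------------------------- #
# Counts / states CSV
# --------------------------------------------------------------------------- #

def read_counts_csv(path: str | Path) -> list[MeristicRecord]:
    """Read bilateral counts (``specimen_id, population, trait, right_count,
    left_count, size``)."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "population": str, "trait": str})
    required = ["specimen_id", "population", "trait", "right_count", "left_count", "size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LandmarkFormatError(f"{path}: missing required columns {missing}")
    return [
        MeristicRecord(
            specimen_id=r.specimen_id,
            population=r.population,
            trait=r.trait,
            right_count=int(r.right_count),
            left_count=int(r.left_count),
            size=float(r.size),
        )
        for r in df.itertuples()
    ]


def write_counts_csv(records: Iterable[MeristicRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "population": r.population,
                "trait": r.trait,
                "right_count": r.right_count,
                "left_count": r.left_count,
                "size": r.size,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_states_csv(path: str | Path) -> list[CategoricalTraitRecord]:
    """Read categorical trait states (``specimen_id, population, trait, state``)."""
    df = pd.read_csv(path, dtype=str)
    required = ["specimen_id", "population", "trait", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LandmarkFormatError(f"{path}: missing required columns {missing}")
    return [
        CategoricalTraitRecord(
            specimen_id=r.specimen_id,
            population=r.population,
            trait=r.trait,
            state=r.state,
        )
        for r in df.itertuples()
    ]
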