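"""Mixed-model Procrustes ANOVA for object symmetry, and Levene's test on
fluctuating-asymmetry scores.

The two-factor design crosses individuals (random) with sides (fixed, the
original vs. reflected-relabeled copy), with replicate digitisations as the
bottom stratum. Directional asymmetry (DA) is tested by the side main
effect; fluctuating asymmetry (FA) by the individual-by-side interaction;
the interaction is tested against measurement error.

Sums of squares are Procrustes sums of squares: coordinate-wise two-factor
sums of squares summed over all landmark coordinates of the 2N augmented
data set (originals plus mirrored copies). Degrees of freedom multiply the
conventional factorial df by the dimension of the shape subspace each
effect occupies: individuals vary in the symmetric subspace (dimension s),
side and interaction in the asymmetric subspace (dimension a), replicate
error in both (s + a).

Effect        SS                                   df
-----------   ----------------------------------   -----------------
Individual    2r * sum_i ||sym_i - sym_bar||^2      (n-1) * s
Side          2nr * ||asym_bar||^2                  a
Ind x Side    2r * sum_i ||asym_i - asym_bar||^2    (n-1) * a
Meas. error   2 * sum_ij (||sym_ij - sym_i||^2
                        + ||asym_ij - asym_i||^2)   n * (r-1) * (s+a)

F ratios follow the mixed model: F_Individual = MS_Ind / MS_IndxSide,
F_Side = MS_Side / MS_IndxSide, F_IndxSide = MS_IndxSide / MS_Error, with
parametric P values from the F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bilateral_symmetry import SymmetryDecomposition, decompose_symmetry
from .errors import DesignError
from .landmark_io import StudySample, SymmetryMap

__all__ = [
    "AnovaRow",
    "ProcrustesAnovaTable",
    "procrustes_anova",
    "assemble_anova_table",
    "variance_components",
    "levene_shape_fa",
]

EFFECT_INDIVIDUAL = "Individual"
EFFECT_SIDE = "Side"
EFFECT_INTERACTION = "Individual x Side"
EFFECT_ERROR = "Measurement error"
_CANONICAL_ORDER = (EFFECT_INDIVIDUAL, EFFECT_SIDE, EFFECT_INTERACTION, EFFECT_ERROR)


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    SS: float
    df: int
    MS: float
    F: float | None = None
    P: float | None = None


@dataclass(frozen=True)
class ProcrustesAnovaTable:
    """Effects x {SS, df, MS, F, P}; machine twin of a printed Procrustes
    ANOVA table (column order SS, MS, df, F, P when formatted)."""

    rows: tuple[AnovaRow, ...]
    n_individuals: int | None = None
    n_replicates: int | None = None
    dims: tuple[int, int] | None = None

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    @property
    def effects(self) -> tuple[str, ...]:
        return tuple(r.effect for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"Effect": r.effect, "SS": r.SS, "MS": r.MS, "df": r.df, "F": r.F, "P": r.P}
                for r in self.rows
            ]
        ).set_index("Effect")

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def format_text(self) -> str:
        """Aligned plain-text table (columns SS, MS, df, F, P)."""
        header = f"{'Effect':<20}{'SS':>14}{'MS':>14}{'df':>7}{'F':>9}{'P':>12}"
        lines = [header, "-" * len(header)]
        for r in self.rows:
            f_str = "" if r.F is None else ("inf" if np.isinf(r.F) else f"{r.F:.2f}")
            if r.P is None or (isinstance(r.P, float) and np.isnan(r.P)):
                p_str = ""
            elif r.P < 1e-4:
                p_str = "<0.0001"
            else:
                p_str = f"{r.P:.4f}"
            lines.append(
                f"{r.effect:<20}{r.SS:>14.8f}{r.MS:>14.4e}{r.df:>7d}{f_str:>9}{p_str:>12}"
            )
        return "\n".join(lines)


def _component_sums_of_squares(
    dec: SymmetryDecomposition, n: int, r: int
) -> tuple[float, float, float, float]:
    """(SS_ind, SS_side, SS_ixs, SS_err) from a decomposition with balanced r."""
    ids, sym_means, asym_means = dec.specimen_means()
    grand_sym = sym_means.mean(axis=0)
    grand_asym = asym_means.mean(axis=0)
    ss_ind = 2.0 * r * float(((sym_means - grand_sym) ** 2).sum())
    ss_side = 2.0 * n * r * float((grand_asym**2).sum())
    ss_ixs = 2.0 * r * float(((asym_means - grand_asym) ** 2).sum())
    ss_err = 0.0
    for j, sid in enumerate(ids):
        idx = [i for i, s in enumerate(dec.specimen_ids) if s == sid]
        ss_err += 2.0 * float(((dec.symmetric[idx] - sym_means[j]) ** 2).sum())
        ss_err += 2.0 * float(((dec.asymmetric[idx] - asym_means[j]) ** 2).sum())
    return ss_ind, ss_side, ss_ixs, ss_err


def procrustes_anova(
    sample: StudySample,
    smap: SymmetryMap,
    dec: SymmetryDecomposition | None = None,
) -> ProcrustesAnovaTable:
    """Procrustes ANOVA of a replicated, bilaterally symmetric sample.

    Requires a balanced design (every specimen digitised the same number of
    times). With a single replicate the measurement-error stratum is absent
    and the individual-by-side interaction becomes the bottom stratum (its F
    and P are then unavailable).

    Parameters
    ----------
    sample : StudySample
        Replicated landmark configurations of one population.
    smap : SymmetryMap
        Paired/median landmark declaration.
    dec : SymmetryDecomposition, optional
        Pre-computed decomposition of exactly this sample (to avoid
        repeating the joint GPA).
    """
    n = sample.n_specimens
    r = sample.replicate_count
    if n < 3:
        raise DesignError(f"Procrustes ANOVA needs at least 3 specimens, got {n}")
    counts = {sid: 0 for sid in sample.specimen_ids}
    for c in sample.configurations:
        counts[c.specimen_id] += 1
    if len(set(counts.values())) != 1:
        raise DesignError(f"unbalanced replication is not supported: {counts}")
    if dec is None:
        dec = decompose_symmetry(sample, smap)
    s, a = dec.dims
    ss_ind, ss_side, ss_ixs, ss_err = _component_sums_of_squares(dec, n, r)
    rows = [
        (EFFECT_INDIVIDUAL, ss_ind, (n - 1) * s),
        (EFFECT_SIDE, ss_side, a),
        (EFFECT_INTERACTION, ss_ixs, (n - 1) * a),
    ]
    if r >= 2:
        rows.append((EFFECT_ERROR, ss_err, n * (r - 1) * (s + a)))
    table = assemble_anova_table(rows)
    return ProcrustesAnovaTable(
        rows=table.rows, n_individuals=n, n_replicates=r, dims=(s, a)
    )


def assemble_anova_table(
    ss_df: Sequence[tuple[str, float, int]]
) -> ProcrustesAnovaTable:
    """Fill MS, F and parametric P values from effect (name, SS, df) triples.

    Denominators follow the mixed model: Individual and Side are tested
    against the Individual x Side interaction; the interaction is tested
    against measurement error (when that stratum is present). If the error
    mean square is zero, the interaction F is flagged infinite and its P is
    undefined.
    """
    by_effect: dict[str, tuple[float, int]] = {}
    for effect, ss, df in ss_df:
        if df <= 0:
            raise DesignError(f"effect {effect!r}: df must be positive, got {df}")
        if ss < 0:
            raise DesignError(f"effect {effect!r}: SS must be non-negative, got {ss}")
        by_effect[effect] = (float(ss), int(df))
    unknown = set(by_effect) - set(_CANONICAL_ORDER)
    if unknown:
        raise DesignError(f"unknown effects {sorted(unknown)}; expected {_CANONICAL_ORDER}")

    def _ms(effect: str) -> float | None:
        if effect not in by_effect:
            return None
        ss, df = by_effect[effect]
        return ss / df

    denominators = {
        EFFECT_INDIVIDUAL: EFFECT_INTERACTION,
        EFFECT_SIDE: EFFECT_INTERACTION,
        EFFECT_INTERACTION: EFFECT_ERROR,
        EFFECT_ERROR: None,
    }
    rows: list[AnovaRow] = []
    for effect in _CANONICAL_ORDER:
        if effect not in by_effect:
            continue
        ss, df = by_effect[effect]
        ms = ss / df
        denom = denominators[effect]
        F = P = None
        if denom is not None and denom in by_effect:
            ms_denom = _ms(denom)
            df_denom = by_effect[denom][1]
            if ms_denom == 0.0:
                F = np.inf
                P = np.nan
            else:
                F = ms / ms_denom
                P = float(stats.f.sf(F, df, df_denom))
        rows.append(AnovaRow(effect=effect, SS=ss, df=df, MS=ms, F=F, P=P))
    return ProcrustesAnovaTable(rows=tuple(rows))


def variance_components(table: ProcrustesAnovaTable) -> dict[str, float]:
    """Per-coordinate variance-component estimates from the mean squares.

    In the augmented-data parameterisation (original plus mirror), the
    expected mean squares are E[MS_err] = 2 sigma_me^2,
    E[MS_ixs] = 2 (r sigma_fa^2 + sigma_me^2) and
    E[MS_ind] = 2 (r sigma_ind^2 + sigma_me^2), where each sigma^2 is the
    variance per coordinate of the corresponding effect within its shape
    subspace. The method-of-moments inversions below return estimates of
    sigma_me^2, sigma_fa^2 and sigma_ind^2 (negative estimates are not
    truncated).
    """
    r = table.n_replicates
    if r is None or r < 2:
        raise DesignError("variance components need a replicated design (r >= 2)")
    ms_err = table[EFFECT_ERROR].MS
    ms_ixs = table[EFFECT_INTERACTION].MS
    ms_ind = table[EFFECT_INDIVIDUAL].MS
    return {
        "sigma2_me": ms_err / 2.0,
        "sigma2_fa": (ms_ixs - ms_err) / (2.0 * r),
        "sigma2_ind": (ms_ind - ms_err) / (2.0 * r),
    }


def levene_shape_fa(
    scores_by_population: Mapping[str, Sequence[float]],
    center: str = "median",
) -> tuple[float, float]:
    """Levene's test for equality of FA magnitude across populations.

    The statistic is computed on absolute deviations of the individual FA
    scores from their group centre; the median centre (Brown-Forsythe
    variant, the default) is robust to departures from normality. Returns
    ``(W, P)`` from the F distribution.
    """
    groups = [np.asarray(v, dtype=float) for v in scores_by_population.values()]
    if len(groups) < 2:
        raise DesignError("Levene's test needs at least 2 groups")
    for name, g in zip(scores_by_population, groups):
        if len(g) < 2:
            raise DesignError(f"group {name!r} has fewer than 2 observations")
    if center not in ("median", "mean"):
        raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
    # All deviations zero (every group constant): no dispersion to compare.
    devs = [np.abs(g - (np.median(g) if center == "median" else g.mean())) for g in groups]
    if all(np.allclose(d, 0.0) for d in devs):
        return 0.0, 1.0
    W, P = stats.levene(*groups, center=center)
    if np.isnan(W):
        return 0.0, 1.0
    return float(W), float(P)
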