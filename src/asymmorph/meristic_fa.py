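"""Fluctuating-asymmetry protocol for bilateral counts, count-size allometry,
and categorical trait tabulation.

For a meristic (countable) bilateral trait the signed side difference
d = R - L per specimen is the raw asymmetry observation. The screening and
index pipeline, in fixed order:

1. iterated two-sided Grubbs outlier screen on the signed differences
   (outliers would artificially inflate FA);
2. Spearman rank correlation of |R - L| against trait size (R + L)/2 —
   size-dependent FA would confound between-sample comparisons;
3. Shapiro-Wilk normality test on the signed differences — ideal FA is
   normally distributed around zero; bimodality signals antisymmetry;
4. one-sample t test of d against zero — a non-zero mean is directional
   asymmetry (DA);
5. the indices: FA1 = mean |R - L| and FA4a = 0.798 * sqrt(var(R - L))
   (n - 1 denominator). FA4a is unbiased by DA: adding a constant to every
   signed difference leaves it unchanged, whereas FA1 inflates. When
   |mean(R - L)| does not exceed FA4a, between-sides variation is dominated
   by developmental instability rather than DA.

Counts are exact integers; no measurement-error stratum applies. No
multiple-testing correction is applied across traits or populations; all
raw P values are reported so users can adjust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .landmark_io import (
    CategoricalTraitRecord,
    MeristicRecord,
    TRAIT_VOCABULARIES,
)
from .procrustes_anova import levene_shape_fa

__all__ = [
    "FAIndicesReport",
    "AllometryFit",
    "CategoricalTraitTable",
    "FA4A_COEFFICIENT",
    "grubbs_critical_value",
    "grubbs_screen",
    "fa_indices",
    "levene_counts",
    "allometry_ancova",
    "tabulate_states",
]

#: The half-normal coefficient sqrt(2/pi) rounded as conventionally printed:
#: for d ~ N(0, sigma^2), E|d| = 0.798 * sigma, so FA4a = 0.798 * sd(d) is on
#: the same scale as FA1 = mean|d| under ideal FA.
FA4A_COEFFICIENT = 0.798


@dataclass(frozen=True)
class FAIndicesReport:
    """FA indices and screening-test results for one trait x population."""

    trait: str
    population: str
    n: int
    FA1: float
    FA4a: float
    DA_mean: float
    t_statistic: float
    t_P: float
    shapiro_P: float
    outliers_removed: tuple[str, ...]
    size_dependence_rho: float
    size_dependence_P: float
    da_dominates: bool

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "population": self.population,
            "n": self.n,
            "FA1": self.FA1,
            "FA4a": self.FA4a,
            "mean (R-L)": self.DA_mean,
            "t-test P": self.t_P,
            "shapiro P": self.shapiro_P,
            "size rho": self.size_dependence_rho,
            "size rho P": self.size_dependence_P,
            "DA exceeds FA4a": self.da_dominates,
            "outliers removed": ";".join(self.outliers_removed),
        }


@dataclass(frozen=True)
class AllometryFit:
    """Per-population least-squares fit of mean count against body size."""

    population: str
    trait: str
    slope: float
    intercept: float
    n: int
    interaction_P: float


@dataclass(frozen=True)
class CategoricalTraitTable:
    """Counts and percentages of ordered categorical states per population."""

    trait: str
    states: tuple[str, ...]
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def percentages(self) -> dict[str, dict[str, float]]:
        out = {}
        for pop, cts in self.counts.items():
            total = sum(cts.values())
            out[pop] = {s: 100.0 * cts.get(s, 0) / total for s in self.states}
        return out

    def to_dataframe(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = []
        for pop in self.counts:
            for s in self.states:
                rows.append(
                    {
                        "trait": self.trait,
                        "population": pop,
                        "state": s,
                        "count": self.counts[pop].get(s, 0),
                        "percentage": pct[pop][s],
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# Grubbs outlier screen
# --------------------------------------------------------------------------- #

def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit for sample size n at level alpha.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise DesignError(f"Grubbs test needs n >= 3, got {n}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(
    diffs: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iterated two-sided Grubbs outlier screen.

    At each iteration the single most extreme value (largest standardized
    deviation from the mean) is tested; if its G statistic exceeds the
    critical value at ``alpha`` it is removed and the test repeats on the
    remainder. Returns ``(kept_values, removed_indices)`` with indices into
    the original sequence. A zero-variance sample is kept untouched (the
    G statistic is undefined).
    """
    values = np.asarray(diffs, dtype=float)
    if values.ndim != 1:
        raise ValueError("diffs must be one-dimensional")
    if len(values) < 3:
        raise DesignError(f"Grubbs screen needs n >= 3, got {len(values)}")
    active = list(range(len(values)))
    removed: list[int] = []
    while len(active) >= 3:
        x = values[active]
        sd = x.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(x - x.mean())
        j = int(np.argmax(dev))
        G = dev[j] / sd
        if G > grubbs_critical_value(len(x), alpha):
            removed.append(active.pop(j))
        else:
            break
    return values[active], sorted(removed)


# --------------------------------------------------------------------------- #
# FA indices pipeline
# --------------------------------------------------------------------------- #

def _homogeneous(records: Sequence[MeristicRecord], attr: str) -> str:
    vals = {getattr(r, attr) for r in records}
    if len(vals) != 1:
        raise DesignError(
            f"fa_indices expects records of a single {attr}, got {sorted(vals)}; "
            f"group first"
        )
    return vals.pop()


def fa_indices(records: Sequence[MeristicRecord], alpha: float = 0.05) -> FAIndicesReport:
    """Run the full meristic FA screening pipeline on one trait x population.

    See the module docstring for the fixed step order. ``alpha`` is the
    Grubbs screening level. With zero variance after screening FA4a is 0 and
    the t and Shapiro tests are flagged undefined (NaN).
    """
    if len(records) < 3:
        raise DesignError(f"fa_indices needs at least 3 records, got {len(records)}")
    trait = _homogeneous(records, "trait")
    population = _homogeneous(records, "population")
    signed = np.array([r.signed_diff for r in records], dtype=float)
    kept, removed_idx = grubbs_screen(signed, alpha=alpha)
    removed_ids = tuple(records[i].specimen_id for i in removed_idx)
    kept_records = [r for i, r in enumerate(records) if i not in removed_idx]
    if len(kept_records) < 3:
        raise DesignError("fewer than 3 records remain after outlier screening")
    d = np.array([r.signed_diff for r in kept_records], dtype=float)
    trait_size = np.array([r.mean_count for r in kept_records], dtype=float)

    import warnings

    with warnings.catch_warnings():
        # constant |R-L| legitimately yields an undefined rho (reported NaN)
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, rho_p = stats.spearmanr(np.abs(d), trait_size)
    if d.std(ddof=1) == 0.0:
        shapiro_p = math.nan
        t_stat, t_p = math.nan, math.nan
        fa4a = 0.0
    else:
        shapiro_p = float(stats.shapiro(d).pvalue)
        t_stat, t_p = stats.ttest_1samp(d, 0.0)
        fa4a = FA4A_COEFFICIENT * float(np.sqrt(d.var(ddof=1)))
    fa1 = float(np.abs(d).mean())
    da_mean = float(d.mean())
    return FAIndicesReport(
        trait=trait,
        population=population,
        n=len(d),
        FA1=fa1,
        FA4a=fa4a,
        DA_mean=da_mean,
        t_statistic=float(t_stat),
        t_P=float(t_p),
        shapiro_P=shapiro_p,
        outliers_removed=removed_ids,
        size_dependence_rho=float(rho),
        size_dependence_P=float(rho_p),
        da_dominates=bool(abs(da_mean) > fa4a),
    )


def levene_counts(
    unsigned_by_population: Mapping[str, Sequence[float]],
    center: str = "median",
) -> tuple[float, float]:
    """Levene's test on unsigned |R - L| values across populations.

    Shares the implementation (and the Brown-Forsythe median-centre default)
    with :func:`asymmorph.procrustes_anova.levene_shape_fa`.
    """
    return levene_shape_fa(unsigned_by_population, center=center)


# --------------------------------------------------------------------------- #
# Allometry ANCOVA
# --------------------------------------------------------------------------- #

def allometry_ancova(
    records: Sequence[MeristicRecord], log_transform: bool = False
) -> list[AllometryFit]:
    """Per-population regression of mean count (R+L)/2 on body size, with an
    ANCOVA test of slope homogeneity.

    The homogeneity P value comes from the size x population interaction
    term of the full linear model fitted to all populations jointly; it is
    attached to every returned :class:`AllometryFit`. With
    ``log_transform``, both count and size are log10-transformed before
    fitting (allometric power-law form).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not records:
        raise DesignError("no records")
    trait = _homogeneous(records, "trait")
    df = pd.DataFrame(
        {
            "population": [r.population for r in records],
            "y": [r.mean_count for r in records],
            "x": [r.size for r in records],
        }
    )
    if log_transform:
        if (df["y"] <= 0).any() or (df["x"] <= 0).any():
            raise DesignError("log transform requires strictly positive counts and sizes")
        df["y"] = np.log10(df["y"])
        df["x"] = np.log10(df["x"])
    pops = df["population"].unique().tolist()
    if len(pops) < 2:
        raise DesignError("ANCOVA needs at least 2 populations")
    for pop, grp in df.groupby("population"):
        if len(grp) < 3:
            raise DesignError(f"population {pop!r} has fewer than 3 records")
        if np.ptp(grp["x"].to_numpy()) == 0.0:
            raise DesignError(f"population {pop!r}: size is constant; fit is singular")
    full = smf.ols("y ~ x * C(population)", data=df).fit()
    per_pop = {
        pop: np.polyfit(df.loc[df["population"] == pop, "x"],
                        df.loc[df["population"] == pop, "y"], 1)
        for pop in pops
    }
    if full.ssr <= 1e-12 * max(full.centered_tss, 1e-30):
        # exact fit: the F test is 0/0; decide homogeneity from the slopes
        slopes = [per_pop[pop][0] for pop in pops]
        scale = max(1.0, max(abs(s) for s in slopes))
        interaction_p = 1.0 if np.ptp(slopes) <= 1e-8 * scale else 0.0
    else:
        anova = sm.stats.anova_lm(full, typ=2)
        interaction_p = float(anova.loc["x:C(population)", "PR(>F)"])
    fits = []
    for pop in pops:
        slope, intercept = per_pop[pop]
        grp = df[df["population"] == pop]
        fits.append(
            AllometryFit(
                population=pop,
                trait=trait,
                slope=float(slope),
                intercept=float(intercept),
                n=len(grp),
                interaction_P=interaction_p,
            )
        )
    return fits


# --------------------------------------------------------------------------- #
# Categorical tabulation
# --------------------------------------------------------------------------- #

def tabulate_states(
    records: Sequence[CategoricalTraitRecord],
    vocabulary: Sequence[str] | None = None,
) -> CategoricalTraitTable:
    """Tabulate categorical state counts and percentages per population.

    States are reported in declared vocabulary order (built-in vocabularies
    cover the subanal-fasciole and labral-projection traits; pass
    ``vocabulary`` for other traits). Records must all belong to one trait.
    A state outside the vocabulary is an error.
    """
    if not records:
        raise DesignError("no records to tabulate")
    traits = {r.trait for r in records}
    if len(traits) != 1:
        raise DesignError(f"tabulate_states expects one trait, got {sorted(traits)}")
    trait = traits.pop()
    if vocabulary is None:
        vocabulary = TRAIT_VOCABULARIES.get(trait)
    if vocabulary is None:
        raise DesignError(
            f"no declared vocabulary for trait {trait!r}; pass one explicitly"
        )
    vocab = tuple(vocabulary)
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        if r.state not in vocab:
            raise DesignError(
                f"{r.specimen_id}: state {r.state!r} not in vocabulary {vocab}"
            )
        pop = counts.setdefault(r.population, {})
        pop[r.state] = pop.get(r.state, 0) + 1
    return CategoricalTraitTable(trait=trait, states=vocab, counts=counts)
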