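"""Meristic FA protocol: Grubbs screen, FA1/FA4a indices, Levene on counts,
allometry ANCOVA and categorical tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asymmorph.errors import DesignError
from asymmorph.landmark_io import CategoricalTraitRecord, MeristicRecord
from asymmorph.meristic_fa import (
    allometry_ancova,
    fa_indices,
    grubbs_critical_value,
    grubbs_screen,
    levene_counts,
    tabulate_states,
)
from asymmorph.synthetic_data import MeristicSimParams, simulate_meristic


def records_from_diffs(diffs, population="A", trait="anterior_petals", size=40.0):
    out = []
    for i, d in enumerate(diffs):
        base = 30
        out.append(
            MeristicRecord(
                specimen_id=f"s{i + 1}",
                population=population,
                trait=trait,
                right_count=base + max(d, 0),
                left_count=base - min(d, 0),
                size=size + i,
            )
        )
    return out


class TestGrubbs:
    def test_no_removal_in_tame_sample(self):
        # max G = 2/1.414 = 1.414 < G_crit(6, 0.05) = 1.887
        kept, removed = grubbs_screen([0, 1, -1, 0, 2, -2])
        assert removed == []
        assert len(kept) == 6
        assert grubbs_critical_value(6, 0.05) == pytest.approx(1.887, abs=0.005)

    def test_gross_outlier_removed(self):
        kept, removed = grubbs_screen([0, 0, 0, 0, 0, 50])
        assert removed == [5]
        assert list(kept) == [0, 0, 0, 0, 0]

    def test_constant_sample_kept_entire(self):
        kept, removed = grubbs_screen([3.0, 3.0, 3.0, 3.0])
        assert removed == []
        assert len(kept) == 4

    def test_iterates_until_clean(self):
        # -80 is flagged first, then 30 once the masking extreme is gone
        kept, removed = grubbs_screen([0, 0.2, -0.1, 0.1, 0, -0.2, 30, -80])
        assert removed == [6, 7] or removed == [7, 6] or set(removed) == {6, 7}
        assert len(kept) == 6

    def test_small_sample_rejected(self):
        with pytest.raises(DesignError):
            grubbs_screen([1.0, 2.0])


class TestFAIndices:
    def test_worked_example_0_1_2(self):
        rep = fa_indices(records_from_diffs([0, 1, 2]))
        assert rep.FA1 == pytest.approx(1.0)
        assert rep.FA4a == pytest.approx(0.798)  # sample variance exactly 1
        assert rep.DA_mean == pytest.approx(1.0)
        assert rep.n == 3

    def test_alternating_signs(self):
        rep = fa_indices(records_from_diffs([-1, 1, -1, 1]))
        assert rep.FA1 == pytest.approx(1.0)
        assert rep.DA_mean == pytest.approx(0.0)
        assert rep.t_P == pytest.approx(1.0)
        assert not rep.da_dominates

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        diffs=st.lists(st.integers(min_value=-5, max_value=5), min_size=5, max_size=20),
        shift=st.integers(min_value=1, max_value=4),
    )
    def test_sign_flip_and_da_shift_invariances(self, diffs, shift):
        """FA1/FA4a invariant under global sign flip (DA negates); FA4a is
        additionally invariant under a constant DA shift, FA1 is not."""
        base = fa_indices(records_from_diffs(diffs))
        flipped = fa_indices(records_from_diffs([-d for d in diffs]))
        assert flipped.FA1 == pytest.approx(base.FA1, abs=1e-12)
        assert flipped.FA4a == pytest.approx(base.FA4a, abs=1e-12)
        assert flipped.DA_mean == pytest.approx(-base.DA_mean, abs=1e-12)
        shifted = fa_indices(records_from_diffs([d + shift for d in diffs]))
        assert shifted.FA4a == pytest.approx(base.FA4a, abs=1e-12)

    def test_half_normal_identity(self):
        """For d ~ N(0, sigma^2), both FA1 and FA4a estimate 0.798 sigma."""
        sigma = 2.83
        recs = simulate_meristic(
            MeristicSimParams(
                n=10_000, da_shift=0.0, sigma_fa_count=sigma, rounding=False, seed=13
            )
        )
        rep = fa_indices(recs)
        assert rep.FA4a == pytest.approx(0.798 * sigma, rel=0.03)
        assert 0.98 < rep.FA1 / rep.FA4a < 1.02

    def test_outlier_removal_flows_through(self):
        recs = records_from_diffs([0, 1, -1, 0, 1, -1, 25])
        rep = fa_indices(recs)
        assert rep.outliers_removed == ("s7",)
        assert rep.n == 6
        assert rep.FA1 == pytest.approx(4 / 6)

    def test_zero_variance_flags_tests_undefined(self):
        rep = fa_indices(records_from_diffs([2, 2, 2, 2]))
        assert rep.FA4a == 0.0
        assert np.isnan(rep.t_P) and np.isnan(rep.shapiro_P)
        assert rep.FA1 == pytest.approx(2.0)

    def test_mixed_populations_rejected(self):
        recs = records_from_diffs([0, 1, 2], population="A") + records_from_diffs(
            [0, 1, 2], population="B"
        )
        with pytest.raises(DesignError, match="population"):
            fa_indices(recs)


class TestLeveneCounts:
    def test_identical_groups(self):
        g = [0.0, 1.0, 2.0, 1.0]
        W, P = levene_counts({"A": g, "B": list(g)})
        assert W == pytest.approx(0.0, abs=1e-12) and P == pytest.approx(1.0)

    def test_power_on_contrasting_fa_levels(self):
        """High FA (sigma ~ 2.83) vs low FA (sigma ~ 1.45) at n=36/35:
        Levene on |R-L| rejects in the majority of runs."""
        rejections = 0
        n_reps = 100
        for i in range(n_reps):
            hi = simulate_meristic(
                MeristicSimParams(n=36, sigma_fa_count=2.83, da_shift=1.89,
                                  population="hi", seed=100 + i)
            )
            lo = simulate_meristic(
                MeristicSimParams(n=35, sigma_fa_count=1.45, da_shift=0.57,
                                  population="lo", seed=7000 + i)
            )
            _, P = levene_counts(
                {
                    "hi": [abs(r.signed_diff) for r in hi],
                    "lo": [abs(r.signed_diff) for r in lo],
                }
            )
            rejections += P < 0.05
        assert rejections > n_reps // 2


class TestAllometryANCOVA:
    def _records(self, slopes, noise, rng, n=35):
        # R = L = y so the (R+L)/2 response equals the planted line exactly
        recs = []
        for p, slope in enumerate(slopes):
            sizes = rng.uniform(30, 60, n)
            for i, s in enumerate(sizes):
                y = 5 + slope * s + rng.normal(0, noise)
                recs.append(
                    MeristicRecord(f"p{p}s{i}", f"pop{p}", "anterior_petals",
                                   y, y, s)
                )
        return recs

    def test_exact_common_slope(self):
        rng = np.random.default_rng(0)
        recs = self._records([2.0, 2.0], noise=0.0, rng=rng)
        fits = allometry_ancova(recs)
        for f in fits:
            assert f.slope == pytest.approx(2.0, abs=1e-9)
        assert fits[0].interaction_P > 0.9

    def test_similar_slopes_rarely_significant(self):
        """Slopes 0.93 vs 0.90 under realistic noise at n=35: the
        interaction is non-significant in most runs."""
        non_sig = 0
        n_reps = 60
        for i in range(n_reps):
            rng = np.random.default_rng(300 + i)
            recs = self._records([0.93, 0.90], noise=3.0, rng=rng)
            fits = allometry_ancova(recs)
            non_sig += fits[0].interaction_P > 0.05
        assert non_sig > n_reps * 0.7

    def test_distinct_slopes_detected(self):
        rng = np.random.default_rng(1)
        recs = self._records([1.5, 0.5], noise=0.5, rng=rng)
        fits = allometry_ancova(recs)
        assert fits[0].interaction_P < 0.01
        assert fits[0].slope == pytest.approx(1.5, abs=0.1)
        assert fits[1].slope == pytest.approx(0.5, abs=0.1)

    def test_log_transform_power_law(self):
        rng = np.random.default_rng(2)
        recs = []
        for i, s in enumerate(rng.uniform(30, 60, 20)):
            y = 3.0 * s**0.9
            recs.append(MeristicRecord(f"a{i}", "A", "t", y, y, s))
        for i, s in enumerate(rng.uniform(30, 60, 20)):
            y = 3.0 * s**0.9
            recs.append(MeristicRecord(f"b{i}", "B", "t", y, y, s))
        fits = allometry_ancova(recs, log_transform=True)
        for f in fits:
            assert f.slope == pytest.approx(0.9, abs=1e-6)

    def test_constant_size_rejected(self):
        recs = records_from_diffs([0, 1, 2], population="A")
        recs = [
            MeristicRecord(r.specimen_id, r.population, r.trait,
                           r.right_count, r.left_count, 40.0)
            for r in recs
        ] + records_from_diffs([0, 1, 2], population="B")
        with pytest.raises(DesignError, match="singular|constant"):
            allometry_ancova(recs)


class TestTabulateStates:
    def test_percentages(self):
        recs = [
            CategoricalTraitRecord(f"s{i}", "A", "subanal_fasciole",
                                   "absent" if i < 4 else "parafasciole")
            for i in range(10)
        ]
        table = tabulate_states(recs)
        pct = table.percentages()["A"]
        assert pct["absent"] == pytest.approx(40.0)
        assert pct["parafasciole"] == pytest.approx(60.0)
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_states_in_vocabulary_order(self):
        recs = [CategoricalTraitRecord("s1", "A", "labrum_projection", "exceeding")]
        table = tabulate_states(recs)
        assert table.states == ("open", "covered", "exceeding")
        assert table.percentages()["A"]["exceeding"] == pytest.approx(100.0)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            CategoricalTraitRecord("s1", "A", "labrum_projection", "banana")

    def test_unknown_trait_needs_explicit_vocabulary(self):
        recs = [CategoricalTraitRecord("s1", "A", "spine_density", "high")]
        with pytest.raises(DesignError, match="vocabulary"):
            tabulate_states(recs)
        table = tabulate_states(recs, vocabulary=("low", "high"))
        assert table.percentages()["A"]["high"] == 100.0
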