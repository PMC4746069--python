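"""Object-symmetry machinery: reflection with relabeling, the
symmetric/asymmetric decomposition, and individual FA scores."""

import numpy as np
import pytest

from asymmorph.bilateral_symmetry import (
    decompose_symmetry,
    individual_fa_scores,
    reflect_relabel,
    reflection_operator,
    symmetry_subspace_dims,
)
from asymmorph.errors import SymmetryMapError
from asymmorph.landmark_io import SymmetryMap
from asymmorph.procrustes_core import procrustes_distance
from asymmorph.synthetic_data import LandmarkSimParams, simulate_landmarks


class TestReflectRelabel:
    def test_hand_worked_symmetric_triangle(self):
        smap = SymmetryMap(pairs=((0, 1),), medians=(2,))
        X = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(reflect_relabel(X, smap), X)

    def test_involution_is_exact(self, template):
        T, smap, _ = template
        rng = np.random.default_rng(0)
        X = T + rng.normal(scale=0.1, size=T.shape)
        np.testing.assert_array_equal(reflect_relabel(reflect_relabel(X, smap), smap), X)

    def test_symmetric_config_is_fixed_point_up_to_similarity(self, template):
        T, smap, _ = template
        assert procrustes_distance(reflect_relabel(T, smap), T) < 1e-10

    def test_operator_matrix_matches_function(self, tiny_map, tiny_symmetric_base):
        R = reflection_operator(tiny_map, 5, 2)
        rng = np.random.default_rng(1)
        X = tiny_symmetric_base + rng.normal(size=(5, 2))
        np.testing.assert_allclose(
            (R @ X.reshape(-1)).reshape(5, 2), reflect_relabel(X, tiny_map), atol=1e-12
        )
        # orthogonal involution
        np.testing.assert_allclose(R @ R, np.eye(10), atol=1e-12)


class TestSubspaceDims:
    @pytest.mark.parametrize(
        "k,u,D,expected",
        [
            (9, 3, 2, (19, 19)),
            (9, 3, 3, (29, 27)),
            (2, 1, 2, (3, 3)),
            (2, 1, 3, (4, 4)),
        ],
    )
    def test_formulas(self, k, u, D, expected):
        smap = SymmetryMap(
            pairs=tuple((2 * i, 2 * i + 1) for i in range(k)),
            medians=tuple(range(2 * k, 2 * k + u)),
        )
        assert symmetry_subspace_dims(smap, D) == expected

    def test_empirical_rank_matches_formula(self, template):
        """Covariance rank of each component equals the formula dimension.

        Checked in the linear (small-variation) regime: at larger
        amplitudes the unit-size constraint curves the shape space and a
        second-order radial direction blurs the rank boundary.
        """
        T, smap, _ = template
        sample = simulate_landmarks(
            LandmarkSimParams(
                n_individuals=60, replicates=1, seed=5, sigma_me=0.0,
                sigma_individual=1e-5, sigma_fa=1e-5, da_magnitude=1e-5,
            )
        )
        dec = decompose_symmetry(sample, smap)
        s, a = dec.dims
        N = dec.n_observations
        sym = dec.symmetric.reshape(N, -1)
        asym = dec.asymmetric.reshape(N, -1)
        for comp, expected in ((sym, s), (asym, a)):
            centered = comp - comp.mean(0)
            svals = np.linalg.svd(centered, compute_uv=False)
            rank = int((svals > svals[0] * 1e-3).sum())
            assert rank == expected


class TestDecomposition:
    def test_symmetric_sample_has_zero_asymmetry(self, template):
        T, smap, _ = template
        rng = np.random.default_rng(2)
        configs = []
        for _ in range(5):
            eps = rng.normal(scale=0.03, size=T.shape)
            sym_eps = 0.5 * (eps + reflect_relabel(eps, smap))
            configs.append(T + sym_eps)
        dec = decompose_symmetry(configs, smap)
        assert np.abs(dec.asymmetric).max() < 1e-9

    def test_components_reconstruct_aligned_original(self, small_sample):
        sample, smap = small_sample
        dec = decompose_symmetry(sample, smap)
        np.testing.assert_allclose(
            dec.symmetric + dec.asymmetric,
            dec.aligned.procrustes_coords,
            atol=1e-9,
        )

    def test_consensus_is_perfectly_symmetric(self, small_sample):
        sample, smap = small_sample
        dec = decompose_symmetry(sample, smap)
        np.testing.assert_allclose(
            dec.consensus, reflect_relabel(dec.consensus, smap), atol=1e-9
        )

    def test_orthogonal_energy_split(self, small_sample):
        sample, smap = small_sample
        dec = decompose_symmetry(sample, smap)
        total = (dec.aligned.procrustes_coords**2).sum()
        split = (dec.symmetric**2).sum() + (dec.asymmetric**2).sum()
        assert split == pytest.approx(total, rel=1e-8)

    def test_components_transform_correctly_under_reflection(self, small_sample):
        """Symmetric parts are reflection-invariant; asymmetric parts negate."""
        sample, smap = small_sample
        dec = decompose_symmetry(sample, smap)
        for i in range(dec.n_observations):
            np.testing.assert_allclose(
                reflect_relabel(dec.symmetric[i], smap), dec.symmetric[i], atol=1e-9
            )
            np.testing.assert_allclose(
                reflect_relabel(dec.asymmetric[i], smap), -dec.asymmetric[i], atol=1e-9
            )

    def test_single_landmark_perturbation_splits_in_half(self, template):
        """base + eps on one paired landmark: asymmetric magnitude ~ eps/2."""
        T, smap, _ = template
        eps = 0.01
        configs = [T.copy() for _ in range(4)]
        bumped = T.copy()
        left, right = smap.pairs[3]
        bumped[left, 1] += eps
        configs.append(bumped)
        dec = decompose_symmetry(configs, smap)
        # the antisymmetric half of a one-sided bump displaces each member
        # of the pair by eps/2 (total Procrustes norm eps/sqrt(2))
        for lm in (left, right):
            assert np.linalg.norm(dec.asymmetric[-1][lm]) == pytest.approx(
                eps / 2, rel=0.05
            )
        pair_energy = (dec.asymmetric[-1][[left, right]] ** 2).sum()
        assert pair_energy / (dec.asymmetric[-1] ** 2).sum() > 0.8

    def test_injected_da_appears_in_mean_asymmetric_component(self, template):
        from asymmorph.synthetic_data import directional_asymmetry_field

        T, smap, _ = template
        params = LandmarkSimParams(
            n_individuals=150, replicates=1, sigma_individual=0.01,
            sigma_fa=0.005, sigma_me=0.0, da_magnitude=0.03, seed=9,
        )
        da = directional_asymmetry_field(params)
        dec = decompose_symmetry(simulate_landmarks(params), smap)
        _, _, asym = dec.specimen_means()
        mean_asym = asym.mean(0)
        # Monte-Carlo error ~ sigma_fa * sqrt(a/n) ~ 0.0018
        assert np.linalg.norm(mean_asym - da) < 3 * 0.005 * np.sqrt(19 / 150)

    def test_degenerate_map_without_pairs_rejected(self, template):
        T, smap, _ = template
        empty = SymmetryMap(pairs=(), medians=smap.medians)
        with pytest.raises(SymmetryMapError):
            decompose_symmetry([T, T + 0.01], empty)


class TestIndividualFAScores:
    def test_symmetric_sample_scores_zero(self, template):
        T, smap, _ = template
        sample = simulate_landmarks(
            LandmarkSimParams(
                n_individuals=5, replicates=2, sigma_fa=0.0, sigma_me=0.0,
                da_magnitude=0.0, seed=3,
            )
        )
        dec = decompose_symmetry(sample, smap)
        scores = individual_fa_scores(dec)
        assert (scores < 1e-9).all()

    def test_pure_da_scores_zero_after_correction(self, template):
        T, smap, _ = template
        sample = simulate_landmarks(
            LandmarkSimParams(
                n_individuals=6, replicates=2, sigma_individual=0.0,
                sigma_fa=0.0, sigma_me=0.0, da_magnitude=0.05, seed=4,
            )
        )
        dec = decompose_symmetry(sample, smap)
        corrected = individual_fa_scores(dec, correct_da=True)
        uncorrected = individual_fa_scores(dec, correct_da=False)
        assert (corrected < 1e-6).all()
        assert (uncorrected > 0.04).all()

    def test_scores_grow_with_fa_magnitude(self, template):
        T, smap, _ = template
        means = []
        for mult in (0.5, 1.0, 2.0):
            sample = simulate_landmarks(
                LandmarkSimParams(
                    n_individuals=40, replicates=2, sigma_fa=0.01 * mult, seed=12
                )
            )
            dec = decompose_symmetry(sample, smap)
            means.append(individual_fa_scores(dec).mean())
        assert means[0] < means[1] < means[2]
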