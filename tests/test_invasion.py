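"""Invasion fitness, selection gradients, ESS search, PIP, landscapes."""

import numpy as np
import pytest

from phenoparasite import (
    ModelParameters,
    PhenologyTraits,
    SeasonBoundaryState,
    density_landscape,
    disease_free_equilibrium,
    find_ess,
    invasion_fitness,
    pairwise_invasibility,
    selection_gradient,
)

NO_PARASITES = SeasonBoundaryState(s_hat=1e4, v_hat=0.0)


class TestInvasionFitness:
    def test_neutrality_on_trait_grid(self, params_tau3):
        """A resident tested against itself at its own attractor has
        fitness exactly 1 (within 1e-4): the strongest single correctness
        check of the whole pipeline, exercising the DDE solver, the season
        maps, the equilibrium and the fitness definition together."""
        for t0, tl in [(0.0, 0.5), (0.5, 0.5), (1.5, 2.0), (0.0, 2.88)]:
            traits = PhenologyTraits(t0=t0, tl=tl)
            result = invasion_fitness(traits, traits, params_tau3)
            assert result.fitness == pytest.approx(1.0, abs=1e-4)

    def test_disease_free_later_start_cannot_invade(self, params_tau3,
                                                    base_traits):
        """Without parasites, fitness is monotone in the maturation
        probability, so any later-emerging mutant loses."""
        result = invasion_fitness(
            PhenologyTraits(t0=0.5, tl=0.5), base_traits, params_tau3,
            initial=NO_PARASITES)
        assert result.fitness < 1.0
        assert result.invades is False

    def test_parasites_reward_late_emergence(self, params_tau3, base_traits):
        """With abundant early-season parasites, a mutant emerging near the
        persistence boundary escapes infection and invades."""
        result = invasion_fitness(
            PhenologyTraits(t0=0.91, tl=0.5), base_traits, params_tau3)
        assert result.fitness > 1.0


class TestSelectionGradient:
    def test_disease_free_gradient_points_early(self, params_tau3):
        grad = selection_gradient(
            "t0", PhenologyTraits(t0=0.5, tl=0.5), params_tau3,
            initial=NO_PARASITES, n_seasons=80)
        assert grad < 0
        grad_tl = selection_gradient(
            "tl", PhenologyTraits(t0=0.0, tl=1.0), params_tau3,
            initial=NO_PARASITES, n_seasons=80)
        assert grad_tl < 0

    def test_parasites_reverse_the_gradient(self, params_tau15):
        """Short-latency parasites at high density select for delayed
        emergence at the early-phenology resident."""
        grad = selection_gradient(
            "t0", PhenologyTraits(t0=0.0, tl=0.5), params_tau15)
        assert grad > 0

    def test_one_sided_at_bound(self, params_tau3):
        """At the t0 = 0 bound only the forward probe is feasible.  The
        disease-free gradient there is slightly positive: survival to the
        season end peaks for hosts emerging near t = 0.3 (less adult-phase
        mortality), so the disease-free optimum sits just inside the
        bound."""
        grad = selection_gradient(
            "t0", PhenologyTraits(t0=0.0, tl=0.5), params_tau3,
            initial=NO_PARASITES, n_seasons=80)
        assert np.isfinite(grad) and 0 < grad < 0.01

    def test_invalid_probe(self, params_tau3):
        with pytest.raises(ValueError):
            selection_gradient("t0", PhenologyTraits(t0=0.0, tl=0.5),
                               params_tau3, h=-0.01)


class TestEssSearch:
    def test_no_parasites_drives_t0_toward_lower_bound(self, params_tau3):
        """Without parasites, selection pushes emergence to the season
        start.  The endpoint is not exactly 0: adult background mortality
        makes emerging in the very first instant marginally worse than a
        slightly later start (survival-to-season-end peaks at emergence
        time ~0.3), leaving the optimum within a few steps of the bound."""
        result = find_ess("t0", 0.3, params_tau3, initial=NO_PARASITES,
                          n_seasons=80)
        assert result.converged
        assert result.value <= 0.05

    def test_no_parasites_drives_tl_to_minimum(self, params_tau3):
        result = find_ess("tl", 0.9, params_tau3, initial=NO_PARASITES,
                          n_seasons=80)
        assert result.converged
        assert result.value == pytest.approx(0.5, abs=1e-9)

    def test_start_invariance_disease_free(self, params_tau3):
        values = [
            find_ess("t0", start, params_tau3, initial=NO_PARASITES,
                     n_seasons=80, step=0.05).value
            for start in (0.1, 0.35)
        ]
        assert values[0] == pytest.approx(values[1], abs=0.05)

    def test_input_validation(self, params_tau3):
        with pytest.raises(ValueError):
            find_ess("t0", -1.0, params_tau3)
        with pytest.raises(ValueError):
            find_ess("size", 0.5, params_tau3)
        with pytest.raises(ValueError):
            find_ess("t0", 0.5, params_tau3, step=0.0)


class TestPairwiseInvasibility:
    def test_diagonal_neutrality_and_disease_free_structure(self,
                                                            params_tau3):
        """On a disease-free PIP in t0, earlier always invades: fitness > 1
        strictly below the diagonal, < 1 above, = 1 on it."""
        grid = np.linspace(0.0, 1.2, 5)
        pip = pairwise_invasibility("t0", grid, params_tau3,
                                    initial=NO_PARASITES, n_seasons=80)
        fitness = pip.fitness
        assert np.allclose(np.diag(fitness), 1.0, atol=1e-4)
        lower = fitness[np.tril_indices_from(fitness, k=-1)]
        upper = fitness[np.triu_indices_from(fitness, k=1)]
        assert np.all(lower > 1.0)
        assert np.all(upper < 1.0)
        signs = pip.sign_matrix()
        assert np.all(signs[np.tril_indices_from(signs, k=-1)] == 1)

    def test_sign_change_brackets_the_optimum(self, params_tau3):
        """With long-latency parasites the mutant fitness along the
        early-emergence resident column changes sign near the persistence
        boundary (about t0 = 0.9)."""
        grid = np.array([0.0, 0.45, 0.93, 1.4])
        pip = pairwise_invasibility("t0", grid, params_tau3, n_seasons=150)
        # against the earliest resident, the near-boundary mutant invades
        assert pip.fitness[0, 2] > 1.0
        # against a resident past the boundary, everything trends back early
        assert pip.fitness[3, 2] > 1.0 and pip.fitness[3, 3] == pytest.approx(
            1.0, abs=1e-4)

    def test_grid_validation(self, params_tau3):
        with pytest.raises(ValueError):
            pairwise_invasibility("t0", np.array([0.5, 0.2]), params_tau3)
        with pytest.raises(ValueError):
            pairwise_invasibility("tl", np.array([0.1, 0.6]), params_tau3)


class TestDensityLandscape:
    def test_disease_free_grid_matches_closed_form(self, params_tau3):
        t0s = np.linspace(0.0, 2.0, 3)
        tls = np.linspace(0.5, 2.5, 3)
        grid = density_landscape(t0s, tls, params_tau3, n_seasons=60,
                                 with_parasites=False)
        assert not grid.failures
        for i, t0 in enumerate(t0s):
            for j, tl in enumerate(tls):
                expected = disease_free_equilibrium(
                    PhenologyTraits(t0=t0, tl=tl), params_tau3)
                assert grid.s_star[i, j] == pytest.approx(expected, rel=1e-4)
        # the corner (earliest, shortest) is the disease-free maximum
        assert grid.s_star[0, 0] == grid.s_star.max()

    def test_parasites_depress_density(self, params_tau3):
        t0s = np.array([0.0, 0.5])
        tls = np.array([0.5, 1.5])
        with_p = density_landscape(t0s, tls, params_tau3, n_seasons=60)
        without = density_landscape(t0s, tls, params_tau3, n_seasons=60,
                                    with_parasites=False)
        assert np.all(with_p.s_star <= without.s_star * (1 + 1e-9))
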