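import numpy as np
import pytest

import evosize as ez
from evosize.rates import (
    allocation_psi,
    compute_rates,
    encounter_rate,
    feeding_kernel,
    feeding_level,
    growth_rate,
    other_mortalities,
    predation_mortality,
)
from .conftest import fine_trapezoid


class TestFeedingKernel:
    def test_peak_at_preferred_ratio(self, phys):
        assert feeding_kernel(phys.beta * 2.0, 2.0, phys.beta, phys.sigma) == pytest.approx(1.0)
        # with beta = 100, a 100 g predator prefers 1 g prey
        assert feeding_kernel(100.0, 1.0, 100.0, 1.0) == pytest.approx(1.0)

    def test_one_sigma_from_peak(self, phys):
        # ln(m/(beta*mp)) = sigma -> phi = e^(-1/2)
        mp = 1.0
        m = phys.beta * mp * np.exp(phys.sigma)
        assert feeding_kernel(m, mp, phys.beta, phys.sigma) == pytest.approx(np.exp(-0.5))

    def test_symmetric_in_log_ratio(self, phys):
        mp = 1.0
        up = feeding_kernel(phys.beta * np.e, mp, phys.beta, phys.sigma)
        down = feeding_kernel(phys.beta / np.e, mp, phys.beta, phys.sigma)
        assert up == pytest.approx(down)

    def test_rejects_nonpositive_mass(self, phys):
        with pytest.raises(ValueError):
            feeding_kernel(0.0, 1.0, phys.beta, phys.sigma)


class TestFeedingLevel:
    def test_half_saturation(self, phys):
        m = 10.0
        E = phys.h * m**phys.n
        assert feeding_level(E, m, phys.h, phys.n) == pytest.approx(0.5)

    def test_zero_and_three_quarters(self, phys):
        m = 3.0
        assert feeding_level(0.0, m, phys.h, phys.n) == 0.0
        assert feeding_level(3 * phys.h * m**phys.n, m, phys.h, phys.n) == pytest.approx(0.75)

    def test_negative_encounter_rejected(self, phys):
        with pytest.raises(ValueError):
            feeding_level(-1.0, 1.0, phys.h, phys.n)


class TestAllocation:
    def test_vanishes_at_small_size(self, phys):
        psi = allocation_psi(1e-6, 2.5, 10.0, phys.u, phys.n)
        assert psi < 1e-10

    def test_value_at_maturation(self, phys):
        # psi(m*) = 0.5 * eta^(1-n); the logistic term is exactly 1/2 at m*
        eta = 0.25
        M = 100.0
        psi = allocation_psi(eta * M, eta * M, M, phys.u, phys.n)
        assert psi == pytest.approx(0.5 * eta ** (1 - phys.n), rel=1e-12)
        assert psi == pytest.approx(0.35355, rel=1e-4)

    def test_value_at_asymptotic_size(self, phys):
        psi = allocation_psi(100.0, 25.0, 100.0, 7.0, phys.n)
        assert psi == pytest.approx(1.0 / (1.0 + 0.25**7), rel=1e-12)

    def test_maturation_above_asymptotic_rejected(self, phys):
        with pytest.raises(ValueError):
            allocation_psi(1.0, 200.0, 100.0, phys.u, phys.n)


class TestGrowth:
    def test_zero_at_critical_feeding_level(self, phys):
        fc = phys.critical_feeding_level
        assert fc == pytest.approx(4.0 / (0.6 * 85.0))
        assert growth_rate(fc, 5.0, 0.0, phys) == pytest.approx(0.0, abs=1e-12)

    def test_max_growth_at_one_gram(self, phys):
        assert growth_rate(1.0, 1.0, 0.0, phys) == pytest.approx(0.6 * 85 - 4)

    def test_full_allocation_stops_growth(self, phys):
        assert growth_rate(1.0, 10.0, 1.0, phys) == 0.0

    def test_deficit_is_floored_not_negative(self, phys):
        assert growth_rate(0.0, 10.0, 0.0, phys) == 0.0


class TestOtherMortalities:
    def test_background_scaling(self, phys):
        m = np.array([10.0])
        _, _, mu_b, _ = other_mortalities(m, 2.5, 1e5, phys)
        assert mu_b == pytest.approx(2 * 10 ** (-1.25), rel=1e-12)
        assert mu_b == pytest.approx(0.11246, rel=1e-4)

    def test_knife_edge_fishing(self, phys):
        M = 1000.0
        m = np.array([100.0, 249.9, 250.0, 900.0])
        _, _, _, mu_f = other_mortalities(m, 250.0, M, phys, F=0.8)
        assert mu_f == pytest.approx([0.0, 0.0, 0.8, 0.8])

    def test_no_starvation_at_critical_feeding(self, phys):
        m = np.array([10.0])
        _, mu_st, _, _ = other_mortalities(m, 2.5, 10.0, phys, deficit=0.0)
        assert mu_st[0] == 0.0

    def test_starvation_from_deficit(self, phys):
        m = np.array([10.0])
        _, mu_st, _, _ = other_mortalities(m, 2.5, 10.0, phys, deficit=2.0)
        assert mu_st[0] == pytest.approx(2.0 / (phys.xi * 10.0))

    def test_senescence_only_after_maturation(self, phys):
        m = np.array([1.0, 2.5, 5.0, 10.0])
        mu_se, _, _, _ = other_mortalities(m, 2.5, 10.0, phys)
        assert mu_se[0] == 0.0 and mu_se[1] == 0.0
        assert 0 < mu_se[2] < mu_se[3] <= phys.se_max


def _resource_only_state(cfg, grid=None):
    grid = grid or cfg.build_grid()
    state = ez.init_community(cfg.species, grid, cfg.resource)
    state.densities[:] = 0.0
    return state


class TestEncounter:
    def test_zero_without_food(self, phys, paper9_cfg):
        state = _resource_only_state(paper9_cfg)
        state.resource.density[:] = 0.0
        E = encounter_rate(state, np.zeros((9, 9)), phys)
        assert np.all(E == 0.0)

    def test_linear_in_gamma(self, paper9_cfg):
        from dataclasses import replace

        state = _resource_only_state(paper9_cfg)
        theta = paper9_cfg.interaction()
        p1 = ez.PhysiologyParams()
        p2 = replace(p1, gamma=2 * p1.gamma)
        E1 = encounter_rate(state, theta, p1)
        E2 = encounter_rate(state, theta, p2)
        assert np.allclose(E2, 2 * E1)

    def test_against_fine_grid_oracle(self, phys, paper9_cfg):
        # resource at carrying capacity, no fish: compare with brute-force
        # quadrature at 10x resolution
        state = _resource_only_state(paper9_cfg)
        theta = np.zeros((9, 9))
        E = encounter_rate(state, theta, phys)
        res = paper9_cfg.resource
        mp = np.logspace(-10, 0, 1300)
        w = fine_trapezoid(mp)
        for mt in (0.01, 1.0, 50.0):
            i = np.argmin(np.abs(state.grid.fish_masses - mt))
            m = state.grid.fish_masses[i]
            integral = np.sum(
                res.carrying_capacity(mp)
                * feeding_kernel(m, mp, phys.beta, phys.sigma)
                * mp
                * w
            )
            oracle = phys.gamma * m**phys.q * integral
            assert abs(E[0, i] / oracle - 1) < 0.005

    def test_emergent_feeding_level_on_pristine_resource(self, phys, paper9_cfg):
        # the search-volume calibration implies f = f0 = 0.5 for fish feeding
        # on an ungrazed resource spectrum
        state = _resource_only_state(paper9_cfg)
        E = encounter_rate(state, np.zeros((9, 9)), phys)
        small = state.grid.fish_masses < 1e-3 * phys.beta  # kernel inside resource range
        f = feeding_level(E[0], state.grid.fish_masses, phys.h, phys.n)
        assert np.allclose(f[small], 0.5, atol=0.01)


class TestPredationMortality:
    def test_zero_interaction_spares_fish_but_not_resource(self, phys, paper9_cfg):
        grid = paper9_cfg.build_grid()
        state = ez.init_community(paper9_cfg.species, grid, paper9_cfg.resource)
        theta = np.zeros((9, 9))
        f = np.zeros((9, grid.n_fish))
        mu_fish, mu_res = predation_mortality(state, theta, phys, f)
        assert np.all(mu_fish == 0.0)
        assert mu_res.max() > 0.0  # fish always graze the resource

    def test_satiated_predators_kill_nothing(self, phys, paper9_cfg):
        grid = paper9_cfg.build_grid()
        state = ez.init_community(paper9_cfg.species, grid, paper9_cfg.resource)
        theta = paper9_cfg.interaction()
        f = np.ones((9, grid.n_fish))
        mu_fish, mu_res = predation_mortality(state, theta, phys, f)
        assert np.all(mu_fish == 0.0) and np.all(mu_res == 0.0)

    def test_against_fine_grid_oracle(self, phys, paper9_cfg):
        # one predator species with a narrow (delta-like) density spike;
        # prey mortality must match brute-force quadrature within 0.5%
        grid = paper9_cfg.build_grid()
        state = ez.init_community(paper9_cfg.species, grid, paper9_cfg.resource)
        state.densities[:] = 0.0
        spike = np.argmin(np.abs(grid.fish_masses - 500.0))
        state.densities[8, spike] = 1.0
        theta = paper9_cfg.interaction()
        f = np.full((9, grid.n_fish), 0.4)
        mu_fish, _ = predation_mortality(state, theta, phys, f, None)
        m_pred = grid.fish_masses[spike]
        dw = grid.fish_bin_widths[spike]
        for mp_t in (1.0, 5.0, 20.0):
            k = np.argmin(np.abs(grid.fish_masses - mp_t))
            mp = grid.fish_masses[k]
            oracle = (
                feeding_kernel(m_pred, mp, phys.beta, phys.sigma)
                * (1 - 0.4)
                * phys.gamma
                * m_pred**phys.q
                * 0.5
                * 1.0
                * dw
            )
            assert mu_fish[0, k] == pytest.approx(oracle, rel=5e-3)


class TestRateBundleInvariants:
    def test_bounds_on_default_community(self, paper9_cfg):
        grid = paper9_cfg.build_grid()
        state = ez.init_community(paper9_cfg.species, grid, paper9_cfg.resource)
        rb = compute_rates(state, paper9_cfg.interaction(), paper9_cfg.phys, F=0.8)
        assert np.all((rb.feeding >= 0) & (rb.feeding < 1))
        assert np.all((rb.psi >= 0) & (rb.psi <= 1))
        assert np.all(rb.growth >= 0)
        for mu in (rb.mu_predation, rb.mu_senescence, rb.mu_starvation,
                   rb.mu_fishing, rb.mu_total, rb.mu_resource_predation):
            assert np.all(mu >= 0)
        assert np.all(rb.mu_background > 0)
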