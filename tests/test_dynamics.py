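import numpy as np
import pytest

import evosize as ez
from evosize.dynamics import pooled_recruitment, resource_step, spawn_output, upwind_step
from evosize.state import ResourceState, initial_abundance
from .conftest import fine_trapezoid


class TestInitialAbundance:
    def test_printed_formula_value(self, grid):
        sp = ez.SpeciesParams(species_id=1, M=10.0, Rmax=0.49208)
        N = initial_abundance(sp, grid, kappa=0.05)
        i = np.argmin(np.abs(grid.fish_masses - 1.0))
        m = grid.fish_masses[i]
        expected = 5e-5 * 10 ** (-0.95) * m ** (-1.1)
        assert N[i] == pytest.approx(expected, rel=1e-12)
        assert N[i] == pytest.approx(5.61e-6 * m ** (-1.1), rel=1e-3)

    def test_mass_dependence_exponent(self, grid):
        sp = ez.SpeciesParams(species_id=1, M=100.0, Rmax=1.0)
        N = initial_abundance(sp, grid, kappa=0.05)
        m = grid.fish_masses
        sel = m <= 100.0
        ratio = N[sel][10] / N[sel][5]
        assert ratio == pytest.approx((m[10] / m[5]) ** (-1.1), rel=1e-12)

    def test_zero_kappa_and_truncation_above_M(self, grid):
        sp = ez.SpeciesParams(species_id=1, M=10.0, Rmax=1.0)
        assert np.all(initial_abundance(sp, grid, kappa=0.0) == 0.0)
        N = initial_abundance(sp, grid, kappa=0.05)
        assert np.all(N[grid.fish_masses > 10.0] == 0.0)


class TestResourceStep:
    def test_carrying_capacity_is_fixed_point(self, grid):
        pr = ez.ResourceParams()
        cc = pr.carrying_capacity(grid.resource_masses)
        res = ResourceState(density=cc.copy(), params=pr)
        out = resource_step(res, grid.resource_masses, np.zeros(grid.n_resource), dt=0.7)
        assert np.allclose(out.density, cc, rtol=1e-12)

    def test_closed_form_regrowth_from_zero(self, grid):
        pr = ez.ResourceParams()
        m = grid.resource_masses
        res = ResourceState(density=np.zeros_like(m), params=pr)
        t = 0.0
        for _ in range(10):
            res = resource_step(res, m, np.zeros_like(m), dt=0.3)
            t += 0.3
        r = pr.r0 * m ** (0.75 - 1.0)
        expected = pr.carrying_capacity(m) * (1.0 - np.exp(-r * t))
        assert np.allclose(res.density, expected, rtol=1e-6)

    def test_steady_state_under_constant_grazing(self, grid):
        pr = ez.ResourceParams()
        m = grid.resource_masses
        mu = np.full_like(m, 2.5)
        res = ResourceState(density=pr.carrying_capacity(m), params=pr)
        for _ in range(400):
            res = resource_step(res, m, mu, dt=1.0)
        r = pr.r0 * m ** (-0.25)
        expected = r * pr.carrying_capacity(m) / (r + 2.5)
        assert np.allclose(res.density, expected, rtol=1e-6)

    def test_rejects_negative_dt(self, grid):
        pr = ez.ResourceParams()
        res = ResourceState(density=pr.carrying_capacity(grid.resource_masses), params=pr)
        with pytest.raises(ValueError):
            resource_step(res, grid.resource_masses, np.zeros(grid.n_resource), dt=-0.1)


class TestSpawnOutput:
    def test_zero_for_immature_and_starving(self, grid, phys):
        P, nw = 2, grid.n_fish
        dens = np.ones((P, nw))
        e_pos = np.ones((P, nw))
        psi = np.zeros((P, nw))
        out = spawn_output(dens, e_pos, psi, grid.fish_bin_widths, phys, grid.egg_mass)
        assert np.all(out == 0.0)
        out2 = spawn_output(dens, np.zeros((P, nw)), np.ones((P, nw)),
                            grid.fish_bin_widths, phys, grid.egg_mass)
        assert np.all(out2 == 0.0)

    def test_smooth_spectrum_against_fine_oracle(self, grid, phys):
        # smooth log-normal bump spectrum with the analytic integrand,
        # compared with 10x-resolution brute-force quadrature
        def density(m):
            # equilibrium-like spectrum slope (the class of spectra the
            # model actually produces)
            return m**-1.1

        def integrand(m):
            e = 0.5 * phys.alpha * phys.h * m**phys.n
            p = np.clip((m / 1000.0) ** 0.25, 0, 1)
            return density(m) * e * p

        m = grid.fish_masses
        e_pos = 0.5 * phys.alpha * phys.h * m**phys.n
        psi = np.clip((m / 1000.0) ** 0.25, 0, 1)
        out = spawn_output(density(m)[None, :], e_pos[None, :], psi[None, :],
                           grid.fish_bin_widths, phys, grid.egg_mass)
        mf = np.logspace(np.log10(m[0]), np.log10(m[-1]), 1000)
        w = fine_trapezoid(mf)
        oracle = phys.eps / (2 * grid.egg_mass) * np.sum(integrand(mf) * w)
        assert out[0] == pytest.approx(oracle, rel=5e-3)


class TestPooledRecruitment:
    def test_beverton_holt_midpoint(self):
        R = pooled_recruitment(np.array([1.0]), np.array([0]), np.array([1.0]))
        assert R[0] == pytest.approx(0.5)

    def test_saturation_at_rmax(self):
        R = pooled_recruitment(np.array([1e9]), np.array([0]), np.array([2.0]))
        assert R[0] == pytest.approx(2.0, rel=1e-6)

    def test_proportional_split_across_phenotypes(self):
        # two phenotypes with spawn outputs 3 and 1, total equal to Rmax = 4
        R = pooled_recruitment(np.array([3.0, 1.0]), np.array([0, 0]), np.array([4.0]))
        assert R == pytest.approx([0.375 * 4, 0.125 * 4])
        assert R.sum() == pytest.approx(2.0)  # Rmax/2 at the midpoint

    def test_zero_spawn_is_not_an_error(self):
        R = pooled_recruitment(np.array([0.0, 0.0]), np.array([0, 0]), np.array([1.0]))
        assert np.all(R == 0.0)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        Rp = rng.uniform(0, 5, size=6)
        sp = np.array([0, 0, 1, 1, 2, 2])
        Rmax = np.array([1.0, 2.0, 3.0])
        R = pooled_recruitment(Rp, sp, Rmax)
        for s in range(3):
            tot = R[sp == s].sum()
            assert tot <= Rmax[s] + 1e-12
            assert tot <= Rp[sp == s].sum() + 1e-12

    def test_rejects_nonpositive_rmax(self):
        with pytest.raises(ValueError):
            pooled_recruitment(np.array([1.0]), np.array([0]), np.array([0.0]))


class TestUpwindStep:
    def test_pure_mortality_decays_exponentially(self, grid):
        c, dt, steps = 0.7, 0.01, 200
        N = np.ones((1, grid.n_fish))
        g = np.zeros_like(N)
        mu = np.full_like(N, c)
        for _ in range(steps):
            upwind_step(N, g, mu, np.zeros(1), grid.fish_bin_widths, dt)
        expected = np.exp(-c * dt * steps)
        assert np.allclose(N, expected, rtol=5e-3)

    def test_conservation_without_mortality_or_growth(self, grid):
        N = np.random.default_rng(1).uniform(size=(1, grid.n_fish))
        total0 = N[0] @ grid.fish_bin_widths
        upwind_step(N, np.zeros_like(N), np.zeros_like(N), np.zeros(1),
                    grid.fish_bin_widths, 0.1)
        assert N[0] @ grid.fish_bin_widths == pytest.approx(total0, rel=1e-12)

    def test_transport_loses_mass_only_through_top(self, grid):
        # positive growth, no mortality: total individuals non-increasing
        N = np.ones((1, grid.n_fish))
        g = np.full_like(N, 5.0)
        total0 = N[0] @ grid.fish_bin_widths
        for _ in range(50):
            upwind_step(N, g, np.zeros_like(N), np.zeros(1), grid.fish_bin_widths, 0.1)
        assert N[0] @ grid.fish_bin_widths <= total0 + 1e-9
        assert np.all(N >= 0)


class TestStepCommunity:
    def test_split_phenotype_matches_merged(self, paper9_cfg):
        # linearity: two identical-trait phenotypes holding half the density
        # each must evolve exactly like the single merged phenotype
        cfg = paper9_cfg
        grid = cfg.build_grid()
        merged = ez.init_community(cfg.species, grid, cfg.resource)
        split = merged.copy()
        split.densities = np.vstack([split.densities, 0.5 * split.densities[0:1]])
        split.densities[0] *= 0.5
        split.species_idx = np.append(split.species_idx, 0)
        split.eta = np.append(split.eta, split.eta[0])
        split.phenotype_id = np.append(split.phenotype_id, 99)
        split.parent_id = np.append(split.parent_id, 0)
        split.birth_time = np.append(split.birth_time, 0.0)
        theta = cfg.interaction()
        for _ in range(5):
            ez.step_community(merged, theta, cfg.phys, F=0.0, dt=0.1)
            ez.step_community(split, theta, cfg.phys, F=0.0, dt=0.1)
        combined = split.densities[0] + split.densities[-1]
        assert np.allclose(combined, merged.densities[0], rtol=1e-10)

    def test_densities_stay_nonnegative_and_time_advances(self, toy3_cfg):
        cfg = toy3_cfg
        state = ez.init_community(cfg.species, cfg.build_grid(), cfg.resource)
        theta = cfg.interaction()
        for _ in range(20):
            ez.step_community(state, theta, cfg.phys, F=0.8, dt=0.1)
        assert np.all(state.densities >= 0)
        assert state.time == pytest.approx(2.0)

    def test_nonfinite_density_aborts(self, toy3_cfg):
        cfg = toy3_cfg
        state = ez.init_community(cfg.species, cfg.build_grid(), cfg.resource)
        state.densities[0, 0] = np.inf
        with pytest.raises(RuntimeError, match="blow-up"):
            ez.step_community(state, cfg.interaction(), cfg.phys, F=0.0, dt=0.1)

    def test_species_symmetry(self):
        # two species with identical parameters, theta = 0, no fishing:
        # identical trajectories
        species = [
            ez.SpeciesParams(species_id=1, M=100.0, eta0=0.25, Rmax=0.08),
            ez.SpeciesParams(species_id=2, M=100.0, eta0=0.25, Rmax=0.08),
        ]
        cfg = ez.ModelConfig(species=species, theta=0.0)
        state = ez.init_community(cfg.species, cfg.build_grid(), cfg.resource)
        theta = cfg.interaction()
        for _ in range(50):
            ez.step_community(state, theta, cfg.phys, F=0.0, dt=0.1)
        assert np.allclose(state.densities[0], state.densities[1], rtol=1e-12)
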