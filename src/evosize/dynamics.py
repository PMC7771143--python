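"""Time stepping of the coupled phenotype/resource dynamics.

Each phenotype's abundance density obeys the conservation (transport)
equation dN/dt + d(gN)/dm = -mu N, discretised with a first-order
semi-implicit upwind scheme (unconditionally positive).  Recruitment enters
as a flux boundary condition at the egg bin.  The background resource follows
semi-chemostat regeneration and is advanced with the exact per-bin
exponential solution given the current predation field.
"""

from __future__ import annotations

import numpy as np

from .params import PhysiologyParams
from .rates import KernelTables, RateBundle, compute_rates
from .state import CommunityState, ResourceState

__all__ = [
    "resource_step",
    "spawn_output",
    "pooled_recruitment",
    "upwind_step",
    "step_community",
]


def resource_step(
    resource: ResourceState,
    masses: np.ndarray,
    mu_resource_predation: np.ndarray,
    dt: float,
    p: float = 0.75,
) -> ResourceState:
    """Advance the semi-chemostat resource one step with the exact solution.

    dN_R/dt = r0 m^(p-1) [kappa m^-lambda - N_R] - mu_p N_R has, for constant
    mu_p over the step, the solution
    N_R(t+dt) = N_eq + (N_R - N_eq) exp(-(r + mu_p) dt) with r = r0 m^(p-1)
    and N_eq = r cc / (r + mu_p).  Positivity is automatic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pr = resource.params
    m = np.asarray(masses, dtype=float)
    r = pr.r0 * m ** (p - 1.0)
    cc = pr.carrying_capacity(m)
    mu = np.maximum(np.asarray(mu_resource_predation, dtype=float), 0.0)
    total = r + mu
    n_eq = r * cc / total
    new = n_eq + (resource.density - n_eq) * np.exp(-total * dt)
    return ResourceState(density=new, params=pr)


def spawn_output(
    densities: np.ndarray,
    e_net_pos: np.ndarray,
    psi: np.ndarray,
    bin_widths: np.ndarray,
    phys: PhysiologyParams,
    egg_mass: float,
) -> np.ndarray:
    """Per-phenotype spawn output Rp (recruits m^-3 yr^-1).

    Rp = eps/(2 m0) * integral of N(m) * (energy surplus)(m) * psi(m) dm;
    the factor 1/2 assumes half the spawners are female, 1/m0 converts egg
    biomass to egg numbers.  The energy surplus is already floored at zero.
    """
    egg_energy = densities * e_net_pos * psi                 # (P, n_fish)
    return phys.eps / (2.0 * egg_mass) * (egg_energy @ bin_widths)


def pooled_recruitment(
    Rp: np.ndarray, species_idx: np.ndarray, Rmax: np.ndarray
) -> np.ndarray:
    """Beverton-Holt recruitment with one R_max shared per species.

    Offspring of all phenotypes of a species are pooled: the species-level
    flux is R_s = Rmax * sum(Rp) / (sum(Rp) + Rmax), then distributed among
    phenotypes in proportion to their spawn output, so abundant phenotypes
    are not disproportionately penalised by density dependence.

    Parameters are per-phenotype ``Rp``, their 0-based species indices, and
    per-species ``Rmax``.  Returns the per-phenotype recruitment flux.
    """
    Rp = np.asarray(Rp, dtype=float)
    if np.any(np.asarray(Rmax) <= 0):
        raise ValueError("Rmax must be positive")
    S = len(Rmax)
    tot = np.zeros(S)
    np.add.at(tot, species_idx, Rp)
    R_species = np.asarray(Rmax) * tot / (tot + np.asarray(Rmax))
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot[species_idx] > 0, Rp / tot[species_idx], 0.0)
    return R_species[species_idx] * share


def upwind_step(
    N: np.ndarray,
    growth: np.ndarray,
    mu: np.ndarray,
    recruit_flux: np.ndarray,
    bin_widths: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One semi-implicit first-order upwind step of the transport equation.

    N, growth, mu are (P, n_bins); recruit_flux is (P,) numbers/volume/yr
    entering through the egg-bin boundary (g*N at m0 equals the recruitment
    flux).  The scheme solves, bin by bin in increasing mass,

        N_i^+ = (N_i + dt/dw_i * g_{i-1} N_{i-1}^+ + [i=0] dt R/dw_0)
                / (1 + dt*(g_i/dw_i + mu_i))

    which keeps densities non-negative for any dt.  Updates in place and
    returns ``N``.
    """
    dw = bin_widths
    n_bins = N.shape[1]
    denom = 1.0 + dt * (growth / dw[None, :] + mu)
    N[:, 0] = (N[:, 0] + dt * recruit_flux / dw[0]) / denom[:, 0]
    for i in range(1, n_bins):
        N[:, i] = (N[:, i] + (dt / dw[i]) * growth[:, i - 1] * N[:, i - 1]) / denom[:, i]
    return N


def step_community(
    state: CommunityState,
    theta: np.ndarray,
    phys: PhysiologyParams,
    F: float | np.ndarray = 0.0,
    dt: float = 0.1,
    tables: KernelTables | None = None,
    rates: RateBundle | None = None,
) -> CommunityState:
    """Advance the whole community by one time step ``dt`` (years), in place.

    Order of operations: rates from the current state; spawn output and
    pooled Beverton-Holt recruitment; upwind transport of every phenotype
    with recruitment as the egg-bin flux; exact resource update with the
    current predation field; truncation of densities above each phenotype's
    asymptotic size.  Raises ``RuntimeError`` on non-finite densities
    (numerical blow-up).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = state.grid
    tables = tables or KernelTables.build(grid, phys)
    rates = rates or compute_rates(state, theta, phys, F=F, tables=tables)
    sp = state.species_idx

    Rp = spawn_output(
        state.densities,
        rates.e_net_pos[sp],
        rates.psi,
        grid.fish_bin_widths,
        phys,
        grid.egg_mass,
    )
    Rmax = np.array([s.Rmax for s in state.species])
    recruit = pooled_recruitment(Rp, sp, Rmax)

    upwind_step(
        state.densities,
        rates.growth,
        rates.mu_total,
        recruit,
        grid.fish_bin_widths,
        dt,
    )
    # individuals cannot grow beyond their species' asymptotic size
    state.densities[grid.fish_masses[None, :] > state.species_M()[:, None]] = 0.0
    if not np.all(np.isfinite(state.densities)):
        bad = np.where(~np.isfinite(state.densities).all(axis=1))[0]
        raise RuntimeError(
            f"non-finite densities after step at t={state.time:.2f} "
            f"(phenotype rows {bad.tolist()}): numerical blow-up"
        )
    state.resource = resource_step(
        state.resource,
        grid.resource_masses,
        rates.mu_resource_predation,
        dt,
        p=phys.p,
    )
    state.time += dt
    return state
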