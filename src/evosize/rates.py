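"""Per-step ecological rates: encounter, feeding, growth, and mortality.

The food web is size-structured: a predator of mass m prefers prey around
m/beta, with a log-normal selection kernel of width sigma.  Encounter sums
the background resource and all fish phenotypes (weighted by the species
interaction matrix), intake saturates via a Holling type II response, and
assimilated energy is split between somatic growth and reproduction by a
size-dependent allocation function.  Mortality has five components:
emergent predation, senescence (a survival cost of reproduction), starvation
(energy deficit), a constant species-level background rate, and knife-edge
fishing.

Encounter and feeding level depend only on the predator's species (all
phenotypes of a species share the interaction-matrix row), so they are
computed per species and broadcast to phenotypes; allocation, growth and
senescence depend on each phenotype's maturation mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import SizeGrid
from .params import PhysiologyParams
from .state import CommunityState

__all__ = [
    "feeding_kernel",
    "KernelTables",
    "encounter_rate",
    "feeding_level",
    "allocation_psi",
    "growth_rate",
    "predation_mortality",
    "other_mortalities",
    "RateBundle",
    "compute_rates",
]


def feeding_kernel(m, mp, beta: float, sigma: float):
    """Log-normal prey-size selection: phi = exp(-ln(m/(beta*mp))^2/(2 sigma^2)).

    Peaks at 1 when the predator:prey mass ratio equals beta; symmetric in
    the log of that ratio.
    """
    m = np.asarray(m, dtype=float)
    mp = np.asarray(mp, dtype=float)
    if np.any(m <= 0) or np.any(mp <= 0):
        raise ValueError("masses must be positive")
    x = np.log(m / (beta * mp))
    out = np.exp(-(x**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KernelTables:
    """Precomputed kernel-times-quadrature matrices for one grid and kernel.

    enc_fish[i, j]  = phi(mf_i, mf_j) * mf_j * dwf_j   (encounter, fish prey)
    enc_res[i, j]   = phi(mf_i, mr_j) * mr_j * dwr_j   (encounter, resource prey)
    pred_fish[k, i] = phi(mf_i, mf_k) * dwf_i          (predation on fish prey k)
    pred_res[k, i]  = phi(mf_i, mr_k) * dwf_i          (predation on resource prey k)
    """

    enc_fish: np.ndarray
    enc_res: np.ndarray
    pred_fish: np.ndarray
    pred_res: np.ndarray

    @classmethod
    def build(cls, grid: SizeGrid, phys: PhysiologyParams) -> "KernelTables":
        mf = grid.fish_masses
        mr = grid.resource_masses
        phi_ff = feeding_kernel(mf[:, None], mf[None, :], phys.beta, phys.sigma)
        phi_fr = feeding_kernel(mf[:, None], mr[None, :], phys.beta, phys.sigma)
        return cls(
            enc_fish=phi_ff * (mf * grid.fish_bin_widths)[None, :],
            enc_res=phi_fr * (mr * grid.resource_bin_widths)[None, :],
            pred_fish=phi_ff.T * grid.fish_bin_widths[None, :],
            pred_res=phi_fr.T * grid.fish_bin_widths[None, :],
        )


def encounter_rate(
    state: CommunityState,
    theta: np.ndarray,
    phys: PhysiologyParams,
    tables: KernelTables | None = None,
) -> np.ndarray:
    """Encountered food (g/yr) per predator species over the fish grid.

    E(m) = gamma m^q * integral of (N_R(mp) + sum_j theta[i, j] N_j(mp))
    phi(m, mp) mp dmp.  The background resource is fully available to every
    predator (availability 1); theta scales only fish-on-fish availability,
    with the diagonal setting cannibalism.  Returns an (S, n_fish) array.
    """
    tables = tables or KernelTables.build(state.grid, phys)
    Ntot = state.species_total_density()            # (S, n_fish)
    if theta.shape != (state.n_species, state.n_species):
        raise ValueError("interaction matrix does not match the community")
    prey = theta @ Ntot                              # (S, n_fish) weighted fish prey
    res_part = tables.enc_res @ state.resource.density   # (n_fish,)
    fish_part = prey @ tables.enc_fish.T                  # (S, n_fish)
    vol = phys.gamma * state.grid.fish_masses**phys.q
    return vol[None, :] * (res_part[None, :] + fish_part)


def feeding_level(E, m, h: float, n: float):
    """Holling type II satiation: f = E / (E + h m^n), in [0, 1)."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("encounter rate must be non-negative")
    out = E / (E + h * np.asarray(m, dtype=float) ** n)
    return out if out.ndim else float(out)


def allocation_psi(m, m_star, M: float, u: float, n: float):
    """Fraction of net energy allocated to reproduction.

    psi(m) = [1 + (m/m*)^(-u)]^(-1) * (m/M)^(1-n): a logistic switch around
    the maturation mass times an allometric factor that drives allocation to
    1 as m approaches the asymptotic size.
    """
    m = np.asarray(m, dtype=float)
    m_star = np.asarray(m_star, dtype=float)
    if np.any(m_star > M):
        raise ValueError("maturation mass cannot exceed asymptotic mass")
    psi = (m / M) ** (1.0 - n) / (1.0 + (m / m_star) ** (-u))
    psi = np.clip(psi, 0.0, 1.0)
    return psi if psi.ndim else float(psi)


def growth_rate(f, m, psi, phys: PhysiologyParams):
    """Somatic growth g = (alpha f h m^n - ks m^p)(1 - psi), floored at zero.

    A negative energy budget does not shrink individuals; the deficit is
    charged as starvation mortality instead (see :func:`other_mortalities`).
    """
    m = np.asarray(m, dtype=float)
    e_net = phys.alpha * np.asarray(f) * phys.h * m**phys.n - phys.ks * m**phys.p
    g = np.maximum(e_net, 0.0) * (1.0 - np.asarray(psi))
    return g if g.ndim else float(g)


def predation_mortality(
    state: CommunityState,
    theta: np.ndarray,
    phys: PhysiologyParams,
    feeding: np.ndarray,
    tables: KernelTables | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predation mortality fields (1/yr) on fish and resource prey.

    mu_p(mp) = sum_j integral phi(m, mp) (1 - f_j(m)) gamma m^q theta N_j(m) dm.
    Satiated predators (f -> 1) contribute nothing.  Fish prey of species i
    receive availability theta[j, i] to predator species j; the resource is
    fully available to every predator.

    Returns ``(mu_fish, mu_res)``: (S, n_fish) per prey species, and
    (n_resource,) for the resource grid.
    """
    tables = tables or KernelTables.build(state.grid, phys)
    Ntot = state.species_total_density()
    vol = phys.gamma * state.grid.fish_masses**phys.q
    # predation pressure density of each predator species over predator mass
    D = (1.0 - feeding) * vol[None, :] * Ntot        # (S, n_fish)
    per_pred_fish = D @ tables.pred_fish.T           # (S_pred, n_fish prey)
    mu_fish = theta.T @ per_pred_fish                # prey species i: sum_j theta[j, i] ...
    mu_res = (D @ tables.pred_res.T).sum(axis=0)     # (n_resource,)
    return mu_fish, mu_res


def other_mortalities(
    m: np.ndarray,
    m_star,
    M: float,
    phys: PhysiologyParams,
    F: float = 0.0,
    selectivity_mass: float | None = None,
    deficit=0.0,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Senescence, starvation, background, and fishing mortality (1/yr).

    - senescence: se_min + (se_max - se_min) e^(-M/m) for m > m*, else 0 —
      a survival cost of reproduction rising toward se_max at the asymptotic
      size.
    - starvation: energy deficit divided by the mobilisable reserve xi*m;
      zero when intake covers metabolism.
    - background: mu0 M^(n-1), constant per species (larger species live
      longer).
    - fishing: knife-edge, F at and above the selectivity mass.
    """
    m = np.asarray(m, dtype=float)
    mu_se = np.where(
        m > np.asarray(m_star),
        phys.se_min + (phys.se_max - phys.se_min) * np.exp(-M / m),
        0.0,
    )
    mu_st = np.maximum(np.asarray(deficit, dtype=float), 0.0) / (phys.xi * m)
    mu_b = phys.mu0 * M ** (phys.n - 1.0)
    sel = 0.25 * M if selectivity_mass is None else selectivity_mass
    mu_f = np.where(m >= sel, F, 0.0)
    return mu_se, np.broadcast_to(mu_st, m.shape), float(mu_b), mu_f


@dataclass
class RateBundle:
    """All rates for one step.  Phenotype-level arrays are (P, n_fish);
    ``encounter`` and ``feeding`` are species-level (S, n_fish) since they are
    shared by all phenotypes of a species."""

    encounter: np.ndarray          # (S, n_fish) g/yr
    feeding: np.ndarray            # (S, n_fish) dimensionless
    e_net_pos: np.ndarray          # (S, n_fish) assimilated energy surplus, g/yr
    deficit: np.ndarray            # (S, n_fish) energy shortfall, g/yr
    psi: np.ndarray                # (P, n_fish)
    growth: np.ndarray             # (P, n_fish) g/yr
    mu_predation: np.ndarray       # (S, n_fish) 1/yr
    mu_senescence: np.ndarray      # (P, n_fish) 1/yr
    mu_starvation: np.ndarray      # (S, n_fish) 1/yr
    mu_background: np.ndarray      # (S,) 1/yr
    mu_fishing: np.ndarray         # (S, n_fish) 1/yr
    mu_total: np.ndarray           # (P, n_fish) 1/yr
    mu_resource_predation: np.ndarray  # (n_resource,) 1/yr

    def phenotype_feeding(self, species_idx: np.ndarray) -> np.ndarray:
        return self.feeding[species_idx]


def compute_rates(
    state: CommunityState,
    theta: np.ndarray,
    phys: PhysiologyParams,
    F: float | np.ndarray = 0.0,
    tables: KernelTables | None = None,
) -> RateBundle:
    """Evaluate every rate field for the current state.

    ``F`` may be a scalar or a per-species array of instantaneous fishing
    mortalities; selectivity masses come from each species' configuration.
    """
    grid = state.grid
    m = grid.fish_masses
    S = state.n_species
    tables = tables or KernelTables.build(grid, phys)

    E = encounter_rate(state, theta, phys, tables)          # (S, n_fish)
    f = feeding_level(E, m[None, :], phys.h, phys.n)        # (S, n_fish)
    e_net = phys.alpha * f * phys.h * m[None, :] ** phys.n - phys.ks * m[None, :] ** phys.p
    e_pos = np.maximum(e_net, 0.0)
    deficit = np.maximum(-e_net, 0.0)

    # phenotype-level allocation and growth
    M_phen = state.species_M()                              # (P,)
    m_star = state.m_star                                   # (P,)
    psi = (m[None, :] / M_phen[:, None]) ** (1.0 - phys.n) / (
        1.0 + (m[None, :] / m_star[:, None]) ** (-phys.u)
    )
    np.clip(psi, 0.0, 1.0, out=psi)
    sp = state.species_idx
    growth = e_pos[sp] * (1.0 - psi)

    mu_fish_pred, mu_res_pred = predation_mortality(state, theta, phys, f, tables)

    Ms = np.array([s.M for s in state.species])
    mu_b = phys.mu0 * Ms ** (phys.n - 1.0)                  # (S,)
    F_arr = np.broadcast_to(np.asarray(F, dtype=float), (S,))
    sel = np.array([s.fishing_selectivity_mass for s in state.species])
    mu_f = np.where(m[None, :] >= sel[:, None], F_arr[:, None], 0.0)
    mu_st = deficit / (phys.xi * m[None, :])                # (S, n_fish)
    mu_se = np.where(
        m[None, :] > m_star[:, None],
        phys.se_min + (phys.se_max - phys.se_min) * np.exp(-M_phen[:, None] / m[None, :]),
        0.0,
    )

    mu_total = mu_se + (mu_fish_pred + mu_st + mu_f + mu_b[:, None])[sp]

    return RateBundle(
        encounter=E,
        feeding=f,
        e_net_pos=e_pos,
        deficit=deficit,
        psi=psi,
        growth=growth,
        mu_predation=mu_fish_pred,
        mu_senescence=mu_se,
        mu_starvation=mu_st,
        mu_background=mu_b,
        mu_fishing=mu_f,
        mu_total=mu_total,
        mu_resource_predation=mu_res_pred,
    )
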