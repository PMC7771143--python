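"""Stochastic phenotype turnover: introduction, mutation, extinction.

Evolution of maturation size is modelled by lineage substitution rather than
interbreeding: at each time step each species has probability chi of budding
a new lineage ("phenotype") off a randomly chosen parent, with the relative
maturation size eta perturbed by a truncated-normal relative change.  The
child starts with a fixed fraction of the parent's biomass (subtracted from
the parent, so introduction conserves community biomass), and lineages whose
total abundance falls below the extinction threshold omega are removed.

Draw order is fixed (species in index order: one uniform per species, then
the mutation draws for species that fire), so a seed fully determines a
replicate.
"""

from __future__ import annotations

import numpy as np

from .params import EvolutionConfig
from .state import CommunityState

__all__ = [
    "mutate_trait",
    "maybe_spawn_phenotypes",
    "prune_extinct",
    "weighted_mean_trait",
]


def mutate_trait(
    parent_eta: float,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
    M: float,
    egg_mass: float,
) -> float:
    """Draw a child trait: eta' = eta*(1 + delta), delta ~ Normal(0, sd)
    truncated to +-mutation_halfwidth, redrawn until the child maturation
    mass lies in (egg_mass, M].  Falls back to clipping after 100 draws."""
    lo = egg_mass / M
    for _ in range(100):
        delta = rng.normal(0.0, cfg.mutation_sd)
        if abs(delta) > cfg.mutation_halfwidth:
            continue
        child = parent_eta * (1.0 + delta)
        if lo < child <= 1.0:
            return child
    return float(min(max(parent_eta, np.nextafter(lo, 1.0)), 1.0))


def maybe_spawn_phenotypes(
    state: CommunityState, cfg: EvolutionConfig, rng: np.random.Generator
) -> CommunityState:
    """Possibly introduce one mutated phenotype per species, in place.

    For each species independently, with probability chi: pick a parent
    uniformly among its extant phenotypes, mutate its trait, and move
    ``init_fraction`` of the parent's density (every size bin scaled equally)
    into the fresh lineage.  Community biomass is unchanged at the instant of
    introduction.  Extinct species are skipped.
    """
    new_rows = []
    for s in range(state.n_species):
        u = rng.uniform()
        if u >= cfg.chi:
            continue
        members = np.where(state.species_idx == s)[0]
        if members.size == 0:
            continue  # species extinct
        parent = members[rng.integers(members.size)]
        child_eta = mutate_trait(
            float(state.eta[parent]),
            cfg,
            rng,
            state.species[s].M,
            state.grid.egg_mass,
        )
        if cfg.seed_as_eggs:
            # alternative seeding: the transferred biomass enters as an
            # egg-size pulse instead of a proportional slice of the spectrum
            biomass = cfg.init_fraction * float(
                state.densities[parent]
                @ (state.grid.fish_masses * state.grid.fish_bin_widths)
            )
            child_density = np.zeros(state.grid.n_fish)
            child_density[0] = biomass / (
                state.grid.egg_mass * state.grid.fish_bin_widths[0]
            )
        else:
            child_density = cfg.init_fraction * state.densities[parent]
        state.densities[parent] *= 1.0 - cfg.init_fraction
        new_rows.append((s, child_eta, parent, child_density))

    for s, child_eta, parent, child_density in new_rows:
        state.densities = np.vstack([state.densities, child_density[None, :]])
        state.species_idx = np.append(state.species_idx, s)
        state.eta = np.append(state.eta, child_eta)
        state.phenotype_id = np.append(state.phenotype_id, state.next_phenotype_id)
        state.parent_id = np.append(
            state.parent_id, state.phenotype_id[parent]
        )
        state.birth_time = np.append(state.birth_time, state.time)
        state.next_phenotype_id += 1
    return state


def prune_extinct(state: CommunityState, cfg: EvolutionConfig) -> CommunityState:
    """Remove phenotypes whose total abundance (density integrated over the
    fish grid) is strictly below omega; surviving densities are untouched.
    Returns the same state, modified in place."""
    keep = state.phenotype_abundance() >= cfg.omega
    if keep.all():
        return state
    state.densities = state.densities[keep]
    state.species_idx = state.species_idx[keep]
    state.eta = state.eta[keep]
    state.phenotype_id = state.phenotype_id[keep]
    state.parent_id = state.parent_id[keep]
    state.birth_time = state.birth_time[keep]
    return state


def weighted_mean_trait(
    state: CommunityState, numbers_weighted: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-species abundance-weighted mean eta and extant phenotype count.

    Weights are phenotype biomasses by default (numbers optionally).  Extinct
    species get NaN mean and count 0.  Returns ``(mean_eta, counts)`` of
    length n_species.
    """
    S = state.n_species
    w = (
        state.phenotype_abundance()
        if numbers_weighted
        else state.phenotype_biomass()
    )
    mean = np.full(S, np.nan)
    counts = np.zeros(S, dtype=int)
    for s in range(S):
        sel = state.species_idx == s
        counts[s] = int(sel.sum())
        ws = w[sel]
        if counts[s] and ws.sum() > 0:
            mean[s] = float(np.average(state.eta[sel], weights=ws))
        elif counts[s]:
            mean[s] = float(state.eta[sel].mean())
    return mean, counts
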