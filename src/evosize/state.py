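"""Community state: evolving phenotype spectra plus the background resource.

Internally all phenotype densities live in one (n_phenotypes, n_fish_bins)
array so that the transport scheme and the rate computations vectorise across
lineages; :class:`PhenotypeSpectrum` offers a per-lineage view for inspection
and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import SizeGrid
from .params import ResourceParams, SpeciesParams

__all__ = [
    "PhenotypeSpectrum",
    "ResourceState",
    "CommunityState",
    "initial_abundance",
    "init_community",
]


@dataclass
class PhenotypeSpectrum:
    """One evolving lineage: a species identity, a maturation trait, and an
    abundance density over the fish mass grid (individuals m^-3 g^-1)."""

    phenotype_id: int
    species_id: int
    eta: float
    m_star: float
    birth_time: float
    parent_id: int | None
    density: np.ndarray


@dataclass
class ResourceState:
    """Background resource spectrum with semi-chemostat regeneration."""

    density: np.ndarray  # N_R(m), individuals m^-3 g^-1, on the resource grid
    params: ResourceParams = field(default_factory=ResourceParams)


@dataclass
class CommunityState:
    """All live phenotypes, the resource, and the simulation clock.

    ``densities`` has one row per extant phenotype; parallel arrays hold each
    phenotype's species index (0-based into ``species``), trait value and
    lineage metadata.
    """

    grid: SizeGrid
    species: list[SpeciesParams]
    densities: np.ndarray          # (P, n_fish)
    species_idx: np.ndarray        # (P,) int, 0-based
    eta: np.ndarray                # (P,) float
    phenotype_id: np.ndarray       # (P,) int
    parent_id: np.ndarray          # (P,) int, -1 for founders
    birth_time: np.ndarray         # (P,) float
    resource: ResourceState
    time: float = 0.0
    next_phenotype_id: int = 0

    @property
    def n_phenotypes(self) -> int:
        return self.densities.shape[0]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def m_star(self) -> np.ndarray:
        """Maturation mass per phenotype (g)."""
        M = np.array([self.species[s].M for s in self.species_idx])
        return self.eta * M

    def species_M(self) -> np.ndarray:
        """Asymptotic mass per phenotype (g)."""
        return np.array([self.species[s].M for s in self.species_idx])

    def phenotype_abundance(self) -> np.ndarray:
        """Total individuals per volume per phenotype (density integrated
        over the fish grid)."""
        return self.densities @ self.grid.fish_bin_widths

    def phenotype_biomass(self) -> np.ndarray:
        """Biomass per volume per phenotype (g m^-3)."""
        return self.densities @ (self.grid.fish_masses * self.grid.fish_bin_widths)

    def species_total_density(self) -> np.ndarray:
        """(S, n_fish) summed density of all phenotypes of each species."""
        out = np.zeros((self.n_species, self.grid.n_fish))
        np.add.at(out, self.species_idx, self.densities)
        return out

    def extant_species(self) -> np.ndarray:
        """Boolean mask over species: at least one live phenotype."""
        alive = np.zeros(self.n_species, dtype=bool)
        alive[np.unique(self.species_idx)] = True
        return alive

    def phenotypes(self) -> list[PhenotypeSpectrum]:
        """Per-lineage views (densities are not copied)."""
        out = []
        for k in range(self.n_phenotypes):
            s = self.species[self.species_idx[k]]
            pid = int(self.parent_id[k])
            out.append(
                PhenotypeSpectrum(
                    phenotype_id=int(self.phenotype_id[k]),
                    species_id=s.species_id,
                    eta=float(self.eta[k]),
                    m_star=float(self.eta[k] * s.M),
                    birth_time=float(self.birth_time[k]),
                    parent_id=None if pid < 0 else pid,
                    density=self.densities[k],
                )
            )
        return out

    def copy(self) -> "CommunityState":
        return CommunityState(
            grid=self.grid,
            species=list(self.species),
            densities=self.densities.copy(),
            species_idx=self.species_idx.copy(),
            eta=self.eta.copy(),
            phenotype_id=self.phenotype_id.copy(),
            parent_id=self.parent_id.copy(),
            birth_time=self.birth_time.copy(),
            resource=ResourceState(
                density=self.resource.density.copy(), params=self.resource.params
            ),
            time=self.time,
            next_phenotype_id=self.next_phenotype_id,
        )


def initial_abundance(
    species: SpeciesParams,
    grid: SizeGrid,
    kappa: float,
    n: float = 0.75,
    q: float = 0.8,
) -> np.ndarray:
    """Equilibrium abundance density used to seed each species at t = 0.

    The closed form N(m) = (kappa/1000) * M^(2n-q-2+0.35) * m^(-n-0.35)
    (an Andersen-Beyer style community equilibrium) is evaluated on every
    fish bin with m <= M and set to zero above the asymptotic size.
    """
    m = grid.fish_masses
    N = (kappa / 1000.0) * species.M ** (2 * n - q - 2 + 0.35) * m ** (-n - 0.35)
    N[m > species.M] = 0.0
    return N


def init_community(
    species: list[SpeciesParams],
    grid: SizeGrid,
    resource: ResourceParams | None = None,
    n: float = 0.75,
    q: float = 0.8,
) -> CommunityState:
    """Deterministic initial state: one founder phenotype per species at its
    equilibrium abundance, resource at carrying capacity."""
    resource = resource or ResourceParams()
    S = len(species)
    dens = np.stack(
        [initial_abundance(sp, grid, resource.kappa, n=n, q=q) for sp in species]
    )
    return CommunityState(
        grid=grid,
        species=list(species),
        densities=dens,
        species_idx=np.arange(S, dtype=np.int64),
        eta=np.array([sp.eta0 for sp in species]),
        phenotype_id=np.arange(S, dtype=np.int64),
        parent_id=np.full(S, -1, dtype=np.int64),
        birth_time=np.zeros(S),
        resource=ResourceState(
            density=resource.carrying_capacity(grid.resource_masses), params=resource
        ),
        time=0.0,
        next_phenotype_id=S,
    )
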