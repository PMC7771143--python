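"""Parameter containers: shared physiology, species traits, resource, evolution.

Defaults reproduce the calibrated 9-species community used throughout: a
single set of physiological rates shared by all species, species differing
only in asymptotic size M, initial relative maturation size eta, and the
maximum recruitment flux R_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "PhysiologyParams",
    "SpeciesParams",
    "ResourceParams",
    "EvolutionConfig",
    "FishingPolicy",
    "interaction_matrix",
    "gamma_from_feeding_level",
    "PAPER9_TABLE",
]


@dataclass(frozen=True)
class PhysiologyParams:
    """Shared physiological parameters (one set for all species).

    Units follow the allometric convention of size-spectrum models: rate
    coefficients carry the grams-exponent needed to make the rate come out
    in g/yr (intake, metabolism) or 1/yr (mortalities).
    """

    alpha: float = 0.6     # assimilation efficiency (-)
    h: float = 85.0        # max intake coefficient (g^(1-n)/yr)
    n: float = 0.75        # intake exponent (-)
    p: float = 0.75        # standard-metabolism exponent (-)
    ks: float = 4.0        # standard-metabolism coefficient (g^(1-p)/yr)
    gamma: float = 538.0   # search-volume coefficient (g^(-q) m^3/yr)
    q: float = 0.8         # search-volume exponent (-)
    beta: float = 100.0    # preferred predator:prey mass ratio (-)
    sigma: float = 1.0     # feeding-kernel width (-)
    u: float = 7.0         # maturation-transition steepness (-)
    eps: float = 1.0       # efficiency of offspring production (-)
    f0: float = 0.5        # initial/expected feeding level (-)
    mu0: float = 2.0       # background-mortality coefficient (g^(1-n)/yr)
    se_min: float = 0.1    # senescence mortality lower bound (1/yr)
    se_max: float = 1.0    # senescence mortality upper bound (1/yr)
    xi: float = 0.1        # fraction of body mass available as energy reserves (-)
    st_r: float = 0.1      # starvation mortality coefficient (1/yr), kept configurable

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"physiology parameter {f.name!r} must be positive")
        if self.alpha > 1 or self.eps > 1:
            raise ValueError("alpha and eps are efficiencies and cannot exceed 1")
        if self.se_min > self.se_max:
            raise ValueError("se_min must not exceed se_max")

    @property
    def critical_feeding_level(self) -> float:
        """Feeding level at which intake exactly covers standard metabolism
        (size-independent when p == n)."""
        return self.ks / (self.alpha * self.h)


def gamma_from_feeding_level(
    phys: PhysiologyParams, kappa: float, lambda_: float
) -> float:
    """Diagnostic: search-volume coefficient implied by an expected feeding
    level f0 on a resource spectrum kappa*m^-lambda.

    gamma = h f0 / (sqrt(2 pi) sigma beta^(lambda-2) e^((lambda-2)^2 sigma^2 / 2)
            kappa (1 - f0)).  With the default physiology this evaluates to
    ~538, matching the tabulated value.
    """
    lm2 = lambda_ - 2.0
    denom = (
        math.sqrt(2.0 * math.pi)
        * phys.sigma
        * phys.beta**lm2
        * math.exp(lm2**2 * phys.sigma**2 / 2.0)
        * kappa
        * (1.0 - phys.f0)
    )
    return phys.h * phys.f0 / denom


@dataclass(frozen=True)
class SpeciesParams:
    """One species: identity, asymptotic size, initial trait, recruitment cap."""

    species_id: int
    M: float                       # asymptotic mass (g)
    eta0: float = 0.25             # initial relative maturation size (-)
    Rmax: float = 1.0              # max recruitment flux (numbers m^-3 yr^-1)
    fishing_selectivity_mass: float | None = None  # knife-edge threshold (g); default 0.25*M

    def __post_init__(self) -> None:
        if not 0 < self.eta0 < 1:
            raise ValueError("eta0 must lie in (0, 1)")
        if self.M <= 0 or self.Rmax <= 0:
            raise ValueError("M and Rmax must be positive")
        if self.fishing_selectivity_mass is None:
            object.__setattr__(self, "fishing_selectivity_mass", 0.25 * self.M)

    @property
    def maturation_mass(self) -> float:
        return self.eta0 * self.M


# The calibrated 9-species community: asymptotic sizes log-spaced 10..1e5 g,
# maturation at a quarter of M, R_max declining with M.
PAPER9_TABLE: tuple[tuple[float, float, float], ...] = (
    # (maturation mass m* (g), asymptotic mass M (g), Rmax)
    (2.5, 10.0, 0.49208),
    (8.0, 32.0, 0.19854),
    (25.0, 100.0, 0.08011),
    (79.0, 316.0, 0.03232),
    (250.0, 1000.0, 0.01304),
    (790.0, 3162.0, 0.00526),
    (2500.0, 10000.0, 0.00212),
    (7905.0, 31622.0, 0.00085),
    (25000.0, 100000.0, 0.00034),
)


@dataclass(frozen=True)
class ResourceParams:
    """Semi-chemostat background resource spectrum."""

    r0: float = 4.0        # regeneration-rate coefficient (g^(1-p)/yr)
    kappa: float = 0.05    # carrying-capacity magnitude (g^(lambda-1) m^-3)
    lambda_: float = 2.05  # spectrum slope, 2 - n + q
    m_cut: float = 1.0     # upper limit of the resource spectrum (g)

    def __post_init__(self) -> None:
        if min(self.r0, self.kappa, self.m_cut) <= 0:
            raise ValueError("resource parameters must be positive")

    def carrying_capacity(self, masses: np.ndarray) -> np.ndarray:
        return self.kappa * np.asarray(masses, dtype=float) ** (-self.lambda_)


@dataclass(frozen=True)
class EvolutionConfig:
    """Stochastic phenotype-turnover settings.

    chi is the per-species probability of introducing one mutated phenotype
    per time step (so the evolutionary tempo scales with dt).  A new lineage
    receives ``init_fraction`` of the parent's biomass; lineages whose total
    abundance drops below ``omega`` are removed.
    """

    chi: float = 0.001              # introduction probability per species per step (-)
    mutation_sd: float = 0.10       # sd of relative trait change (-)
    mutation_halfwidth: float = 0.20  # truncation of relative trait change (-)
    init_fraction: float = 0.05     # fraction of parent biomass given to the child (-)
    omega: float = 1e-30            # extinction threshold (individuals m^-3)
    seed: int | None = None
    seed_as_eggs: bool = False      # if True, the 5% biomass enters as an egg-size pulse
    numbers_weighted_trait: bool = False  # trait mean weighting: biomass (default) or numbers

    def __post_init__(self) -> None:
        if not 0 <= self.chi <= 1:
            raise ValueError("chi must be a probability")
        if not 0 < self.init_fraction < 1:
            raise ValueError("init_fraction must lie in (0, 1)")
        if self.omega <= 0 or self.mutation_sd <= 0 or self.mutation_halfwidth <= 0:
            raise ValueError("omega, mutation_sd, mutation_halfwidth must be positive")


@dataclass(frozen=True)
class FishingPolicy:
    """Knife-edge fishing: mortality F applied at and above the selectivity
    mass, which stays fixed at its initial value (it does not track evolved
    maturation sizes)."""

    F: float = 0.8  # instantaneous fishing mortality (1/yr); default fished scenario

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")


def interaction_matrix(n_species: int, theta: float | np.ndarray = 0.5) -> np.ndarray:
    """Availability matrix theta[predator_species, prey_species] in [0, 1].

    The factorial scenarios use a constant matrix: 0.5 everywhere with
    predation enabled (the diagonal sets cannibalism), 0 everywhere without,
    in which case fish feed only on the background resource.
    """
    th = np.asarray(theta, dtype=float)
    if th.ndim == 0:
        th = np.full((n_species, n_species), float(th))
    if th.shape != (n_species, n_species):
        raise ValueError("interaction matrix has wrong shape")
    if np.any(th < 0) or np.any(th > 1):
        raise ValueError("interaction entries must lie in [0, 1]")
    return th
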