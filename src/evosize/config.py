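"""Configuration: YAML/JSON parsing, defaults, fixtures, digests.

A run is described by one structured file with sections ``species``,
``physiology``, ``interaction``, ``resource``, ``evolution``, ``fishing``,
``numerics`` and ``run``.  Unspecified keys fall back to the calibrated
9-species community defaults.  Parameter names may be given either as ASCII
identifiers or as the conventional symbols (greek letters included).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .grids import SizeGrid, make_grid
from .params import (
    PAPER9_TABLE,
    EvolutionConfig,
    FishingPolicy,
    PhysiologyParams,
    ResourceParams,
    SpeciesParams,
    interaction_matrix,
)

__all__ = [
    "Numerics",
    "RunSettings",
    "ModelConfig",
    "load_config",
    "dump_config",
    "config_digest",
    "make_fixture",
]


@dataclass(frozen=True)
class Numerics:
    """Discretisation: time step and grid resolutions."""

    dt: float = 0.1               # yr
    egg_mass: float = 0.001       # g
    max_mass: float = 1e5         # g, upper end of the fish grid
    n_fish_bins: int = 100
    n_resource_bins: int = 160
    resource_min: float = 1e-10   # g

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def build_grid(self, m_cut: float = 1.0) -> SizeGrid:
        return make_grid(
            egg_mass=self.egg_mass,
            max_mass=self.max_mass,
            n_fish_bins=self.n_fish_bins,
            n_resource_bins=self.n_resource_bins,
            resource_min=self.resource_min,
            m_cut=m_cut,
        )


@dataclass(frozen=True)
class RunSettings:
    """Experiment design settings."""

    burn_in_years: float = 3000.0
    post_years: float = 3000.0
    n_replicates: int = 10
    base_seed: int = 0
    thin_every: float = 1.0       # recording interval, years

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.thin_every <= 0:
            raise ValueError("n_replicates >= 1 and thin_every > 0 required")


# accepted aliases (symbol or variant spelling -> canonical field name)
_ALIASES: dict[str, dict[str, str]] = {
    "physiology": {
        "α": "alpha", "γ": "gamma", "β": "beta", "σ": "sigma", "ε": "eps",
        "epsilon": "eps", "ξ": "xi", "μ0": "mu0", "mu_0": "mu0",
        "semin": "se_min", "semax": "se_max", "str": "st_r",
    },
    "resource": {"κ": "kappa", "λ": "lambda_", "lambda": "lambda_",
                 "r_0": "r0", "mcut": "m_cut"},
    "evolution": {"χ": "chi", "Ω": "omega", "omega_threshold": "omega"},
    "species": {"η": "eta0", "eta": "eta0", "R_max": "Rmax", "rmax": "Rmax",
                "m_star": None, "maturation_mass": None},
    "fishing": {"f": "F"},
    "numerics": {"m0": "egg_mass", "m_0": "egg_mass"},
    "interaction": {"θ": "theta"},
    "run": {"seed": "base_seed", "replicates": "n_replicates"},
}


def _normalise(section: str, d: dict, allowed: set[str]) -> dict:
    out = {}
    aliases = _ALIASES.get(section, {})
    for k, v in d.items():
        canon = aliases.get(k, k)
        if canon is None:  # recognised but derived (e.g. m*), ignore
            continue
        if canon not in allowed:
            raise ValueError(f"unknown key {k!r} in section {section!r}")
        out[canon] = v
    return out


@dataclass
class ModelConfig:
    """Full validated configuration of a simulation."""

    species: list[SpeciesParams]
    phys: PhysiologyParams = field(default_factory=PhysiologyParams)
    resource: ResourceParams = field(default_factory=ResourceParams)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    theta: float | np.ndarray = 0.5
    fishing: FishingPolicy = field(default_factory=FishingPolicy)
    numerics: Numerics = field(default_factory=Numerics)
    run: RunSettings = field(default_factory=RunSettings)

    def interaction(self) -> np.ndarray:
        return interaction_matrix(len(self.species), self.theta)

    def build_grid(self) -> SizeGrid:
        max_M = max(s.M for s in self.species)
        max_mass = max(self.numerics.max_mass, max_M)
        num = self.numerics
        return make_grid(
            egg_mass=num.egg_mass,
            max_mass=max_mass,
            n_fish_bins=num.n_fish_bins,
            n_resource_bins=num.n_resource_bins,
            resource_min=num.resource_min,
            m_cut=self.resource.m_cut,
        )

    def to_dict(self) -> dict:
        th = self.theta
        return {
            "species": [asdict(s) for s in self.species],
            "physiology": asdict(self.phys),
            "resource": asdict(self.resource),
            "evolution": asdict(self.evolution),
            "interaction": {"theta": th.tolist() if isinstance(th, np.ndarray) else th},
            "fishing": asdict(self.fishing),
            "numerics": asdict(self.numerics),
            "run": asdict(self.run),
        }

    @property
    def digest(self) -> str:
        return config_digest(self.to_dict())


def config_digest(d: dict) -> str:
    """Stable content hash of a configuration dictionary."""
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"), default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _field_names(cls) -> set[str]:
    return {f.name for f in fields(cls)}


def _config_from_dict(raw: dict) -> ModelConfig:
    raw = dict(raw or {})
    known_sections = {
        "species", "physiology", "resource", "evolution", "interaction",
        "fishing", "numerics", "run",
    }
    for k in raw:
        if k not in known_sections:
            raise ValueError(f"unknown configuration section {k!r}")

    sp_raw = raw.get("species")
    if sp_raw is None:
        species = default_species()
    else:
        species = []
        allowed = _field_names(SpeciesParams)
        for i, entry in enumerate(sp_raw):
            e = _normalise("species", dict(entry), allowed)
            e.setdefault("species_id", i + 1)
            species.append(SpeciesParams(**e))

    phys = PhysiologyParams(
        **_normalise("physiology", raw.get("physiology", {}), _field_names(PhysiologyParams))
    )
    resource = ResourceParams(
        **_normalise("resource", raw.get("resource", {}), _field_names(ResourceParams))
    )
    evolution = EvolutionConfig(
        **_normalise("evolution", raw.get("evolution", {}), _field_names(EvolutionConfig))
    )
    inter = _normalise("interaction", raw.get("interaction", {}), {"theta"})
    theta = inter.get("theta", 0.5)
    if isinstance(theta, list):
        theta = np.asarray(theta, dtype=float)
    fishing = FishingPolicy(
        **_normalise("fishing", raw.get("fishing", {}), _field_names(FishingPolicy))
    )
    numerics = Numerics(
        **_normalise("numerics", raw.get("numerics", {}), _field_names(Numerics))
    )
    run = RunSettings(**_normalise("run", raw.get("run", {}), _field_names(RunSettings)))
    return ModelConfig(
        species=species,
        phys=phys,
        resource=resource,
        evolution=evolution,
        theta=theta,
        fishing=fishing,
        numerics=numerics,
        run=run,
    )


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML (or JSON) configuration file.

    An empty file yields the full default configuration (the calibrated
    9-species community).  Unknown keys and out-of-range values raise
    ``ValueError`` naming the offending key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    return _config_from_dict(raw)


def dump_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML; load -> dump -> load preserves the
    digest."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def default_species() -> list[SpeciesParams]:
    """The calibrated 9-species community: asymptotic sizes log-spaced from
    10 g to 100 kg, eta0 = 0.25, R_max declining with size."""
    return [
        SpeciesParams(species_id=i + 1, M=M, eta0=mstar / M, Rmax=rmax)
        for i, (mstar, M, rmax) in enumerate(PAPER9_TABLE)
    ]


def make_fixture(kind: str) -> ModelConfig:
    """Ready-made communities for experiments and tests.

    - ``paper9``: the full calibrated 9-species community, predation on.
    - ``toy3``: 3 species (M = 10, 1e3, 1e5 g) on a coarser grid — a fast
      profile for CI-scale runs.
    - ``single``: one species, no predatory interactions (resource feeding
      only).
    """
    if kind == "paper9":
        return ModelConfig(species=default_species())
    if kind == "toy3":
        rows = [PAPER9_TABLE[0], PAPER9_TABLE[4], PAPER9_TABLE[8]]
        species = [
            SpeciesParams(species_id=i + 1, M=M, eta0=mstar / M, Rmax=rmax)
            for i, (mstar, M, rmax) in enumerate(rows)
        ]
        return ModelConfig(
            species=species,
            numerics=Numerics(n_fish_bins=50, n_resource_bins=80),
        )
    if kind == "single":
        return ModelConfig(
            species=[SpeciesParams(species_id=1, M=1000.0, eta0=0.25, Rmax=0.01304)],
            theta=0.0,
            numerics=Numerics(n_fish_bins=60, n_resource_bins=80, max_mass=1e3),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
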