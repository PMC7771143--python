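"""Simulation design: burn-in, state fork, factorial scenarios, sweeps.

The reference design: run the community for a burn-in period without fishing
so phenotype diversity builds up, save the full stochastic state, then fork
paired continuations from that identical state with and without fishing.
Replicates differ only in their RNG seed (replicate r uses base_seed + r);
by default a fork resumes the saved RNG stream, so the F = 0 fork is the
exact continuation of the burn-in and fished/unfished forks are paired on
identical mutation histories.  Passing ``reseed`` gives a fork an
independent child stream instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import ModelConfig, make_fixture
from .dynamics import step_community
from .evolution import maybe_spawn_phenotypes, prune_extinct, weighted_mean_trait
from .fitness import RateHistory
from .rates import KernelTables, compute_rates
from .reporting import Recorder, RunResult
from .state import CommunityState, ResourceState, init_community

logger = logging.getLogger("evosize")

__all__ = [
    "ScenarioSpec",
    "CommunityCollapse",
    "simulate",
    "save_checkpoint",
    "load_checkpoint",
    "run_burn_in",
    "fork_with_fishing",
    "fishing_gradient_sweep",
    "sensitivity_sweep",
]


class CommunityCollapse(RuntimeError):
    """All species went extinct."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One experiment scenario.

    ``predation_on`` selects the interaction matrix (all 0.5 vs all 0);
    ``fishing_on``/``F`` control the knife-edge fishery applied after the
    burn-in fork.
    """

    predation_on: bool = True
    fishing_on: bool = False
    F: float = 0.8
    burn_in_years: float = 3000.0
    post_years: float = 3000.0
    n_replicates: int = 10
    base_seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if self.burn_in_years < 0 or self.post_years < 0:
            raise ValueError("years must be non-negative")

    def configure(self, cfg: ModelConfig | None = None) -> ModelConfig:
        cfg = cfg or make_fixture("paper9")
        cfg = apply_overrides(cfg, self.overrides)
        theta = 0.5 if self.predation_on else 0.0
        return replace_config(cfg, theta=theta)


def replace_config(cfg: ModelConfig, **kwargs) -> ModelConfig:
    d = {
        "species": cfg.species,
        "phys": cfg.phys,
        "resource": cfg.resource,
        "evolution": cfg.evolution,
        "theta": cfg.theta,
        "fishing": cfg.fishing,
        "numerics": cfg.numerics,
        "run": cfg.run,
    }
    d.update(kwargs)
    return ModelConfig(**d)


_SWEEPABLE = {
    # parameter name -> (section, attribute)
    "F": ("fishing", "F"),
    "eta0": ("species", "eta0"),
    "mutation_sd": ("evolution", "mutation_sd"),
    "chi": ("evolution", "chi"),
    "init_fraction": ("evolution", "init_fraction"),
    "sigma": ("phys", "sigma"),
    "beta": ("phys", "beta"),
}


def apply_overrides(cfg: ModelConfig, overrides: dict) -> ModelConfig:
    """Apply named parameter overrides (the sensitivity-sweep knobs)."""
    for name, value in overrides.items():
        if name not in _SWEEPABLE:
            raise ValueError(
                f"unknown sweep parameter {name!r}; choose from {sorted(_SWEEPABLE)}"
            )
        section, attr = _SWEEPABLE[name]
        if section == "species":
            new_species = [replace(s, **{attr: value}) for s in cfg.species]
            cfg = replace_config(cfg, species=new_species)
        else:
            cfg = replace_config(cfg, **{section: replace(getattr(cfg, section), **{attr: value})})
    return cfg


def simulate(
    cfg: ModelConfig,
    years: float,
    seed: int | None = None,
    state: CommunityState | None = None,
    rng: np.random.Generator | None = None,
    F: float | None = None,
    record_feeding: str = "final",
    history: RateHistory | None = None,
    history_window: tuple[float, float] | None = None,
    history_every: int = 1,
) -> tuple[CommunityState, RunResult, np.random.Generator]:
    """Run the coupled eco-evolutionary model for ``years`` years.

    Starts from ``state`` (or the deterministic initial community), applying
    fishing mortality ``F`` (default: the configured policy).  Snapshots are
    recorded every ``run.thin_every`` years.  If ``history`` is given,
    per-step rate fields are recorded into it for times inside
    ``history_window`` (start, end), thinned to every ``history_every``-th
    step, for later cohort/fitness analysis.

    Returns ``(final_state, result, rng)``.  Raises
    :class:`CommunityCollapse` if every species goes extinct.
    """
    grid_state = state if state is not None else init_community(
        cfg.species, cfg.build_grid(), cfg.resource, n=cfg.phys.n, q=cfg.phys.q
    )
    theta = cfg.interaction()
    phys = cfg.phys
    evo = cfg.evolution
    dt = cfg.numerics.dt
    F_eff = cfg.fishing.F if F is None else F
    if rng is None:
        rng = np.random.default_rng(cfg.evolution.seed if seed is None else seed)
    tables = KernelTables.build(grid_state.grid, phys)
    recorder = Recorder(record_feeding=record_feeding)

    n_steps = int(round(years / dt))
    thin_steps = max(1, int(round(cfg.run.thin_every / dt)))
    stochastic = evo.chi > 0

    for step in range(n_steps):
        rates = compute_rates(grid_state, theta, phys, F=F_eff, tables=tables)
        if step % thin_steps == 0:
            mean_eta, counts = weighted_mean_trait(
                grid_state, numbers_weighted=evo.numbers_weighted_trait
            )
            recorder.snapshot(grid_state, rates, mean_eta, counts)
        if history is not None and step % history_every == 0:
            lo, hi = history_window or (-np.inf, np.inf)
            if lo - 1e-9 <= grid_state.time < hi - 1e-9:
                history.record(grid_state, rates, phys)
        step_community(grid_state, theta, phys, F=F_eff, dt=dt, tables=tables, rates=rates)
        if stochastic:
            maybe_spawn_phenotypes(grid_state, evo, rng)
        prune_extinct(grid_state, evo)
        if grid_state.n_phenotypes == 0:
            raise CommunityCollapse(
                f"all species extinct at t={grid_state.time:.1f} yr"
            )

    # closing snapshot at the final state
    rates = compute_rates(grid_state, theta, phys, F=F_eff, tables=tables)
    mean_eta, counts = weighted_mean_trait(
        grid_state, numbers_weighted=evo.numbers_weighted_trait
    )
    recorder.snapshot(grid_state, rates, mean_eta, counts)
    recorder.final_feeding(grid_state, rates)

    metadata = {
        "config_digest": cfg.digest,
        "seed": seed,
        "F": F_eff,
        "theta": float(np.asarray(cfg.theta).ravel()[0]) if np.ndim(cfg.theta) else cfg.theta,
        "years": years,
        "n_steps": n_steps,
        "t_start": grid_state.time - years,
        "t_end": grid_state.time,
    }
    result = recorder.build(metadata)
    result.lineage = _lineage_table(grid_state)
    logger.info(
        "run finished: digest=%s seed=%s F=%s steps=%d phenotypes=%d",
        cfg.digest, seed, F_eff, n_steps, grid_state.n_phenotypes,
    )
    return grid_state, result, rng


def _lineage_table(state: CommunityState) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phenotype_id": state.phenotype_id,
            "species_id": [state.species[s].species_id for s in state.species_idx],
            "parent_id": state.parent_id,
            "eta": state.eta,
            "birth_time": state.birth_time,
            "death_time": np.nan,  # extant lineages only; pruned ones are gone
        }
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    path: str | Path,
    state: CommunityState,
    rng: np.random.Generator,
    config_digest: str,
) -> None:
    """Save the full simulation state (community + resource + RNG + digest)
    to an HDF5 container; save -> load -> save is bit-identical."""
    with h5py.File(path, "w") as f:
        f.create_dataset("densities", data=state.densities)
        f.create_dataset("species_idx", data=state.species_idx)
        f.create_dataset("eta", data=state.eta)
        f.create_dataset("phenotype_id", data=state.phenotype_id)
        f.create_dataset("parent_id", data=state.parent_id)
        f.create_dataset("birth_time", data=state.birth_time)
        f.create_dataset("resource_density", data=state.resource.density)
        f.attrs["time"] = state.time
        f.attrs["next_phenotype_id"] = state.next_phenotype_id
        f.attrs["config_digest"] = config_digest
        f.attrs["rng_state"] = json.dumps(rng.bit_generator.state)


def load_checkpoint(
    path: str | Path, cfg: ModelConfig, force: bool = False
) -> tuple[CommunityState, np.random.Generator]:
    """Restore a checkpoint saved by :func:`save_checkpoint`.

    The grid, species table and resource parameters are rebuilt from ``cfg``,
    whose digest must match the one stored in the file (unless ``force``).
    """
    with h5py.File(path, "r") as f:
        stored = f.attrs["config_digest"]
        if stored != cfg.digest and not force:
            raise ValueError(
                f"checkpoint digest {stored} does not match configuration {cfg.digest}"
            )
        grid = cfg.build_grid()
        state = CommunityState(
            grid=grid,
            species=list(cfg.species),
            densities=f["densities"][...],
            species_idx=f["species_idx"][...],
            eta=f["eta"][...],
            phenotype_id=f["phenotype_id"][...],
            parent_id=f["parent_id"][...],
            birth_time=f["birth_time"][...],
            resource=ResourceState(
                density=f["resource_density"][...], params=cfg.resource
            ),
            time=float(f.attrs["time"]),
            next_phenotype_id=int(f.attrs["next_phenotype_id"]),
        )
        rng_state = json.loads(f.attrs["rng_state"])
    rng = np.random.default_rng()
    rng.bit_generator.state = rng_state
    return state, rng


# ---------------------------------------------------------------------------
# the experiment design


def run_burn_in(
    spec: ScenarioSpec,
    cfg: ModelConfig | None = None,
    replicate: int = 0,
    checkpoint_path: str | Path | None = None,
    **simulate_kwargs,
) -> tuple[CommunityState, RunResult, np.random.Generator]:
    """Burn-in: simulate ``burn_in_years`` with fishing off.

    Replicate ``r`` is seeded with ``base_seed + r``.  If ``checkpoint_path``
    is given, the final state and RNG are saved there.
    """
    cfg = spec.configure(cfg)
    seed = spec.base_seed + replicate
    state, result, rng = simulate(
        cfg, spec.burn_in_years, seed=seed, F=0.0, **simulate_kwargs
    )
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, state, rng, cfg.digest)
    return state, result, rng


def fork_with_fishing(
    checkpoint_path: str | Path,
    cfg: ModelConfig,
    F_values: list[float],
    years: float,
    reseed: int | None = None,
    **simulate_kwargs,
) -> dict[float, RunResult]:
    """Continue paired runs from one saved state under different fishing
    mortalities.

    Every fork restarts from the identical checkpoint state.  With
    ``reseed=None`` the saved RNG stream is resumed, so the F = 0 fork is the
    exact continuation of the burn-in and all forks share one mutation
    history; with an integer ``reseed`` each fork f gets the independent
    child stream ``SeedSequence(reseed, spawn_key=(f,))``.
    """
    out: dict[float, RunResult] = {}
    for i, F in enumerate(F_values):
        state, rng = load_checkpoint(checkpoint_path, cfg)
        if reseed is not None:
            rng = np.random.default_rng(np.random.SeedSequence(reseed, spawn_key=(i,)))
        _, result, _ = simulate(
            cfg, years, seed=reseed, state=state, rng=rng, F=F, **simulate_kwargs
        )
        result.metadata["forked_from"] = str(checkpoint_path)
        out[F] = result
    return out


def fishing_gradient_sweep(
    checkpoint_path: str | Path,
    cfg: ModelConfig,
    F_list: list[float] | None = None,
    years: float = 3000.0,
    reseed: int | None = None,
    **simulate_kwargs,
) -> pd.DataFrame:
    """Final biomass-weighted mean eta per species for each fishing
    mortality on the grid (default 0.1 .. 1.0 in steps of 0.1)."""
    F_list = list(F_list) if F_list is not None else [round(0.1 * k, 1) for k in range(1, 11)]
    rows = []
    results = fork_with_fishing(
        checkpoint_path, cfg, F_list, years, reseed=reseed, **simulate_kwargs
    )
    for F, res in results.items():
        fin = res.final_trait()
        for _, r in fin.iterrows():
            rows.append(
                {
                    "F": F,
                    "species_id": int(r["species_id"]),
                    "final_eta": r["weighted_eta"],
                    "n_phenotypes": int(r["n_phenotypes"]),
                }
            )
    return pd.DataFrame(rows)


def sensitivity_sweep(
    parameter: str,
    values: list[float],
    spec: ScenarioSpec,
    cfg: ModelConfig | None = None,
    years: float | None = None,
    **simulate_kwargs,
) -> dict[float, RunResult]:
    """Re-run the scenario with one parameter swept over a grid.

    ``parameter`` must be one of the exposed knobs (F, eta0, mutation_sd,
    chi, init_fraction, sigma, beta).  An empty grid returns an empty dict
    without running anything.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; choose from {sorted(_SWEEPABLE)}"
        )
    out: dict[float, RunResult] = {}
    for v in values:
        sub = ScenarioSpec(
            predation_on=spec.predation_on,
            fishing_on=spec.fishing_on,
            F=spec.F if parameter != "F" else v,
            burn_in_years=spec.burn_in_years,
            post_years=spec.post_years,
            n_replicates=spec.n_replicates,
            base_seed=spec.base_seed,
            overrides={**spec.overrides, **({parameter: v} if parameter != "F" else {})},
        )
        sub_cfg = sub.configure(cfg)
        F = v if parameter == "F" and sub.fishing_on else (sub.F if sub.fishing_on else 0.0)
        _, result, _ = simulate(
            sub_cfg,
            years if years is not None else sub.burn_in_years,
            seed=sub.base_seed,
            F=F,
            **simulate_kwargs,
        )
        out[v] = result
    return out
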