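"""Result containers, time-series recording, summaries, CSV round trips.

All tabular outputs are tidy CSV (UTF-8, header row, '.' decimal, missing
values as empty fields); every table carries the configuration digest so that
results from different configurations are not silently mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("evosize")

__all__ = ["Recorder", "RunResult", "summarize", "write_result", "read_result"]


@dataclass
class Recorder:
    """Accumulates yearly (or thinned) snapshots during a run."""

    record_feeding: str = "final"  # "none" | "final" | "all"
    _trait: list = field(default_factory=list)
    _biomass: list = field(default_factory=list)
    _feeding: list = field(default_factory=list)

    def snapshot(self, state, rates, weighted_eta, counts) -> None:
        t = state.time
        biom = state.phenotype_biomass()
        for s in range(state.n_species):
            self._trait.append(
                (t, state.species[s].species_id, weighted_eta[s], int(counts[s]))
            )
        for k in range(state.n_phenotypes):
            self._biomass.append(
                (
                    t,
                    state.species[state.species_idx[k]].species_id,
                    int(state.phenotype_id[k]),
                    float(state.eta[k]),
                    float(biom[k]),
                )
            )
        if self.record_feeding == "all" and rates is not None:
            self._append_feeding(state, rates)

    def _append_feeding(self, state, rates) -> None:
        m = state.grid.fish_masses
        for s in range(state.n_species):
            sp = state.species[s]
            mask = m <= sp.M
            for mi, fi in zip(m[mask], rates.feeding[s][mask]):
                self._feeding.append((state.time, sp.species_id, float(mi), float(fi)))

    def final_feeding(self, state, rates) -> None:
        if self.record_feeding in ("final", "all"):
            self._append_feeding(state, rates)

    def build(self, metadata: dict) -> "RunResult":
        trait = pd.DataFrame(
            self._trait, columns=["time", "species_id", "weighted_eta", "n_phenotypes"]
        )
        biomass = pd.DataFrame(
            self._biomass, columns=["time", "species_id", "phenotype_id", "eta", "biomass"]
        )
        feeding = pd.DataFrame(
            self._feeding, columns=["time", "species_id", "size", "f"]
        )
        return RunResult(metadata=metadata, trait=trait, biomass=biomass, feeding=feeding)


@dataclass
class RunResult:
    """Recorded outputs of one simulation.

    Tables:
    - ``trait``: time, species_id, weighted_eta, n_phenotypes
    - ``biomass``: time, species_id, phenotype_id, eta, biomass (g m^-3)
    - ``feeding``: time, species_id, size (g), f
    - ``lineage``: phenotype_id, species_id, parent_id, eta, birth_time,
      death_time (empty if extant at the end)
    """

    metadata: dict
    trait: pd.DataFrame
    biomass: pd.DataFrame
    feeding: pd.DataFrame = field(default_factory=pd.DataFrame)
    lineage: pd.DataFrame = field(default_factory=pd.DataFrame)
    fitness: pd.DataFrame | None = None

    @property
    def digest(self) -> str:
        return self.metadata.get("config_digest", "")

    def final_trait(self) -> pd.DataFrame:
        """Weighted mean eta and phenotype count per species at the last
        recorded time."""
        t_end = self.trait["time"].max()
        return self.trait[self.trait["time"] == t_end].reset_index(drop=True)


def summarize(results: list[RunResult], force: bool = False) -> pd.DataFrame:
    """Across-replicate summary of final trait values.

    Returns one row per species: mean, sd and per-replicate final weighted
    eta, plus the proportional change relative to the earliest recorded
    value.  Results with mixed configuration digests are rejected unless
    ``force`` is set.
    """
    if not results:
        raise ValueError("need at least one RunResult")
    digests = {r.digest for r in results}
    if len(digests) > 1 and not force:
        raise ValueError(f"mixed config digests {sorted(digests)}; pass force=True to combine")
    rows = []
    for rep, r in enumerate(results):
        fin = r.final_trait()
        t0 = r.trait["time"].min()
        init = r.trait[r.trait["time"] == t0].set_index("species_id")["weighted_eta"]
        for _, row in fin.iterrows():
            sid = row["species_id"]
            eta = row["weighted_eta"]
            rows.append(
                {
                    "replicate": rep,
                    "seed": r.metadata.get("seed"),
                    "species_id": sid,
                    "final_eta": eta,
                    "prop_change": eta / init.loc[sid] - 1.0 if np.isfinite(eta) else np.nan,
                }
            )
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby("species_id")["final_eta"]
        .agg(mean_final_eta="mean", sd_final_eta=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan)
        .reset_index()
    )
    chg = per_rep.groupby("species_id")["prop_change"].mean().rename("mean_prop_change")
    return agg.merge(chg, on="species_id")


def write_result(result: RunResult, outdir: str | Path) -> None:
    """Write all tables of a result as CSV files plus a metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.trait.to_csv(outdir / "trait.csv", index=False)
    result.biomass.to_csv(outdir / "biomass.csv", index=False)
    result.feeding.to_csv(outdir / "feeding.csv", index=False)
    result.lineage.to_csv(outdir / "lineage.csv", index=False)
    if result.fitness is not None:
        result.fitness.to_csv(outdir / "fitness.csv", index=False)
    pd.Series(
        {k: v for k, v in result.metadata.items()}, name="value"
    ).rename_axis("key").to_csv(outdir / "metadata.csv")
    logger.info(
        "wrote result: digest=%s seed=%s steps=%s -> %s",
        result.digest,
        result.metadata.get("seed"),
        result.metadata.get("n_steps"),
        outdir,
    )


def read_result(outdir: str | Path) -> RunResult:
    """Read a result written by :func:`write_result` (lossless round trip)."""
    outdir = Path(outdir)
    meta = pd.read_csv(outdir / "metadata.csv", index_col=0)["value"].to_dict()
    fitness_path = outdir / "fitness.csv"
    return RunResult(
        metadata=meta,
        trait=pd.read_csv(outdir / "trait.csv"),
        biomass=pd.read_csv(outdir / "biomass.csv"),
        feeding=pd.read_csv(outdir / "feeding.csv"),
        lineage=pd.read_csv(outdir / "lineage.csv"),
        fitness=pd.read_csv(fitness_path) if fitness_path.exists() else None,
    )
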