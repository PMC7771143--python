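"""Fitness: cohort tracking along growth characteristics.

The fitness of a phenotype is a modified lifetime reproductive output
("eggs per recruit"): a cohort born at t0 is followed for a horizon t_max
(default 50 years) along its growth characteristic dm/dt = g(m, t) through
the rate fields the forward simulation actually produced.  Survivorship
decays with the total mortality along the path; the cohort's spawn output is
run through the species' Beverton-Holt recruitment and the resulting
recruitment flux is integrated over the horizon and normalised by the
cohort's initial numbers.  The cohort is bookkeeping only — it does not feed
back on the community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PhysiologyParams
from .rates import RateBundle
from .state import CommunityState

__all__ = ["RateHistory", "CohortTrack", "track_cohort", "phenotype_fitness", "fitness_landscape"]


@dataclass
class RateHistory:
    """Per-step rate fields recorded during a forward run, for cohort
    tracking.  Each snapshot stores, for every extant phenotype: the growth
    and total-mortality fields over the fish grid, the per-capita spawn-output
    rate eps/(2 m0) * (energy surplus) * psi (eggs per individual per year as
    a function of body mass), and the numbers currently in the egg bin."""

    masses: np.ndarray
    times: list[float] = field(default_factory=list)
    phenotype_ids: list[np.ndarray] = field(default_factory=list)
    species_idx: list[np.ndarray] = field(default_factory=list)
    eta: list[np.ndarray] = field(default_factory=list)
    growth: list[np.ndarray] = field(default_factory=list)
    mu_total: list[np.ndarray] = field(default_factory=list)
    spawn_percap: list[np.ndarray] = field(default_factory=list)
    egg_numbers: list[np.ndarray] = field(default_factory=list)

    def record(
        self, state: CommunityState, rates: RateBundle, phys: PhysiologyParams
    ) -> None:
        sp = state.species_idx
        percap = (
            phys.eps
            / (2.0 * state.grid.egg_mass)
            * rates.e_net_pos[sp]
            * rates.psi
        )
        self.times.append(state.time)
        self.phenotype_ids.append(state.phenotype_id.copy())
        self.species_idx.append(sp.copy())
        self.eta.append(state.eta.copy())
        self.growth.append(rates.growth.copy())
        self.mu_total.append(rates.mu_total.copy())
        self.spawn_percap.append(percap.copy())
        self.egg_numbers.append(
            state.densities[:, 0] * state.grid.fish_bin_widths[0]
        )

    def step_index_at(self, t: float) -> int:
        times = np.asarray(self.times)
        idx = int(np.searchsorted(times, t - 1e-9))
        if idx >= len(self.times):
            raise ValueError(f"no recorded rates at or after t={t}")
        return idx


@dataclass
class CohortTrack:
    """A cohort followed along its growth characteristic."""

    phenotype_id: int
    t0: float
    horizon: float
    times: np.ndarray         # step times within [t0, t0 + horizon)
    mass: np.ndarray          # m(t) along the characteristic (g)
    survivorship: np.ndarray  # fraction of the cohort still alive, in [0, 1]
    spawn_rate: np.ndarray    # per-capita spawn-output rate (eggs/ind/yr)


def _interp_field(field_row: np.ndarray, masses: np.ndarray, m: float) -> float:
    return float(np.interp(np.log(m), np.log(masses), field_row))


def track_cohort(
    history: RateHistory,
    phenotype_id: int,
    t0: float | None = None,
    horizon: float = 50.0,
) -> CohortTrack:
    """Follow a cohort of ``phenotype_id`` born at ``t0`` for ``horizon``
    years through the recorded rate fields.

    The cohort starts at the egg mass with survivorship 1; at each recorded
    step the growth, mortality and per-capita spawn-rate fields are
    interpolated (linearly in log mass) at the cohort's current mass, then
    mass and survivorship are advanced over the recording interval.  If the
    lineage disappears from the record (pruned as extinct) survivorship drops
    to zero.
    """
    t0 = history.times[0] if t0 is None else t0
    i0 = history.step_index_at(t0)
    times_arr = np.asarray(history.times)
    if times_arr[-1] < t0 + horizon - 1e-9:
        # allow the last recorded interval to close the horizon exactly
        last_dt = times_arr[-1] - times_arr[-2] if len(times_arr) > 1 else 0.0
        if times_arr[-1] + last_dt < t0 + horizon - 1e-9:
            raise ValueError("recorded history does not cover the requested horizon")
    sel = (times_arr >= t0 - 1e-9) & (times_arr < t0 + horizon - 1e-9)
    idxs = np.where(sel)[0]

    m = float(history.masses[0])
    surv = 1.0
    t_out, m_out, s_out, r_out = [], [], [], []
    alive = True
    for k, i in enumerate(idxs):
        dt = (
            times_arr[idxs[k + 1]] - times_arr[i]
            if k + 1 < len(idxs)
            else (times_arr[i] - times_arr[i - 1] if i > 0 else 0.0)
        )
        ids = history.phenotype_ids[i]
        pos = np.where(ids == phenotype_id)[0]
        if pos.size == 0:
            alive = False
        if not alive:
            t_out.append(times_arr[i]); m_out.append(m); s_out.append(0.0); r_out.append(0.0)
            continue
        row = int(pos[0])
        g = _interp_field(history.growth[i][row], history.masses, m)
        mu = _interp_field(history.mu_total[i][row], history.masses, m)
        r = _interp_field(history.spawn_percap[i][row], history.masses, m)
        t_out.append(times_arr[i]); m_out.append(m); s_out.append(surv); r_out.append(r)
        m = m + max(g, 0.0) * dt
        surv = surv * float(np.exp(-mu * dt))
    return CohortTrack(
        phenotype_id=phenotype_id,
        t0=t0,
        horizon=horizon,
        times=np.asarray(t_out),
        mass=np.asarray(m_out),
        survivorship=np.asarray(s_out),
        spawn_rate=np.asarray(r_out),
    )


def phenotype_fitness(
    cohort: CohortTrack, Rmax: float, initial_numbers: float
) -> float:
    """Lifetime-reproductive-output fitness proxy.

    fitness = integral over the horizon of Rmax*Rp/(Rp + Rmax) dt, divided by
    the cohort's initial numbers, where Rp(t) is the cohort's own spawn
    output: initial_numbers * survivorship(t) * per-capita spawn rate(t).
    Comparable across phenotypes within a species (same Rmax), not across
    species.
    """
    if initial_numbers <= 0:
        raise ValueError("initial_numbers must be positive")
    if cohort.times.size < 2:
        return 0.0
    dts = np.diff(cohort.times)
    dts = np.append(dts, dts[-1])
    Rp = initial_numbers * cohort.survivorship * cohort.spawn_rate
    integrand = Rmax * Rp / (Rp + Rmax)
    return float(np.sum(integrand * dts) / initial_numbers)


def fitness_landscape(
    history: RateHistory,
    species_Rmax: np.ndarray,
    snapshot_year: float | None = None,
    horizon: float = 50.0,
    fishing_on: bool | None = None,
    predation_on: bool | None = None,
) -> pd.DataFrame:
    """One fitness value per phenotype extant at the snapshot.

    Cohorts start at the first recorded step at or after ``snapshot_year``;
    each cohort's initial numbers are the phenotype's egg-bin numbers at that
    step (falling back to a nominal unit cohort if the egg bin is empty, in
    which case only the linear, density-independent regime is probed).
    Returns a tidy frame: snapshot_year, species_id, phenotype_id, eta,
    fitness, and optional scenario flags.
    """
    t0 = history.times[0] if snapshot_year is None else snapshot_year
    i0 = history.step_index_at(t0)
    t0 = history.times[i0]
    rows = []
    for row, pid in enumerate(history.phenotype_ids[i0]):
        n0 = float(history.egg_numbers[i0][row])
        if n0 <= 0:
            n0 = 1e-12
        cohort = track_cohort(history, int(pid), t0=t0, horizon=horizon)
        s = int(history.species_idx[i0][row])
        fit = phenotype_fitness(cohort, float(species_Rmax[s]), n0)
        rows.append(
            {
                "snapshot_year": t0,
                "species_id": s + 1,
                "phenotype_id": int(pid),
                "eta": float(history.eta[i0][row]),
                "fitness": fit,
                "fishing": fishing_on,
                "predation": predation_on,
            }
        )
    return pd.DataFrame(rows)
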