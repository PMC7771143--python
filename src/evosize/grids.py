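"""Logarithmic body-mass grids and quadrature weights.

Two grids are used throughout: a fish grid running from the egg mass m0 up to
(at least) the largest asymptotic size in the community, and a background
resource grid running from bacterial sizes up to the resource cut-off m_cut.
All integrals over mass (encounter, predation mortality, spawn output) are
evaluated with trapezoid weights on these grids, so the weights double as bin
widths for the finite-difference transport scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SizeGrid", "make_grid", "trapezoid_weights"]


def trapezoid_weights(masses: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for an ordered mass grid.

    Interior weight i is (m[i+1] - m[i-1])/2; the end points carry half of
    their adjacent interval.  Summing the weights reproduces the grid span
    exactly, so integrating a constant is exact for any bin count.
    """
    m = np.asarray(masses, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("need a 1-d grid with at least two masses")
    w = np.empty_like(m)
    w[1:-1] = 0.5 * (m[2:] - m[:-2])
    w[0] = 0.5 * (m[1] - m[0])
    w[-1] = 0.5 * (m[-1] - m[-2])
    return w


@dataclass(frozen=True)
class SizeGrid:
    """Log-spaced mass grids for fish and background resource.

    Attributes
    ----------
    fish_masses : ndarray
        Body masses (g), strictly increasing; the first entry is the egg mass.
    fish_bin_widths : ndarray
        Trapezoid quadrature weights (g) for the fish grid.
    resource_masses : ndarray
        Resource item masses (g), spanning plankton/bacteria sizes up to m_cut.
    resource_bin_widths : ndarray
        Trapezoid quadrature weights (g) for the resource grid.
    egg_mass : float
        Offspring mass m0 (g); equal to ``fish_masses[0]``.
    """

    fish_masses: np.ndarray
    fish_bin_widths: np.ndarray
    resource_masses: np.ndarray
    resource_bin_widths: np.ndarray
    egg_mass: float = field(default=0.001)

    def __post_init__(self) -> None:
        for name in ("fish_masses", "resource_masses"):
            m = getattr(self, name)
            if np.any(m <= 0) or np.any(np.diff(m) <= 0):
                raise ValueError(f"{name} must be positive and strictly increasing")
        if not np.isclose(self.fish_masses[0], self.egg_mass):
            raise ValueError("fish grid must start at the egg mass")

    @property
    def n_fish(self) -> int:
        return self.fish_masses.size

    @property
    def n_resource(self) -> int:
        return self.resource_masses.size


def make_grid(
    egg_mass: float = 0.001,
    max_mass: float = 1e5,
    n_fish_bins: int = 100,
    n_resource_bins: int = 160,
    resource_min: float = 1e-10,
    m_cut: float = 1.0,
) -> SizeGrid:
    """Build log-spaced fish and resource grids.

    Parameters
    ----------
    egg_mass, max_mass : float
        Bounds of the fish grid (g).  ``max_mass`` should be at least the
        largest asymptotic size in the community.
    n_fish_bins, n_resource_bins : int
        Number of grid points (>= 10 each).
    resource_min, m_cut : float
        Bounds of the background resource grid (g); the resource spectrum
        spans bacteria to zooplankton, 1e-10 g up to m_cut = 1 g by default.
    """
    if egg_mass <= 0 or max_mass <= 0 or resource_min <= 0 or m_cut <= 0:
        raise ValueError("masses must be positive")
    if max_mass <= egg_mass:
        raise ValueError("max_mass must exceed egg_mass")
    if resource_min >= m_cut:
        raise ValueError("resource_min must be below m_cut")
    if n_fish_bins < 10 or n_resource_bins < 10:
        raise ValueError("need at least 10 bins per grid")
    fish = np.logspace(np.log10(egg_mass), np.log10(max_mass), n_fish_bins)
    fish[0] = egg_mass  # guard against logspace round-off at the boundary
    res = np.logspace(np.log10(resource_min), np.log10(m_cut), n_resource_bins)
    return SizeGrid(
        fish_masses=fish,
        fish_bin_widths=trapezoid_weights(fish),
        resource_masses=res,
        resource_bin_widths=trapezoid_weights(res),
        egg_mass=egg_mass,
    )
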