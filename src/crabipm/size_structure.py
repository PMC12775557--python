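"""Discretised size domain and per-bin abundance vectors.

The population state is a density over carapace width discretised onto a
regular grid of ``m`` bins of width ``delta``; every kernel operation in the
package integrates over this grid with the midpoint rule, while initial and
recruit densities are binned by CDF differences (more accurate near the
lower boundary, where recruit mass concentrates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["SizeGrid", "DensityVector", "make_grid", "bin_density"]


class GridError(ValueError):
    """Raised for inconsistent grid configuration."""


@dataclass(frozen=True)
class SizeGrid:
    """Regular discretisation of the size domain [lower, upper] (mm).

    Bins are 1-based, half-open ``[lower + (i-1)*delta, lower + i*delta)``;
    ``midpoints[i-1] = lower + (i - 1/2) * delta``.
    """

    lower: float
    upper: float
    delta: float
    midpoints: np.ndarray = field(repr=False)
    m: int

    @property
    def edges(self) -> np.ndarray:
        """Bin edges, length ``m + 1``."""
        return np.linspace(self.lower, self.upper, self.m + 1)

    def locate(self, x: np.ndarray) -> np.ndarray:
        """Indices (0-based) of the bins containing sizes ``x``."""
        x = np.asarray(x, dtype=float)
        idx = np.floor((x - self.lower) / self.delta).astype(int)
        return np.clip(idx, 0, self.m - 1)


def make_grid(lower: float, upper: float, delta: float) -> SizeGrid:
    """Build a regular size grid.

    ``(upper - lower) / delta`` must be an integer number of bins.
    """
    if upper <= lower:
        raise GridError(f"upper ({upper}) must exceed lower ({lower})")
    if delta <= 0:
        raise GridError(f"delta must be positive, got {delta}")
    n = (upper - lower) / delta
    m = int(round(n))
    if abs(n - m) > 1e-9 or m < 1:
        raise GridError(
            f"grid range ({lower}, {upper}) is not divisible by delta={delta}"
        )
    mids = lower + (np.arange(1, m + 1) - 0.5) * delta
    return SizeGrid(lower=float(lower), upper=float(upper), delta=float(delta),
                    midpoints=mids, m=m)


@dataclass
class DensityVector:
    """Per-bin abundance (individuals already integrated over each bin)."""

    grid: SizeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.m,):
            raise ValueError(
                f"values must have length m={self.grid.m}, got {self.values.shape}"
            )
        if np.any(self.values < -1e-9):
            raise ValueError("abundance values must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "DensityVector":
        return DensityVector(self.grid, self.values.copy())


def bin_density(pdf_mass, grid: SizeGrid, total: float) -> DensityVector:
    """Discretise a probability density into per-bin abundances.

    Parameters
    ----------
    pdf_mass
        Either a frozen scipy distribution (anything exposing ``.cdf``) or a
        vectorised callable pdf of size. CDF differences between bin edges
        are used when available; otherwise each bin is integrated on a fine
        sub-grid (Simpson's rule).
    grid
        Target discretisation.
    total
        Total abundance to distribute; mass falling outside the grid is
        renormalised into it so the result sums to ``total`` exactly.
    """
    if total < 0:
        raise ValueError("total abundance must be non-negative")
    edges = grid.edges
    if hasattr(pdf_mass, "cdf"):
        cdf = pdf_mass.cdf(edges)
        mass = np.diff(cdf)
    else:
        from scipy.integrate import simpson

        n_sub = 33
        mass = np.empty(grid.m)
        for i in range(grid.m):
            xs = np.linspace(edges[i], edges[i + 1], n_sub)
            mass[i] = simpson(np.asarray(pdf_mass(xs), dtype=float), x=xs)
    mass = np.clip(mass, 0.0, None)
    z = mass.sum()
    if z <= 0:
        raise ValueError("pdf has zero mass on the size domain")
    return DensityVector(grid, total * mass / z)
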