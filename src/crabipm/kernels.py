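"""Seasonal growth, natural survival, and the size-transition kernel.

Growth follows a seasonally oscillating von Bertalanffy curve: a sine term
with period one year modulates the instantaneous growth rate so that growth
peaks in summer and approaches zero in winter.  The projection kernel is the
product of a (row-normalised) growth kernel and size-dependent natural
survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .size_structure import DensityVector, SizeGrid

__all__ = [
    "GrowthParams",
    "MortalityParams",
    "Kernel",
    "seasonal_s",
    "size_at_age",
    "growth_mean",
    "growth_kernel",
    "natural_survival",
    "projection_kernel",
]


@dataclass
class GrowthParams:
    """Parameters of the seasonal growth model.

    ``x_inf``: asymptotic size (mm); ``k``: rate of approach (1/yr);
    ``A``: seasonal oscillation amplitude; ``d_s``: year fraction of the
    oscillation inflection (time of fastest growth); ``sigma_G``: sd of the
    growth increment (mm); ``d_0``: theoretical age at size zero (yr);
    ``sigma_w``/``sigma_u``: log-sd of size-at-age error and sd of its
    year random effect.
    """

    x_inf: float
    k: float
    A: float
    d_s: float
    sigma_G: float
    d_0: float = 0.0
    sigma_w: float = 0.1
    sigma_u: float = 0.1

    def validate(self) -> None:
        if self.x_inf <= 0 or self.k <= 0 or self.sigma_G < 0:
            raise ValueError("x_inf, k must be > 0 and sigma_G >= 0")
        if not (0 <= self.d_s < 1):
            raise ValueError("d_s must lie in [0, 1)")


@dataclass
class MortalityParams:
    """Non-winter natural mortality: ``beta`` size-independent intensity
    (1/yr), ``alpha`` size-dependent scalar (mm)."""

    beta: float
    alpha: float

    def validate(self) -> None:
        if self.beta < 0 or self.alpha < 0:
            raise ValueError("beta and alpha must be non-negative")


@dataclass
class Kernel:
    """m x m size-transition weights; entry (i, j) is the probability that an
    individual at midpoint i moves to bin j over the step (survival folded
    in, so row sums are <= 1)."""

    grid: SizeGrid
    matrix: np.ndarray = field(repr=False)

    def apply(self, state: DensityVector) -> DensityVector:
        """Project a per-bin abundance vector one step forward."""
        return DensityVector(self.grid, self.matrix.T @ state.values)

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def seasonal_s(a, p: GrowthParams):
    """Seasonal oscillation integral s(a) = (A k / 2pi) sin(2pi (a - d_s)).

    Periodic with period one year; s(a + 1) == s(a).
    """
    a = np.asarray(a, dtype=float)
    out = p.A * p.k / (2.0 * np.pi) * np.sin(2.0 * np.pi * (a - p.d_s))
    return out if out.ndim else float(out)


def size_at_age(a, p: GrowthParams):
    """Expected size at age ``a`` (years) on the seasonal growth curve.

    Negative values (possible for a slightly below d_0) are truncated to
    zero with a warning.
    """
    a = np.asarray(a, dtype=float)
    expo = -p.k * (a - p.d_0) - seasonal_s(a, p) + seasonal_s(p.d_0, p)
    w = p.x_inf * (1.0 - np.exp(expo))
    if np.any(w < 0):
        warnings.warn("size_at_age below d_0 truncated to 0", RuntimeWarning)
        w = np.clip(w, 0.0, None)
    return w if w.ndim else float(w)


def growth_mean(x, d_t: float, d_next: float, delta_t: float, p: GrowthParams):
    """Expected size after an increment of ``delta_t`` years starting at
    size ``x`` and year fraction ``d_t`` (ending at ``d_next``)."""
    if delta_t < 0:
        raise ValueError("delta_t must be non-negative")
    x = np.asarray(x, dtype=float)
    fac = 1.0 - np.exp(-p.k * delta_t - seasonal_s(d_next, p) + seasonal_s(d_t, p))
    out = x + (p.x_inf - x) * fac
    return out if out.ndim else float(out)


def growth_kernel(grid: SizeGrid, d_t: float, d_next: float, delta_t: float,
                  p: GrowthParams) -> Kernel:
    """Growth-only kernel: normal spread of width sigma_G around the growth
    mean, truncated to the grid and renormalised so each row sums to one."""
    mu = growth_mean(grid.midpoints, d_t, d_next, delta_t, p)
    return _normal_transition(grid, mu, p.sigma_G)


def _normal_transition(grid: SizeGrid, mu: np.ndarray, sigma: float) -> Kernel:
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if sigma <= 0:
        # degenerate: all mass to the bin containing mu
        mat = np.zeros((mu.size, grid.m))
        mat[np.arange(mu.size), grid.locate(mu)] = 1.0
        return Kernel(grid, mat)
    edges = grid.edges
    z = (edges[None, :] - mu[:, None]) / sigma
    cdf = ndtr(z)
    mat = np.diff(cdf, axis=1)
    rs = mat.sum(axis=1, keepdims=True)
    if np.any(rs <= 0):
        raise FloatingPointError("growth kernel row with zero mass on grid")
    return Kernel(grid, mat / rs)


def natural_survival(x, delta_t: float, p: MortalityParams):
    """Non-winter survival over ``delta_t`` years:
    S(x) = exp(-delta_t * (beta + (alpha/x)^2)).

    Mortality decreases with size; x == 0 gets survival 0 (infinite-hazard
    limit) when alpha > 0.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        size_term = np.where(x > 0, (p.alpha / np.where(x > 0, x, 1.0)) ** 2, np.inf)
    if p.alpha == 0:
        size_term = np.zeros_like(x)
    out = np.exp(-delta_t * (p.beta + size_term))
    out = np.where((x <= 0) & (p.alpha > 0), 0.0, out)
    return out if out.ndim else float(out)


def projection_kernel(grid: SizeGrid, d_t: float, d_next: float, delta_t: float,
                      gp: GrowthParams, mp: MortalityParams) -> Kernel:
    """Full projection kernel: growth kernel scaled by natural survival of
    the source size, so row i sums to S(x_i)."""
    g = growth_kernel(grid, d_t, d_next, delta_t, gp)
    s = natural_survival(grid.midpoints, delta_t, mp)
    return Kernel(grid, g.matrix * np.asarray(s)[:, None])
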