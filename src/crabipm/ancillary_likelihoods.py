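"""Auxiliary-data likelihoods: size-at-age growth records and the
mark-recapture experiment that informs trap capture rates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kernels import GrowthParams, Kernel, MortalityParams, projection_kernel
from .observation import TrapParams, binom_logpmf, capture_probability
from .size_structure import DensityVector, SizeGrid

__all__ = [
    "SizeAtAgeData",
    "MarkRecaptureData",
    "size_at_age_loglik",
    "mc_project",
    "mc_occasion_kernels",
    "mc_recapture_loglik",
    "support_barrier",
]


def support_barrier(excess) -> np.ndarray:
    """Steep log-penalty for counts exceeding a continuous latent pool.

    ``excess`` is count - pool - 1 (one-crab rounding slack); positive
    values are effectively impossible (~ -1100 log-units per crab) but the
    penalty stays finite so optimisers and samplers can find their way back
    into the supported region.
    """
    v = np.clip(np.asarray(excess, dtype=float), 0.0, None)
    return -1e3 * v * v - 1e2 * v


@dataclass
class SizeAtAgeData:
    """Columnar size-at-age records."""

    crab_id: np.ndarray
    year: np.ndarray        # collection year (groups the random effect)
    age: np.ndarray         # fractional years
    width: np.ndarray       # carapace width (mm)

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year)
        self.age = np.asarray(self.age, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if np.any(self.width <= 0):
            raise ValueError("carapace widths must be positive")

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.year)


@dataclass
class MarkRecaptureData:
    """Mark-recapture occasion table.

    ``marked[t]`` crabs are marked and released at occasion t (the final
    occasion releases none); ``recaptured[t]`` are recaptured at occasion
    t >= 1.  ``times`` is the absolute year-fraction timeline (0 = April 1
    of the experiment year), so both occasion gaps and seasonal phase are
    derived from it.
    """

    times: np.ndarray              # (T+1,) increasing year fractions
    marked: np.ndarray             # (T+1, m)
    recaptured: np.ndarray         # (T+1, m); row 0 unused
    n_traps: np.ndarray            # (T+1,) Fukui traps fished per occasion
    soak_days: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.marked = np.asarray(self.marked, dtype=float)
        self.recaptured = np.asarray(self.recaptured, dtype=float)
        self.n_traps = np.asarray(self.n_traps, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("occasion times must be strictly increasing")
        if np.any(self.marked < 0) or np.any(self.recaptured < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_occasions(self) -> int:
        return self.times.shape[0]


def size_at_age_loglik(data: SizeAtAgeData, gp: GrowthParams,
                       year_effects: dict) -> float:
    """Log-likelihood of size-at-age records.

    Widths are log-normal around the seasonal growth curve, with a per-year
    location shift ``eps_u`` whose Normal(0, sigma_u) density is included.
    """
    import math
    import warnings

    from .kernels import size_at_age

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        w_tilde = np.asarray(size_at_age(data.age, gp), dtype=float)
    if np.any(w_tilde <= 0):
        return -np.inf
    eps = np.array([year_effects.get(u, 0.0) for u in data.year])
    logw = np.log(data.width)
    z = (logw - (np.log(w_tilde) + eps)) / gp.sigma_w
    log_2pi = math.log(2.0 * math.pi)
    ll = float(np.sum(-0.5 * z ** 2 - math.log(gp.sigma_w) - 0.5 * log_2pi
                      - logw))  # - log w: Jacobian of the log-normal
    for u in np.unique(data.year):
        e = year_effects.get(u, 0.0)
        ll += -0.5 * (e / gp.sigma_u) ** 2 - math.log(gp.sigma_u) \
            - 0.5 * log_2pi
    return ll


def mc_project(marked: DensityVector, K_mc: Kernel) -> DensityVector:
    """Propagate the marked pool one occasion forward through growth and
    natural survival."""
    return K_mc.apply(marked)


def mc_occasion_kernels(data: MarkRecaptureData, grid: SizeGrid,
                        gp: GrowthParams, mp: MortalityParams) -> list[Kernel]:
    """Projection kernels between consecutive occasions (length T)."""
    ks = []
    for t in range(data.n_occasions - 1):
        d_t, d_next = data.times[t], data.times[t + 1]
        ks.append(projection_kernel(grid, d_t, d_next, d_next - d_t, gp, mp))
    return ks


def mc_recapture_loglik(data: MarkRecaptureData, grid: SizeGrid,
                        gp: GrowthParams, mp: MortalityParams,
                        tp: TrapParams, kernels=None,
                        relax_trials: bool = False) -> float:
    """Binomial log-likelihood of recaptures given the projected marked pool
    and Fukui-trap capture probabilities.

    With ``relax_trials`` a one-crab rounding slack is allowed: the
    continuous pool projection can fall fractionally below a realised
    recapture count in sparse bins, so r <= pool + 1 is tolerated (trials
    clamped up to r); larger exceedances are impossible.  The strict form
    returns -inf whenever r exceeds the pool at all.
    """
    ks = kernels if kernels is not None else mc_occasion_kernels(data, grid, gp, mp)
    from .observation import hazard

    hz = np.asarray(hazard(grid.midpoints, "fukui", tp))
    pool = np.zeros(grid.m)
    ll = 0.0
    for t in range(data.n_occasions):
        if t > 0:
            r = data.recaptured[t]
            if relax_trials:
                ll += float(np.sum(support_barrier(r - pool - 1.0)))
                trials = np.maximum(pool, r)
            else:
                trials = pool
            # identical traps: exposure adds, so p = 1 - exp(-O * H * soak)
            p = -np.expm1(-data.n_traps[t] * hz * data.soak_days)
            ll += float(np.sum(binom_logpmf(r, trials, p)))
            if not np.isfinite(ll):
                return -np.inf
        if t < data.n_occasions - 1:
            pool = ks[t].matrix.T @ (pool + data.marked[t])
    return ll
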