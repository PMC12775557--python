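"""Latent process dynamics: within-season projection with removals, annual
recruitment pulses, and density- and size-dependent overwinter survival.

The season runs April-October on a biweekly clock: ``t = 1..t_max`` time
points at year fractions ``d_t = (t-1) * d_tmax / (t_max - 1)`` with
``d_1 = 0`` (April 1) and ``d_tmax = 0.53``.  The winter bridge covers the
remaining ``1 - d_tmax`` of the year, during which growth continues but
survival becomes density-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .kernels import Kernel, growth_kernel, projection_kernel
from .observation import sample_removals
from .params import OVERWINTER_FORMS, OverwinterParams, ParameterSet, RecruitInitParams
from .size_structure import DensityVector, SizeGrid, bin_density

__all__ = [
    "Season",
    "TrajectoryState",
    "step_within_season",
    "overwinter_survival_prob",
    "overwinter_transition",
    "initial_density",
    "recruit_density",
    "simulate_trajectory",
    "expected_trajectory",
    "season_kernels",
]

# survival is clamped below 1 so the overwinter binomial is always valid
_SURV_CAP = 1.0 - 1e-12


@dataclass(frozen=True)
class Season:
    """Within-year time discretisation."""

    t_max: int = 15      # observation time points per season
    t_R: int = 6         # recruit entry index
    d_tmax: float = 0.53  # year fraction at the last time point

    @property
    def dt_step(self) -> float:
        """Step length between consecutive time points (years)."""
        return self.d_tmax / (self.t_max - 1)

    @property
    def dt_winter(self) -> float:
        return 1.0 - self.d_tmax

    def d(self, t: int) -> float:
        """Year fraction of time point t (1-based)."""
        return (t - 1) * self.dt_step

    @property
    def year_fractions(self) -> np.ndarray:
        return np.arange(self.t_max) * self.dt_step


def season_kernels(grid: SizeGrid, season: Season, params: ParameterSet):
    """Within-season projection kernels (length t_max - 1) plus the
    overwinter growth-only kernel."""
    ks = [
        projection_kernel(grid, season.d(t), season.d(t + 1), season.dt_step,
                          params.growth, params.mortality)
        for t in range(1, season.t_max)
    ]
    g_o = growth_kernel(grid, season.d_tmax, 1.0, season.dt_winter, params.growth)
    return ks, g_o


@dataclass
class TrajectoryState:
    """Full latent trajectory of one simulation or one expectation pass.

    ``n[t-1, y, :]`` is the latent per-bin abundance at time point t of year
    y *before* that occasion's removals; ``removals`` holds the per-bin
    totals removed.
    """

    grid: SizeGrid
    season: Season
    n: np.ndarray                  # (t_max, n_years, m)
    removals: np.ndarray           # (t_max, n_years, m)
    m_tilde: np.ndarray            # (n_years - 1, m) post-growth pre-winter
    lambda_R: np.ndarray           # (n_years,)
    eps_y: np.ndarray              # (n_years - 1,)
    per_trap: dict = field(default_factory=dict)  # (y, t) -> (n_traps, m) counts

    @property
    def n_years(self) -> int:
        return self.n.shape[1]

    def totals(self) -> np.ndarray:
        """Total abundance across bins, shape (t_max, n_years)."""
        return self.n.sum(axis=2)


def step_within_season(state: DensityVector, removals: DensityVector,
                       K: Kernel, recruits: Optional[DensityVector] = None
                       ) -> DensityVector:
    """One biweekly projection: survivors of removal grow/survive through
    the kernel; a recruitment pulse is added when scheduled."""
    rem = removals.values
    if np.any(rem > state.values + 1e-9):
        raise ValueError("removals exceed latent abundance in some size bin")
    nxt = K.matrix.T @ np.clip(state.values - rem, 0.0, None)
    if recruits is not None:
        nxt = nxt + recruits.values
    return DensityVector(state.grid, nxt)


def overwinter_survival_prob(x, N_total: float, p: OverwinterParams,
                             eps: float, form: str = "density_size"):
    """Probability of surviving the winter for size ``x`` given pre-winter
    total abundance ``N_total`` (clamped to [0, 1))."""
    x = np.asarray(x, dtype=float)
    if form == "density_size":
        log_s = -p.alpha_o * N_total / x ** 2 + eps
    elif form == "size":
        log_s = -p.alpha_o / x ** 2 + eps
    elif form == "density":
        log_s = -p.alpha_o * N_total + eps
    elif form == "constant":
        log_s = -p.alpha_o + eps + np.zeros_like(x)
    else:
        raise ValueError(f"unknown overwinter form {form!r}; "
                         f"choose from {OVERWINTER_FORMS}")
    out = np.minimum(np.exp(np.minimum(log_s, 0.0)), _SURV_CAP)
    return out if out.ndim else float(out)


def overwinter_transition(state_end: DensityVector, removals_end: DensityVector,
                          G_o: Kernel, p: OverwinterParams, eps_y: float,
                          rng, form: str = "density_size",
                          n_total: Optional[float] = None):
    """Bridge from the last time point of year y to the first of year y+1.

    Growth first (deterministic flow, rounded to integer bins), then a
    per-bin binomial survival draw with density- and size-dependent
    probability. Returns ``(next_state, m_tilde)``.
    """
    if n_total is None:
        n_total = state_end.total
    m_tilde = np.round(
        G_o.matrix.T @ np.clip(state_end.values - removals_end.values, 0.0, None)
    )
    s = overwinter_survival_prob(state_end.grid.midpoints, n_total, p, eps_y, form)
    survivors = rng.binomial(m_tilde.astype(int), s)
    return DensityVector(state_end.grid, survivors.astype(float)), m_tilde


def _cdf_bin(cdf_at_edges: np.ndarray, total: float) -> np.ndarray:
    mass = np.clip(np.diff(cdf_at_edges), 0.0, None)
    z = mass.sum()
    if z <= 0:
        raise ValueError("density has zero mass on the size domain")
    return total * mass / z


def initial_density(p: RecruitInitParams, grid: SizeGrid) -> DensityVector:
    """Log-normal initial adult size distribution scaled to lambda_A."""
    from scipy.special import ndtr

    edges = grid.edges
    with np.errstate(divide="ignore"):
        cdf = np.where(edges > 0,
                       ndtr((np.log(np.maximum(edges, 1e-300)) - p.mu_A)
                            / p.sigma_A),
                       0.0)
    return DensityVector(grid, _cdf_bin(cdf, p.lambda_A))


def recruit_density(lambda_R: float, p: RecruitInitParams,
                    grid: SizeGrid) -> DensityVector:
    """Normal recruit size distribution (truncated to the grid) scaled to
    the annual pulse size ``lambda_R``."""
    from scipy.special import ndtr

    if lambda_R < 0:
        raise ValueError("lambda_R must be non-negative")
    if lambda_R == 0:
        return DensityVector(grid, np.zeros(grid.m))
    cdf = ndtr((grid.edges - p.mu_R) / p.sigma_R)
    return DensityVector(grid, _cdf_bin(cdf, lambda_R))


EffortSchedule = Callable[[int, int], list]
"""effort(year_index, t) -> list of (gear, soak_days) traps fished."""


def simulate_trajectory(params: ParameterSet, effort: Optional[EffortSchedule],
                        n_years: int, grid: SizeGrid, season: Season, rng,
                        overwinter_form: str = "density_size",
                        init_state: Optional[DensityVector] = None,
                        record_split: bool = True,
                        overwinter_stochastic: bool = True) -> TrajectoryState:
    """Stochastic forward simulation of the full latent + observation
    process.

    Recruit pulses are drawn log-normally unless ``params.recruit.lambda_R_y``
    is given; winter random effects come from ``params.overwinter.eps_y`` or
    Normal(0, sigma_o).  Removals (when ``effort`` yields traps) are sampled
    from the trapping observation model and subtracted from the latent state.
    """
    m = grid.m
    t_max = season.t_max
    rec = params.recruit
    if rec.lambda_R_y is not None:
        lam_R = np.asarray(rec.lambda_R_y, dtype=float)
        if lam_R.shape != (n_years,):
            raise ValueError("lambda_R_y must have one entry per year")
    else:
        lam_R = np.exp(rng.normal(rec.mu_lambda, rec.sigma_lambda, size=n_years))
    ow = params.overwinter
    if ow.eps_y is not None:
        eps = np.asarray(ow.eps_y, dtype=float)
        if eps.shape != (n_years - 1,):
            raise ValueError("eps_y must have one entry per winter")
    else:
        eps = rng.normal(0.0, ow.sigma_o, size=max(n_years - 1, 0))

    ks, g_o = season_kernels(grid, season, params)
    n_arr = np.zeros((t_max, n_years, m))
    c_arr = np.zeros((t_max, n_years, m))
    m_tilde = np.zeros((max(n_years - 1, 0), m))
    per_trap: dict = {}

    state = init_state.copy() if init_state is not None else initial_density(rec, grid)
    for y in range(n_years):
        recruits = recruit_density(lam_R[y], rec, grid)
        for t in range(1, t_max + 1):
            n_arr[t - 1, y] = state.values
            traps = effort(y, t) if effort is not None else []
            if traps:
                totals, split = sample_removals(state, traps, params.traps,
                                                rng, split=record_split)
                c_arr[t - 1, y] = totals
                if record_split:
                    per_trap[(y, t)] = split
            removals = DensityVector(grid, c_arr[t - 1, y])
            if t < t_max:
                state = step_within_season(
                    state, removals, ks[t - 1],
                    recruits if t == rec.t_R else None)
        if y < n_years - 1:
            if overwinter_stochastic:
                state, m_tilde[y] = overwinter_transition(
                    DensityVector(grid, n_arr[t_max - 1, y]),
                    DensityVector(grid, c_arr[t_max - 1, y]),
                    g_o, ow, eps[y], rng, form=overwinter_form)
            else:
                # expectation propagation: matches the marginal likelihood
                n_total = n_arr[t_max - 1, y].sum()
                m_tilde[y] = g_o.matrix.T @ np.clip(
                    n_arr[t_max - 1, y] - c_arr[t_max - 1, y], 0.0, None)
                s = overwinter_survival_prob(grid.midpoints, n_total, ow,
                                             eps[y], overwinter_form)
                state = DensityVector(grid, m_tilde[y] * s)
    return TrajectoryState(grid=grid, season=season, n=n_arr, removals=c_arr,
                           m_tilde=m_tilde, lambda_R=lam_R, eps_y=eps,
                           per_trap=per_trap)


def expected_trajectory(params: ParameterSet, lambda_R: np.ndarray,
                        eps_y: np.ndarray, removals: np.ndarray,
                        grid: SizeGrid, season: Season,
                        overwinter_form: str = "density_size",
                        kernels=None, winter_survivors=None,
                        return_winter: bool = False):
    """Deterministic latent trajectory given per-year latents and observed
    removals.

    By default the overwinter binomial is replaced by its expectation
    (marginal-approximation likelihood).  When ``winter_survivors`` (array
    (n_years - 1, m)) is given, those latent values start each new year
    instead.  With ``return_winter`` the post-growth pools and survival
    probabilities are returned too: ``(n_arr, m_tilde, s_winter)``.
    """
    t_max = season.t_max
    n_years = lambda_R.shape[0]
    ks, g_o = kernels if kernels is not None else season_kernels(grid, season, params)
    rec = params.recruit
    n_arr = np.empty((t_max, n_years, grid.m))
    m_tilde = np.zeros((max(n_years - 1, 0), grid.m))
    s_winter = np.zeros((max(n_years - 1, 0), grid.m))
    state = initial_density(rec, grid).values
    for y in range(n_years):
        recruits = recruit_density(lambda_R[y], rec, grid).values
        for t in range(1, t_max + 1):
            n_arr[t - 1, y] = state
            if t < t_max:
                state = ks[t - 1].matrix.T @ np.clip(
                    state - removals[t - 1, y], 0.0, None)
                if t == rec.t_R:
                    state = state + recruits
        if y < n_years - 1:
            n_total = n_arr[t_max - 1, y].sum()
            m_tilde[y] = g_o.matrix.T @ np.clip(
                n_arr[t_max - 1, y] - removals[t_max - 1, y], 0.0, None)
            s_winter[y] = overwinter_survival_prob(grid.midpoints, n_total,
                                                   params.overwinter, eps_y[y],
                                                   overwinter_form)
            if winter_survivors is not None:
                state = np.asarray(winter_survivors[y], dtype=float)
            else:
                state = m_tilde[y] * s_winter[y]
    if return_winter:
        return n_arr, m_tilde, s_winter
    return n_arr
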