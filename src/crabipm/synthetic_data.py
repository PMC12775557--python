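"""Generative emulation of the three dataset types from a known truth.

Everything flows through the same process/observation code paths used by
inference, so synthetic datasets are exact draws from the fitted model's
generative structure: a multi-year removal time series (d1), size-at-age
records (d2) and a mark-recapture occasion table (d3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .demography import Season, TrajectoryState, simulate_trajectory
from .kernels import GrowthParams, MortalityParams, size_at_age
from .observation import GEARS, RemovalRecord, TrapParams, capture_probability
from .ancillary_likelihoods import MarkRecaptureData, SizeAtAgeData
from .params import OverwinterParams, ParameterSet, RecruitInitParams
from .size_structure import SizeGrid, make_grid

__all__ = ["SyntheticTruth", "default_truth", "TrappingDesign",
           "generate_d1", "generate_d2", "generate_d3"]


def default_truth() -> ParameterSet:
    """Scenario-default parameter set.

    Values are chosen so simulated populations behave like an establishing
    harbour population under an active removal program (asymptotic size
    ~80 mm, summer growth peak at year fraction 0.25, recruit pulses
    spanning ~50-1400, initial adults ~440).  These are illustrative
    defaults for simulation studies, not estimates of any real system.
    """
    return ParameterSet(
        growth=GrowthParams(x_inf=80.7, k=0.9, A=0.9, d_s=0.25, sigma_G=2.8,
                            d_0=0.0, sigma_w=0.08, sigma_u=0.05),
        mortality=MortalityParams(beta=0.3, alpha=10.0),
        overwinter=OverwinterParams(alpha_o=1.8, sigma_o=0.3),
        traps=TrapParams(
            h_max={"fukui": 0.02, "shrimp": 0.06, "minnow": 0.02},
            h_k={"fukui": 0.40, "shrimp": 0.45},
            h_0={"fukui": 45.0, "shrimp": 42.0},
            h_A=45.0, h_sigma=60.0, rho=50.0),
        recruit=RecruitInitParams(mu_A=np.log(35.0), sigma_A=0.25,
                                  lambda_A=438.0, mu_R=5.4, sigma_R=2.0,
                                  mu_lambda=5.4, sigma_lambda=1.2,
                                  t_R=6),
    )


@dataclass(frozen=True)
class TrappingDesign:
    """Removal-survey layout for d1 generation."""

    n_years: int = 4
    traps_per_occasion: int = 20
    gear_mix: tuple = (("fukui", 0.5), ("shrimp", 0.3), ("minnow", 0.2))
    soak_days: float = 1.0
    occasions: Optional[tuple] = None  # time indices fished; default all

    def trap_list(self) -> list:
        traps = []
        for gear, fraction in self.gear_mix:
            if gear not in GEARS:
                raise ValueError(f"unknown gear {gear!r}")
            traps += [(gear, self.soak_days)] * int(round(
                fraction * self.traps_per_occasion))
        return traps


@dataclass
class SyntheticTruth:
    """Known generating state of a synthetic study."""

    params: ParameterSet
    seed: int
    grid: SizeGrid
    season: Season
    trajectory: Optional[TrajectoryState] = None
    eps_u: dict = field(default_factory=dict)
    overwinter_form: str = "density_size"


def generate_d1(params: ParameterSet, design: TrappingDesign, seed: int,
                grid: Optional[SizeGrid] = None,
                season: Optional[Season] = None,
                overwinter_form: str = "density_size",
                overwinter_stochastic: bool = True):
    """Simulate the removal time series.

    Returns ``(records, truth)`` where records is a list of
    :class:`RemovalRecord` (one per trap-occasion, zero-count traps
    included) and truth carries the full latent trajectory.
    """
    grid = grid if grid is not None else make_grid(0, 110, 5)
    season = season if season is not None else Season()
    rng = np.random.default_rng(seed)
    traps = design.trap_list()
    fished = set(design.occasions) if design.occasions is not None \
        else set(range(1, season.t_max + 1))

    def effort(year: int, t: int):
        return traps if t in fished else []

    traj = simulate_trajectory(params, effort, design.n_years, grid, season,
                               rng, overwinter_form=overwinter_form,
                               overwinter_stochastic=overwinter_stochastic)
    records = []
    for (y, t), split in sorted(traj.per_trap.items()):
        for j, (gear, soak) in enumerate(traps):
            records.append(RemovalRecord(year=y, t=t, trap_id=f"{gear}_{j}",
                                         gear=gear, soak_days=soak,
                                         counts=split[j]))
    truth = SyntheticTruth(params=params, seed=seed, grid=grid, season=season,
                           trajectory=traj, overwinter_form=overwinter_form)
    return records, truth


def generate_d2(params: ParameterSet, n_per_year: int, years, seed: int,
                age_range: tuple = (0.5, 4.0)) -> tuple:
    """Simulate size-at-age records: widths log-normal around the seasonal
    growth curve with a shared per-year random effect.

    Returns ``(SizeAtAgeData, eps_u dict)``.
    """
    gp = params.growth
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    if lo <= gp.d_0:
        raise ValueError("ages must exceed d_0")
    ids, yrs, ages, widths = [], [], [], []
    eps_u = {}
    for u in years:
        eps_u[u] = rng.normal(0.0, gp.sigma_u)
        a = rng.uniform(lo, hi, size=n_per_year)
        w_bar = np.asarray(size_at_age(a, gp))
        w = np.exp(rng.normal(np.log(w_bar) + eps_u[u], gp.sigma_w))
        ids += [f"{u}_{i}" for i in range(n_per_year)]
        yrs += [u] * n_per_year
        ages.append(a)
        widths.append(w)
    data = SizeAtAgeData(crab_id=np.array(ids), year=np.array(yrs),
                         age=np.concatenate(ages),
                         width=np.concatenate(widths))
    return data, eps_u


def generate_d3(params: ParameterSet, n_occasions: int, marked_per_occasion: int,
                n_traps: int, seed: int,
                grid: Optional[SizeGrid] = None,
                start_yearfrac: float = 0.3, gap_years: float = 0.04,
                soak_days: float = 1.0,
                marked_size: tuple = (45.0, 10.0)) -> MarkRecaptureData:
    """Simulate the mark-recapture experiment.

    Newly marked crabs (normal sizes around ``marked_size``) are released at
    occasions 0..T-1; the pool grows/survives between occasions and
    recaptures are binomial with Fukui-trap capture probability.
    """
    from .ancillary_likelihoods import mc_occasion_kernels

    grid = grid if grid is not None else make_grid(0, 110, 5)
    rng = np.random.default_rng(seed)
    times = start_yearfrac + gap_years * np.arange(n_occasions)
    marked = np.zeros((n_occasions, grid.m))
    recaptured = np.zeros((n_occasions, grid.m))
    mu, sd = marked_size
    for t in range(n_occasions - 1):
        sizes = rng.normal(mu, sd, size=marked_per_occasion)
        sizes = sizes[(sizes > grid.lower) & (sizes < grid.upper)]
        np.add.at(marked[t], grid.locate(sizes), 1)
    data = MarkRecaptureData(times=times, marked=marked, recaptured=recaptured,
                             n_traps=np.full(n_occasions, float(n_traps)),
                             soak_days=soak_days)
    ks = mc_occasion_kernels(data, grid, params.growth, params.mortality)
    pool = np.zeros(grid.m)
    traps = [("fukui", soak_days)] * n_traps
    p = np.atleast_1d(capture_probability(grid.midpoints, traps, params.traps))
    for t in range(n_occasions):
        if t > 0:
            # floor keeps recaptures <= the continuous pool the likelihood sees
            expected = np.clip(pool, 0.0, None)
            recaptured[t] = rng.binomial(np.floor(expected).astype(int), p)
        if t < n_occasions - 1:
            pool = ks[t].matrix.T @ (pool + marked[t])
    data.recaptured = recaptured
    return data
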