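"""Joint posterior over all three data sources, MCMC sampling, WAIC and
posterior predictive checks.

The sampler is a blocked adaptive random-walk Metropolis (Haario-style
covariance adaptation with Robbins-Monro scale tuning) on transformed
(unconstrained) parameters.  The latent yearly quantities -- recruit pulse
sizes, winter random effects and size-at-age year effects -- are sampled
alongside the structural parameters; the discrete overwinter binomial is
marginalised by expectation propagation by default (``latent_mode =
'approx'``) or sampled as integer latent vectors (``'exact'``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp

from .ancillary_likelihoods import (MarkRecaptureData, SizeAtAgeData,
                                    mc_recapture_loglik, size_at_age_loglik)
from .demography import (Season, expected_trajectory, overwinter_survival_prob,
                         season_kernels)
from .kernels import GrowthParams, MortalityParams
from .observation import (TrapParams, binom_logpmf, capture_probability,
                          conditional_trap_probs, dirichlet_multinomial_logpmf,
                          sample_removals)
from .params import OVERWINTER_FORMS, OverwinterParams, ParameterSet, RecruitInitParams
from .size_structure import DensityVector, SizeGrid, make_grid

__all__ = [
    "D1Data",
    "IntegratedModel",
    "PosteriorDraws",
    "run_mcmc",
    "compute_waic",
    "waic_model_selection",
    "posterior_predictive_check",
    "split_rhat",
    "effective_sample_size",
    "default_priors",
]


# --------------------------------------------------------------------------
# D1 container
# --------------------------------------------------------------------------

@dataclass
class D1Data:
    """Removal time series arranged for likelihood evaluation.

    ``totals[t-1, y]`` holds the per-bin removal totals; ``occasions`` maps
    (y, t) -> (trap list [(gear, soak)], per-trap count matrix (J, m)).
    """

    grid: SizeGrid
    n_years: int
    t_max: int
    totals: np.ndarray                  # (t_max, n_years, m)
    occasions: dict = field(default_factory=dict)
    _groups: Optional[list] = field(default=None, repr=False)

    def groups(self) -> list:
        """Occasions grouped by identical trap signature for vectorised
        likelihood evaluation: list of (traps, t_idx, y_idx, counts, totals)
        with counts (n_occ, J, m)."""
        if self._groups is None:
            by_sig: dict = {}
            for (y, t), (traps, counts) in sorted(self.occasions.items()):
                by_sig.setdefault(tuple(traps), []).append((y, t, counts))
            groups = []
            for sig, items in by_sig.items():
                y_idx = np.array([y for y, _, _ in items])
                t_idx = np.array([t for _, t, _ in items])
                counts = np.stack([cc for _, _, cc in items])
                groups.append((list(sig), t_idx, y_idx, counts,
                               counts.sum(axis=1)))
            self._groups = groups
        return self._groups

    @classmethod
    def from_records(cls, records, grid: SizeGrid, n_years: int, t_max: int
                     ) -> "D1Data":
        totals = np.zeros((t_max, n_years, grid.m))
        by_occ: dict = {}
        for r in records:
            by_occ.setdefault((r.year, r.t), []).append(r)
        occasions = {}
        for (y, t), recs in by_occ.items():
            if not (0 <= y < n_years and 1 <= t <= t_max):
                raise ValueError(f"record outside design: year={y}, t={t}")
            counts = np.stack([np.asarray(r.counts, dtype=float) for r in recs])
            totals[t - 1, y] = counts.sum(axis=0)
            occasions[(y, t)] = ([(r.gear, r.soak_days) for r in recs], counts)
        return cls(grid=grid, n_years=n_years, t_max=t_max, totals=totals,
                   occasions=occasions)


# --------------------------------------------------------------------------
# free-parameter bookkeeping
# --------------------------------------------------------------------------

_GROWTH_KEYS = ("x_inf", "k", "A", "d_s", "sigma_G", "d_0", "sigma_w", "sigma_u")
_MORT_KEYS = ("beta", "alpha")
_OW_KEYS = ("alpha_o", "sigma_o")
_TRAP_SCALARS = ("h_A", "h_sigma", "rho")
_RECRUIT_KEYS = ("mu_A", "sigma_A", "lambda_A", "mu_R", "sigma_R",
                 "mu_lambda", "sigma_lambda")


def default_priors() -> dict:
    """Weakly-informative default priors (natural scale), fully
    overridable via the run config."""
    halfnorm = stats.halfnorm
    return {
        "x_inf": stats.norm(75, 15),
        "k": stats.lognorm(s=0.7, scale=0.8),
        "A": stats.uniform(0, 1.5),
        "d_s": stats.uniform(0, 1),
        "sigma_G": halfnorm(scale=5),
        "d_0": stats.norm(0, 0.5),
        "sigma_w": halfnorm(scale=0.5),
        "sigma_u": halfnorm(scale=0.3),
        "beta": halfnorm(scale=1.0),
        "alpha": halfnorm(scale=20),
        # scale-free: alpha_o spans orders of magnitude across the
        # candidate overwinter formulations
        "alpha_o": stats.lognorm(s=4.0, scale=0.3),
        "sigma_o": halfnorm(scale=1),
        "h_max_fukui": halfnorm(scale=0.2),
        "h_max_shrimp": halfnorm(scale=0.2),
        "h_max_minnow": halfnorm(scale=0.2),
        "h_k_fukui": halfnorm(scale=1),
        "h_k_shrimp": halfnorm(scale=1),
        "h_0_fukui": stats.norm(45, 20),
        "h_0_shrimp": stats.norm(45, 20),
        "h_A": stats.norm(45, 20),
        "h_sigma": halfnorm(scale=500),
        "rho": stats.lognorm(s=1.0, scale=30),
        "mu_A": stats.norm(3.5, 1),
        "sigma_A": halfnorm(scale=1),
        "lambda_A": stats.lognorm(s=1.5, scale=300),
        "mu_R": stats.norm(5, 3),
        "sigma_R": halfnorm(scale=3),
        "mu_lambda": stats.norm(5.5, 2),
        "sigma_lambda": halfnorm(scale=2),
    }


_DEFAULT_INITS = {
    "x_inf": 70.0, "k": 0.8, "A": 0.7, "d_s": 0.3, "sigma_G": 3.0,
    "d_0": 0.05, "sigma_w": 0.12, "sigma_u": 0.1, "beta": 0.3, "alpha": 8.0,
    "alpha_o": 1.0, "sigma_o": 0.3, "h_max_fukui": 0.02, "h_max_shrimp": 0.05,
    "h_max_minnow": 0.02, "h_k_fukui": 0.25, "h_k_shrimp": 0.2,
    "h_0_fukui": 45.0, "h_0_shrimp": 42.0, "h_A": 45.0, "h_sigma": 150.0,
    "rho": 30.0, "mu_A": 3.5, "sigma_A": 0.3, "lambda_A": 400.0, "mu_R": 5.0,
    "sigma_R": 2.0, "mu_lambda": 5.5, "sigma_lambda": 1.0,
}

# transform per parameter: positive -> log; bounded -> (logit, lo, hi);
# unconstrained -> identity
_TRANSFORMS = {}
for _k in ("x_inf", "k", "sigma_G", "sigma_w", "sigma_u", "beta", "alpha",
           "alpha_o", "sigma_o", "h_max_fukui", "h_max_shrimp", "h_max_minnow",
           "h_k_fukui", "h_k_shrimp", "h_sigma", "rho", "sigma_A", "lambda_A",
           "sigma_R", "sigma_lambda"):
    _TRANSFORMS[_k] = ("log",)
_TRANSFORMS["A"] = ("logit", 0.0, 1.5)
_TRANSFORMS["d_s"] = ("logit", 0.0, 1.0)
for _k in ("d_0", "h_0_fukui", "h_0_shrimp", "h_A", "mu_A", "mu_R", "mu_lambda"):
    _TRANSFORMS[_k] = ("identity",)


_LOG_2PI = math.log(2.0 * math.pi)


def _fast_logpdf(frozen):
    """Closed-form logpdf for the common prior families (scipy frozen-dist
    call overhead dominates the posterior evaluation otherwise)."""
    try:
        name = frozen.dist.name
        shapes, loc, scale = frozen.dist._parse_args(*frozen.args, **frozen.kwds)
    except Exception:  # pragma: no cover - fallback for exotic priors
        return frozen.logpdf
    if name == "norm":
        def lp(x, loc=loc, scale=scale):
            return -0.5 * ((x - loc) / scale) ** 2 - math.log(scale) \
                - 0.5 * _LOG_2PI
        return lp
    if name == "halfnorm":
        c = 0.5 * math.log(2.0 / math.pi)
        def lp(x, loc=loc, scale=scale, c=c):
            if x < loc:
                return -math.inf
            return c - math.log(scale) - 0.5 * ((x - loc) / scale) ** 2
        return lp
    if name == "lognorm":
        s = shapes[0]
        def lp(x, s=s, loc=loc, scale=scale):
            y = (x - loc) / scale
            if y <= 0:
                return -math.inf
            ly = math.log(y)
            return (-math.log(s) - ly - math.log(scale) - 0.5 * _LOG_2PI
                    - ly * ly / (2.0 * s * s))
        return lp
    if name == "uniform":
        def lp(x, loc=loc, scale=scale):
            return -math.log(scale) if loc <= x <= loc + scale else -math.inf
        return lp
    return frozen.logpdf


def _to_unconstrained(name: str, x: float) -> float:
    tr = _TRANSFORMS.get(name, ("identity",))
    if tr[0] == "log":
        return math.log(x)
    if tr[0] == "logit":
        lo, hi = tr[1], tr[2]
        u = (x - lo) / (hi - lo)
        u = min(max(u, 1e-12), 1 - 1e-12)
        return math.log(u / (1 - u))
    return x


def _from_unconstrained(name: str, z: float):
    """Return (natural value, log |d nat / d z|)."""
    tr = _TRANSFORMS.get(name, ("identity",))
    if tr[0] == "log":
        return math.exp(z), z
    if tr[0] == "logit":
        lo, hi = tr[1], tr[2]
        s = expit(z)
        return lo + (hi - lo) * s, math.log(hi - lo) + math.log(s) + math.log1p(-s)
    return z, 0.0


# --------------------------------------------------------------------------
# the integrated model
# --------------------------------------------------------------------------

class IntegratedModel:
    """Joint log-posterior over D1 (removal series), D2 (size-at-age) and
    D3 (mark-recapture), with priors and latent process densities.

    Parameters not listed in ``sample`` stay fixed at their values in
    ``base_params``.
    """

    def __init__(self, base_params: ParameterSet,
                 d1: Optional[D1Data] = None,
                 d2: Optional[SizeAtAgeData] = None,
                 d3: Optional[MarkRecaptureData] = None,
                 grid: Optional[SizeGrid] = None,
                 season: Optional[Season] = None,
                 overwinter_form: str = "density_size",
                 priors: Optional[dict] = None,
                 sample: Optional[Sequence[str]] = None,
                 latent_mode: str = "approx"):
        if overwinter_form not in OVERWINTER_FORMS:
            raise ValueError(f"unknown overwinter form {overwinter_form!r}")
        if latent_mode not in ("approx", "exact"):
            raise ValueError("latent_mode must be 'approx' or 'exact'")
        self.base_params = base_params
        self.d1, self.d2, self.d3 = d1, d2, d3
        self.grid = grid if grid is not None else make_grid(0, 110, 5)
        self.season = season if season is not None else Season()
        self.overwinter_form = overwinter_form
        self.latent_mode = latent_mode
        self.priors = dict(default_priors())
        if priors:
            self.priors.update(priors)
        self._prior_fns = {nm: _fast_logpdf(d) for nm, d in self.priors.items()}
        self._kcache: dict = {}

        self.n_years = d1.n_years if d1 is not None else 0
        self.d2_years = list(d2.years) if d2 is not None else []

        names: list[str] = []
        if sample is None:
            sample = list(_DEFAULT_INITS)
        for nm in sample:
            if nm not in _DEFAULT_INITS:
                raise ValueError(f"unknown parameter {nm!r}")
            names.append(nm)
        # latent blocks (non-centred: standard-normal z-scores scaled by the
        # hyper-parameters, which decorrelates them from mu/sigma updates)
        for y in range(self.n_years):
            names.append(f"lambda_R_z_{y}")
            _TRANSFORMS.setdefault(f"lambda_R_z_{y}", ("identity",))
        for y in range(max(self.n_years - 1, 0)):
            names.append(f"eps_y_z_{y}")
            _TRANSFORMS.setdefault(f"eps_y_z_{y}", ("identity",))
        for u in self.d2_years:
            names.append(f"eps_u_{u}")
            _TRANSFORMS.setdefault(f"eps_u_{u}", ("identity",))
        if latent_mode == "exact" and d1 is not None:
            # per-winter survivor vectors as continuous latents with the
            # binomial density (continuous relaxation of the integer draw)
            for y in range(max(self.n_years - 1, 0)):
                for i in range(self.grid.m):
                    names.append(f"ow_{y}_{i}")
                    _TRANSFORMS.setdefault(f"ow_{y}_{i}", ("identity",))
        self.names = names
        self.dim = len(names)

    # -- parameter plumbing -------------------------------------------------

    def default_init(self) -> dict:
        """Data-free (plus crude data-scale) starting values."""
        init = {nm: _DEFAULT_INITS[nm] for nm in self.names if nm in _DEFAULT_INITS}
        if "alpha_o" in init:
            # survival-scale-preserving starts per overwinter form
            init["alpha_o"] = {"density_size": 1.0, "size": 30.0,
                               "density": 1e-3, "constant": 0.5}[
                                   self.overwinter_form]
        # scale abundance inits so observed removals are feasible
        mu_l = init.get("mu_lambda", self.base_params.recruit.mu_lambda)
        sd_l = init.get("sigma_lambda", self.base_params.recruit.sigma_lambda)
        if self.d1 is not None:
            per_year = self.d1.totals.sum(axis=(0, 2))
            init_lambda_A = max(400.0, 4.0 * per_year[0] if per_year.size else 0.0)
            if "lambda_A" in init:
                init["lambda_A"] = init_lambda_A
            for y in range(self.n_years):
                lam0 = max(300.0, 4.0 * per_year[y])
                init[f"lambda_R_z_{y}"] = (math.log(lam0) - mu_l) / sd_l
        else:
            for y in range(self.n_years):
                init[f"lambda_R_z_{y}"] = 0.0
        for y in range(max(self.n_years - 1, 0)):
            init[f"eps_y_z_{y}"] = 0.0
        for u in self.d2_years:
            init[f"eps_u_{u}"] = 0.0
        return init

    def init_vector(self, overrides: Optional[dict] = None) -> np.ndarray:
        vals = self.default_init()
        if overrides:
            overrides = dict(overrides)
            # accept natural-scale latent overrides; convert to z-scores
            mu_l = overrides.get("mu_lambda", vals.get(
                "mu_lambda", self.base_params.recruit.mu_lambda))
            sd_l = overrides.get("sigma_lambda", vals.get(
                "sigma_lambda", self.base_params.recruit.sigma_lambda))
            sd_o = overrides.get("sigma_o", vals.get(
                "sigma_o", self.base_params.overwinter.sigma_o))
            for y in range(self.n_years):
                if f"lambda_R_{y}" in overrides:
                    overrides[f"lambda_R_z_{y}"] = \
                        (math.log(overrides.pop(f"lambda_R_{y}")) - mu_l) / sd_l
            for y in range(max(self.n_years - 1, 0)):
                if f"eps_y_{y}" in overrides:
                    overrides[f"eps_y_z_{y}"] = \
                        overrides.pop(f"eps_y_{y}") / max(sd_o, 1e-12)
            vals.update({k: v for k, v in overrides.items() if k in set(self.names)})
        if self.d1 is not None:
            self._boost_to_feasibility(vals)
        if self.latent_mode == "exact" and self.d1 is not None:
            # start winter survivors at their expectation, padded by the
            # following year's observed removals so counts stay feasible
            params = self.build_params(vals)
            lam, eps_y, _, _ = self._latents(vals, params)
            _, m_tilde, s_w = expected_trajectory(
                params, lam, eps_y, self.d1.totals, self.grid, self.season,
                self.overwinter_form, return_winter=True)
            for y in range(max(self.n_years - 1, 0)):
                pad = self.d1.totals[:, y + 1, :].sum(axis=0)
                # keep clear of the w <= m_tilde boundary: perturbations of
                # upstream parameters move m_tilde; survival can underflow
                # to exactly 0 in small bins, where w must start at 0
                w0 = np.minimum(m_tilde[y] * s_w[y] + pad, 0.8 * m_tilde[y])
                w0 = np.where(s_w[y] > 0, w0, 0.0)
                for i in range(self.grid.m):
                    vals[f"ow_{y}_{i}"] = w0[i]
        return np.array([_to_unconstrained(nm, vals[nm]) for nm in self.names])

    def _boost_to_feasibility(self, vals: dict, max_rounds: int = 40) -> None:
        """Raise abundance-related starting values until the latent
        trajectory can support every observed removal count (the strict
        binomial support makes infeasible starts common otherwise)."""
        for _ in range(max_rounds):
            params = self.build_params(vals)
            lam, eps_y, _, _ = self._latents(vals, params)
            try:
                n_arr = self.latent_trajectory(params, lam, eps_y)
            except (ValueError, FloatingPointError):
                return
            viol = self.d1.totals.transpose(1, 0, 2) > \
                n_arr.transpose(1, 0, 2) + 0.99
            bad_years = np.unique(np.nonzero(viol)[0])
            if bad_years.size == 0:
                return
            for y in bad_years:
                if y == 0 and "lambda_A" in vals:
                    vals["lambda_A"] *= 1.4
                if f"lambda_R_z_{y}" in vals:
                    vals[f"lambda_R_z_{y}"] += 0.25
                if y > 0 and f"lambda_R_z_{y - 1}" in vals:
                    vals[f"lambda_R_z_{y - 1}"] += 0.25
                if y > 0 and f"eps_y_z_{y - 1}" in vals:
                    vals[f"eps_y_z_{y - 1}"] += 0.4

    def refeasible(self, z: np.ndarray) -> np.ndarray:
        """Re-apply the feasibility boost to an unconstrained vector
        (used between optimisation stages, which can strand the latent
        trajectory below an observed count).  Never returns a worse point:
        the boost is only kept when it raises the log-posterior."""
        if self.d1 is None:
            return z
        nat, _ = self._unpack(z)
        self._boost_to_feasibility(nat)
        z_new = np.array([_to_unconstrained(nm, nat[nm]) for nm in self.names])
        lp_old, lp_new = self.logpost(z), self.logpost(z_new)
        if np.isfinite(lp_new) and (not np.isfinite(lp_old) or lp_new > lp_old):
            return z_new
        return z

    def _unpack(self, z: np.ndarray):
        """Unconstrained vector -> (natural dict, log-jacobian)."""
        nat = {}
        logjac = 0.0
        for nm, zi in zip(self.names, z):
            v, lj = _from_unconstrained(nm, zi)
            nat[nm] = v
            logjac += lj
        return nat, logjac

    def build_params(self, nat: dict) -> ParameterSet:
        b = self.base_params
        g = replace(b.growth, **{k: nat[k] for k in _GROWTH_KEYS if k in nat})
        m = replace(b.mortality, **{k: nat[k] for k in _MORT_KEYS if k in nat})
        ow = replace(b.overwinter, **{k: nat[k] for k in _OW_KEYS if k in nat})
        h_max = dict(b.traps.h_max)
        h_k = dict(b.traps.h_k)
        h_0 = dict(b.traps.h_0)
        for gname in ("fukui", "shrimp", "minnow"):
            if f"h_max_{gname}" in nat:
                h_max[gname] = nat[f"h_max_{gname}"]
        for gname in ("fukui", "shrimp"):
            if f"h_k_{gname}" in nat:
                h_k[gname] = nat[f"h_k_{gname}"]
            if f"h_0_{gname}" in nat:
                h_0[gname] = nat[f"h_0_{gname}"]
        tp = TrapParams(h_max=h_max, h_k=h_k, h_0=h_0,
                        h_A=nat.get("h_A", b.traps.h_A),
                        h_sigma=nat.get("h_sigma", b.traps.h_sigma),
                        rho=nat.get("rho", b.traps.rho))
        rc = replace(b.recruit, **{k: nat[k] for k in _RECRUIT_KEYS if k in nat})
        return ParameterSet(growth=g, mortality=m, overwinter=ow, traps=tp,
                            recruit=rc)

    def _latents(self, nat: dict, params: ParameterSet):
        """Materialise the non-centred yearly latents on their natural
        scale: lambda_R = exp(mu_lambda + sigma_lambda z), eps = sigma_o z."""
        rc, ow = params.recruit, params.overwinter
        lam = np.exp(rc.mu_lambda + rc.sigma_lambda * np.array(
            [nat.get(f"lambda_R_z_{y}", 0.0) for y in range(self.n_years)]))
        eps_y = ow.sigma_o * np.array(
            [nat.get(f"eps_y_z_{y}", 0.0)
             for y in range(max(self.n_years - 1, 0))])
        eps_u = {u: nat.get(f"eps_u_{u}", 0.0) for u in self.d2_years}
        w = None
        if self.latent_mode == "exact" and self.d1 is not None:
            w = np.array([[nat.get(f"ow_{y}_{i}", 0.0)
                           for i in range(self.grid.m)]
                          for y in range(max(self.n_years - 1, 0))])
        return lam, eps_y, eps_u, w

    def derived(self, nat: dict, params: ParameterSet) -> dict:
        """Natural-scale values of the non-centred latents, for reporting."""
        lam, eps_y, _, _ = self._latents(nat, params)
        out = {f"lambda_R_{y}": lam[y] for y in range(self.n_years)}
        out.update({f"eps_y_{y}": eps_y[y]
                    for y in range(max(self.n_years - 1, 0))})
        return out

    @property
    def report_names(self) -> list:
        return list(self.names) + [f"lambda_R_{y}" for y in range(self.n_years)] \
            + [f"eps_y_{y}" for y in range(max(self.n_years - 1, 0))]

    # -- likelihood components ----------------------------------------------

    def _season_kernels(self, params: ParameterSet):
        """Season/winter projection kernels, caching the growth part on the
        growth parameters; the (cheap) survival scaling is applied fresh so
        mortality updates do not force a rebuild."""
        from .kernels import Kernel, growth_kernel, natural_survival

        g, mt = params.growth, params.mortality
        gkey = (g.x_inf, g.k, g.A, g.d_s, g.sigma_G)
        hit = self._kcache.get("season_growth")
        if hit is None or hit[0] != gkey:
            season = self.season
            gks = [growth_kernel(self.grid, season.d(t), season.d(t + 1),
                                 season.dt_step, g).matrix
                   for t in range(1, season.t_max)]
            g_o = growth_kernel(self.grid, season.d_tmax, 1.0,
                                season.dt_winter, g)
            hit = (gkey, gks, g_o)
            self._kcache["season_growth"] = hit
        _, gks, g_o = hit
        s = np.asarray(natural_survival(self.grid.midpoints,
                                        self.season.dt_step, mt))
        ks = [Kernel(self.grid, gm * s[:, None]) for gm in gks]
        return ks, g_o

    def _mc_kernels(self, params: ParameterSet):
        from .kernels import Kernel, growth_kernel, natural_survival

        g, mt = params.growth, params.mortality
        gkey = (g.x_inf, g.k, g.A, g.d_s, g.sigma_G)
        hit = self._kcache.get("mc_growth")
        if hit is None or hit[0] != gkey:
            times = self.d3.times
            gks = [growth_kernel(self.grid, times[t], times[t + 1],
                                 times[t + 1] - times[t], g).matrix
                   for t in range(self.d3.n_occasions - 1)]
            hit = (gkey, gks)
            self._kcache["mc_growth"] = hit
        _, gks = hit
        times = self.d3.times
        out = []
        for t, gm in enumerate(gks):
            s = np.asarray(natural_survival(self.grid.midpoints,
                                            times[t + 1] - times[t], mt))
            out.append(Kernel(self.grid, gm * s[:, None]))
        return out

    def latent_trajectory(self, params: ParameterSet, lam: np.ndarray,
                          eps_y: np.ndarray, w=None) -> np.ndarray:
        return expected_trajectory(params, lam, eps_y, self.d1.totals,
                                   self.grid, self.season,
                                   self.overwinter_form, winter_survivors=w,
                                   kernels=self._season_kernels(params))

    def winter_latent_logdensity(self, params: ParameterSet, lam: np.ndarray,
                                 eps_y: np.ndarray, w: np.ndarray) -> float:
        """Continuous-binomial density of the latent winter survivors."""
        _, m_tilde, s_w = expected_trajectory(
            params, lam, eps_y, self.d1.totals, self.grid, self.season,
            self.overwinter_form, winter_survivors=w, return_winter=True,
            kernels=self._season_kernels(params))
        return float(np.sum(binom_logpmf(w, m_tilde, s_w)))

    def d1_loglik(self, params: ParameterSet, lam: np.ndarray,
                  eps_y: np.ndarray, pointwise: bool = False, w=None):
        """Removal-series log-likelihood (or pointwise per-cell vector).

        The binomial trial count is the latent abundance; because the
        marginalised latent is continuous while counts are integers, a
        one-crab rounding slack is allowed (count <= latent + 1, with
        trials clamped up to the count).  Beyond that the observation is
        impossible (-inf).
        """
        n_arr = self.latent_trajectory(params, lam, eps_y, w=w)
        x = self.grid.midpoints
        cells = [] if pointwise else None
        total = 0.0
        from .ancillary_likelihoods import support_barrier
        tp = params.traps
        # capture probabilities and the trap-split term depend only on the
        # trap parameters, so cache them across latent/abundance updates
        tkey = (tuple(sorted(tp.h_max.items())), tuple(sorted(tp.h_k.items())),
                tuple(sorted(tp.h_0.items())), tp.h_A, tp.h_sigma, tp.rho)
        for gi, (traps, t_idx, y_idx, counts, totals) in \
                enumerate(self.d1.groups()):
            latent = n_arr[t_idx - 1, y_idx]            # (n_occ, m)
            barrier = support_barrier(totals - latent - 1.0)
            trials = np.maximum(latent, totals)
            hit = self._kcache.get(("d1obs", gi))
            if hit is None or hit[0] != tkey:
                pcap = np.atleast_1d(capture_probability(x, traps, tp))
                if len(traps) > 1:
                    import warnings as _w
                    with _w.catch_warnings():
                        _w.simplefilter("ignore", RuntimeWarning)
                        pc = conditional_trap_probs(x, traps, tp)
                    # category axis first: (J, n_occ, m)
                    dm = dirichlet_multinomial_logpmf(
                        counts.transpose(1, 0, 2), tp.rho * pc[:, None, :])
                else:
                    dm = 0.0
                hit = (tkey, pcap, dm)
                self._kcache[("d1obs", gi)] = hit
            _, pcap, dm = hit
            cell = binom_logpmf(totals, trials, pcap[None, :]) + dm + barrier
            if pointwise:
                cells.append(cell.reshape(-1))
            else:
                total += float(cell.sum())
                if not np.isfinite(total):
                    return -np.inf
        if pointwise:
            return np.concatenate(cells) if cells else np.zeros(0)
        return total

    def process_logdensity(self, nat: dict) -> float:
        """Standard-normal density of the non-centred latent z-scores."""
        lp = 0.0
        for y in range(self.n_years):
            z = nat.get(f"lambda_R_z_{y}", 0.0)
            lp += -0.5 * z * z - 0.5 * _LOG_2PI
        for y in range(max(self.n_years - 1, 0)):
            z = nat.get(f"eps_y_z_{y}", 0.0)
            lp += -0.5 * z * z - 0.5 * _LOG_2PI
        return lp

    def log_prior(self, nat: dict) -> float:
        lp = 0.0
        for nm, v in nat.items():
            fn = self._prior_fns.get(nm)
            if fn is not None:
                lp += float(fn(v))
        return lp

    def logpost(self, z: np.ndarray) -> float:
        try:
            nat, logjac = self._unpack(z)
        except (OverflowError, ValueError):
            return -np.inf
        params = self.build_params(nat)
        lam, eps_y, eps_u, w = self._latents(nat, params)
        lp = self.log_prior(nat) + logjac
        if not np.isfinite(lp):
            return -np.inf
        lp += self.process_logdensity(nat)
        try:
            if self.d1 is not None:
                if w is not None:
                    lp += self.winter_latent_logdensity(params, lam, eps_y, w)
                    if not np.isfinite(lp):
                        return -np.inf
                lp += self.d1_loglik(params, lam, eps_y, w=w)
                if not np.isfinite(lp):
                    return -np.inf
            if self.d2 is not None:
                lp += size_at_age_loglik(self.d2, params.growth, eps_u)
            if self.d3 is not None:
                lp += mc_recapture_loglik(self.d3, self.grid, params.growth,
                                          params.mortality, params.traps,
                                          kernels=self._mc_kernels(params),
                                          relax_trials=True)
        except (ValueError, FloatingPointError, OverflowError):
            # domain failure (e.g. recruit density pushed off the grid or a
            # degenerate kernel row): impossible parameter region
            return -np.inf
        if np.isnan(lp):
            return -np.inf
        return float(lp)

    # -- convenience --------------------------------------------------------

    def params_at(self, nat: dict) -> ParameterSet:
        return self.build_params(nat)

    def default_blocks(self) -> list[np.ndarray]:
        """Index blocks for the blocked sampler: growth-ish, observation,
        overwinter, abundance."""
        groups = {
            "growth": set(_GROWTH_KEYS) | {f"eps_u_{u}" for u in self.d2_years},
            "obs": set(_MORT_KEYS) | {nm for nm in self.names if nm.startswith("h_")}
                   | {"rho"},
            "winter": set(_OW_KEYS) | {nm for nm in self.names
                                       if nm.startswith("eps_y_")},
            "abund": set(_RECRUIT_KEYS) | {nm for nm in self.names
                                           if nm.startswith("lambda_R_")},
        }
        blocks = []
        assigned = set()
        for g in ("growth", "obs", "winter", "abund"):
            idx = [i for i, nm in enumerate(self.names) if nm in groups[g]]
            if idx:
                blocks.append(np.array(idx))
                assigned |= {self.names[i] for i in idx}
        # extra overlapping block along the mortality/abundance ridge:
        # natural mortality trades off against recruitment and initial
        # abundance, so joint proposals are needed to move along it
        ridge = {"beta", "alpha", "lambda_A", "mu_lambda", "alpha_o"} \
            | {nm for nm in self.names if nm.startswith("lambda_R_z_")}
        idx = [i for i, nm in enumerate(self.names) if nm in ridge]
        if len(idx) > 1:
            blocks.append(np.array(idx))
        # one block per winter's survivor latents (exact mode)
        for y in range(max(self.n_years - 1, 0)):
            idx = [i for i, nm in enumerate(self.names)
                   if nm.startswith(f"ow_{y}_")]
            if idx:
                blocks.append(np.array(idx))
                assigned |= {self.names[i] for i in idx}
        rest = [i for i, nm in enumerate(self.names) if nm not in assigned]
        if rest:
            blocks.append(np.array(rest))
        return blocks


# --------------------------------------------------------------------------
# MCMC
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Thinned posterior draws on the natural scale."""

    names: list
    array: np.ndarray      # (n_chains, n_draws, dim)
    logpost: np.ndarray    # (n_chains, n_draws)
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.array[:, :, self.names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def stacked(self) -> np.ndarray:
        return self.array.reshape(-1, self.array.shape[2])

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, nm in enumerate(self.names):
            x = self.array[:, :, j]
            flat = x.reshape(-1)
            rows.append({
                "parameter": nm,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": np.quantile(flat, 0.025),
                "q50": np.quantile(flat, 0.5),
                "q97.5": np.quantile(flat, 0.975),
                "rhat": split_rhat(x),
                "ess": effective_sample_size(x),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def to_long_dataframe(self) -> pd.DataFrame:
        nc, nd, _ = self.array.shape
        frames = []
        for j, nm in enumerate(self.names):
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(nc), nd),
                "draw": np.tile(np.arange(nd), nc),
                "parameter": nm,
                "value": self.array[:, :, j].reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_long_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        names = list(df["parameter"].unique())
        nc = df["chain"].nunique()
        nd = df["draw"].nunique()
        arr = np.empty((nc, nd, len(names)))
        for j, nm in enumerate(names):
            sub = df[df["parameter"] == nm].sort_values(["chain", "draw"])
            arr[:, :, j] = sub["value"].to_numpy().reshape(nc, nd)
        return cls(names=names, array=arr,
                   logpost=np.zeros((nc, nd)))


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (standard definition)."""
    x = np.asarray(x, dtype=float)
    nc, nd = x.shape
    half = nd // 2
    if half < 2:
        return np.nan
    chains = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    if w <= 0:
        return 1.0
    return float(np.sqrt(var_hat / w))


def effective_sample_size(x: np.ndarray) -> float:
    """Bulk ESS via Geyer's initial monotone positive sequence, summed
    autocorrelations averaged over chains."""
    x = np.asarray(x, dtype=float)
    nc, nd = x.shape
    if nd < 4:
        return float(nc * nd)
    acov = np.zeros(nd)
    for c in range(nc):
        xc = x[c] - x[c].mean()
        f = np.fft.rfft(np.concatenate([xc, np.zeros(nd)]))
        ac = np.fft.irfft(f * np.conj(f))[:nd].real / nd
        acov += ac / nc
    if acov[0] <= 0:
        return float(nc * nd)
    rho = acov / acov[0]
    # Geyer: sum pairs until a pair sum goes non-positive, enforce monotone
    tau = 1.0
    prev = np.inf
    for k in range(1, nd // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += 2 * pair
    return float(nc * nd / max(tau, 1e-12))


def _block_ascent(model: IntegratedModel, z: np.ndarray, blocks,
                  maxiter_per_block: int, use=None) -> np.ndarray:
    from scipy.optimize import minimize

    saved = (model.d1, model.d2, model.d3)
    try:
        if use is not None:
            model.d1 = saved[0] if "d1" in use else None
            model.d2 = saved[1] if "d2" in use else None
            model.d3 = saved[2] if "d3" in use else None
        for b in blocks:
            def neg(zb, b=b):
                zz = z.copy()
                zz[b] = zb
                lp = model.logpost(zz)
                return -lp if np.isfinite(lp) else 1e12

            base = model.logpost(z)
            res = minimize(neg, z[b], method="Nelder-Mead",
                           options={"maxiter": maxiter_per_block,
                                    "xatol": 1e-3, "fatol": 1e-3})
            # never accept the infeasibility sentinel (1e12)
            if np.isfinite(res.fun) and res.fun < 5e11 \
                    and -res.fun >= base - 1e-9:
                z[b] = res.x
    finally:
        model.d1, model.d2, model.d3 = saved
    return z


def _d2_growth_mle(model: IntegratedModel, z: np.ndarray) -> np.ndarray:
    """Multi-start maximum-likelihood fit of the growth curve to the
    size-at-age data alone.

    The growth curve is the one sub-problem with a clean, smooth likelihood
    and a known phase-shifted local optimum; pinning it first keeps the
    joint optimisation out of the wrong seasonal basin.
    """
    from scipy.optimize import minimize

    from .ancillary_likelihoods import size_at_age_loglik

    free = [nm for nm in ("x_inf", "k", "A", "d_s", "d_0", "sigma_w")
            if nm in model.names]
    if not free or model.d2 is None:
        return z
    nat0, _ = model._unpack(z)
    years = list(model.d2.years)

    def nll(theta):
        nat = dict(nat0)
        nat.update(zip(free, theta))
        if not (5.0 < nat.get("x_inf", 80.0) < 300.0
                and 0.0 <= nat.get("d_s", 0.2) < 1.0
                and 0.0 < nat.get("A", 0.5) < 1.5
                and nat.get("k", 0.5) > 0.01
                and nat.get("sigma_w", 0.1) > 1e-4):
            return 1e12
        gp = model.build_params(nat).growth
        ll = size_at_age_loglik(model.d2, gp, {u: 0.0 for u in years})
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for ds0 in (0.1, 0.3, 0.5, 0.7, 0.9):
        for x0 in (60.0, 85.0):
            start = [dict(nat0, d_s=ds0, x_inf=x0, k=0.8, A=0.7,
                          d_0=0.0)[nm] for nm in free]
            res = minimize(nll, start, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-4,
                                    "fatol": 1e-6})
            if best is None or res.fun < best.fun:
                best = res
    if best is not None and best.fun < 1e11:
        nat = dict(nat0)
        nat.update(zip(free, best.x))
        z = z.copy()
        for nm in free:
            z[model.names.index(nm)] = _to_unconstrained(nm, nat[nm])
    return z


def optimize_start(model: IntegratedModel, z0: np.ndarray,
                   blocks: Optional[list] = None, sweeps: int = 2,
                   maxiter_per_block: int = 400) -> np.ndarray:
    """Blockwise Nelder-Mead ascent of the log-posterior to seed chains
    near the mode (derivative-free: the posterior has hard cliffs).

    Stages fight the mortality/capture/abundance ridge: growth parameters
    are first fit against the size-at-age data alone, observation and
    mortality against the mark-recapture data, abundance against the
    removal series; joint sweeps then polish.
    """
    if blocks is None:
        blocks = model.default_blocks()

    def stage_block(names_wanted) -> list:
        idx = [i for i, nm in enumerate(model.names) if nm in names_wanted
               or nm.startswith(tuple(p for p in names_wanted
                                      if p.endswith("_")))]
        return [np.array(idx)] if idx else []

    # each stage only moves parameters its dataset actually informs,
    # otherwise uninformed coordinates drift to their prior modes
    d2_names = {"x_inf", "k", "A", "d_s", "d_0", "sigma_w", "sigma_u",
                "eps_u_"}
    obs_names = {"sigma_G", "beta", "alpha", "rho", "h_"}
    abund_names = {"alpha_o", "sigma_o", "lambda_R_z_", "eps_y_z_",
                   "ow_"} | set(_RECRUIT_KEYS)
    # every stage is judged on the FULL posterior (masked objectives can
    # diverge); stages only control which coordinates move
    z = z0.copy()
    if model.d2 is not None:
        z = _d2_growth_mle(model, z)
        z = model.refeasible(z)
    if model.d3 is not None or model.d1 is not None:
        z = _block_ascent(model, z, stage_block(obs_names), maxiter_per_block)
        z = model.refeasible(z)
    if model.d1 is not None:
        z = _block_ascent(model, z, stage_block(abund_names),
                          maxiter_per_block)
    # joint sweeps hold the d2-fitted growth curve fixed: with abundance
    # still off, the full posterior absorbs removal-series misfit by
    # inflating sigma_w and shifting the seasonal phase, stranding the
    # search in the wrong basin (the sampler refines growth afterwards)
    pinned = {"x_inf", "k", "A", "d_s", "d_0", "sigma_w"} \
        if model.d2 is not None else set()
    sweep_blocks = []
    for b in blocks:
        keep = np.array([i for i in b if model.names[i] not in pinned])
        if keep.size:
            sweep_blocks.append(keep)
    for _ in range(sweeps):
        z = _block_ascent(model, z, sweep_blocks, maxiter_per_block)
        z = model.refeasible(z)
    return z


def run_mcmc(model: IntegratedModel, n_iter: int = 4000, n_chains: int = 4,
             burn: Optional[int] = None, thin: int = 1, seed: int = 0,
             init: Optional[dict] = None, blocks: Optional[list] = None,
             target_accept: float = 0.234, optimize_init: bool = True,
             init_jitter: float = 0.15, progress: bool = False
             ) -> PosteriorDraws:
    """Blocked adaptive random-walk Metropolis.

    Returns thinned post-burn-in draws on the natural scale; two runs with
    identical seeds produce identical draws.  With ``optimize_init`` the
    shared starting point is first pushed towards the posterior mode by a
    derivative-free blockwise search; each chain then starts from a
    jittered copy.
    """
    if burn is None:
        burn = n_iter // 2
    if blocks is None:
        blocks = model.default_blocks()
    dim = model.dim
    n_kept = (n_iter - burn) // thin
    if n_kept < 1:
        raise ValueError("n_iter, burn and thin leave no draws")
    report_names = model.report_names
    out = np.empty((n_chains, n_kept, len(report_names)))
    out_lp = np.empty((n_chains, n_kept))

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(n_chains)
    z_start = model.init_vector(init)
    if optimize_init:
        z_start = optimize_start(model, z_start, blocks=blocks)
    # winter-survivor latents sit near a hard support boundary: no jitter
    jitter_mask = np.array([0.0 if nm.startswith("ow_") else 1.0
                            for nm in model.names])
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        z = z_start + jitter_mask * rng.normal(0, init_jitter, size=dim) \
            if optimize_init else z_start.copy()
        z = model.refeasible(z)
        # jitter until finite
        lp = model.logpost(z)
        tries = 0
        while not np.isfinite(lp) and tries < 200:
            z_try = model.refeasible(
                z + jitter_mask * rng.normal(0, 0.1 * 0.95 ** tries,
                                             size=dim))
            lp_try = model.logpost(z_try)
            if np.isfinite(lp_try):
                z, lp = z_try, lp_try
                break
            tries += 1
        if not np.isfinite(lp):
            raise RuntimeError(
                "could not find a finite starting point; check data/config "
                "consistency (e.g. removals exceeding plausible abundance)")

        # per-block adaptation state
        b_state = []
        for b in blocks:
            d = len(b)
            b_state.append({
                "mean": z[b].copy(),
                "cov": np.eye(d) * 0.01,
                "chol": np.linalg.cholesky(np.eye(d) * 0.01),
                "log_scale": math.log(2.38 ** 2 / d),
                "stale": 0,
            })

        kept = 0
        for it in range(n_iter):
            gamma = (it + 1) ** -0.6
            for b, st in zip(blocks, b_state):
                d = len(b)
                step = math.exp(0.5 * st["log_scale"])
                prop = z.copy()
                prop[b] = z[b] + step * (st["chol"] @ rng.standard_normal(d))
                lp_prop = model.logpost(prop)
                log_alpha = lp_prop - lp
                acc = math.log(rng.random()) < log_alpha if np.isfinite(lp_prop) \
                    else False
                if acc:
                    z, lp = prop, lp_prop
                # Robbins-Monro scale adaptation
                a_prob = min(1.0, math.exp(min(log_alpha, 0.0))) \
                    if np.isfinite(log_alpha) else 0.0
                st["log_scale"] += gamma * (a_prob - target_accept)
                # covariance adaptation
                delta = z[b] - st["mean"]
                st["mean"] += gamma * delta
                st["cov"] += gamma * (np.outer(delta, delta) - st["cov"])
                st["stale"] += 1
                if st["stale"] >= 100:
                    try:
                        st["chol"] = np.linalg.cholesky(
                            st["cov"] + 1e-9 * np.eye(d))
                        st["stale"] = 0
                    except np.linalg.LinAlgError:
                        st["stale"] = 0
            if it >= burn and (it - burn) % thin == 0 and kept < n_kept:
                nat, _ = model._unpack(z)
                der = model.derived(nat, model.build_params(nat))
                nat.update(der)
                out[c, kept] = [nat[nm] for nm in report_names]
                out_lp[c, kept] = lp
                kept += 1
    return PosteriorDraws(names=list(report_names), array=out, logpost=out_lp,
                          seed=seed,
                          meta={"n_iter": n_iter, "burn": burn, "thin": thin,
                                "n_chains": n_chains,
                                "overwinter_form": model.overwinter_form})


# --------------------------------------------------------------------------
# WAIC and posterior predictive checks
# --------------------------------------------------------------------------

def _pointwise_matrix(draws: PosteriorDraws, model: IntegratedModel,
                      max_draws: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    flat = draws.stacked()
    lp_idx = np.arange(flat.shape[0])
    if max_draws is not None and flat.shape[0] > max_draws:
        rng = rng or np.random.default_rng(0)
        lp_idx = rng.choice(flat.shape[0], size=max_draws, replace=False)
    rows = []
    for i in lp_idx:
        nat = dict(zip(draws.names, flat[i]))
        params = model.build_params(nat)
        lam, eps_y, _, w = model._latents(nat, params)
        rows.append(model.d1_loglik(params, lam, eps_y, pointwise=True, w=w))
    return np.stack(rows)


def compute_waic(draws: PosteriorDraws, model: IntegratedModel,
                 max_draws: Optional[int] = 1000,
                 rng: Optional[np.random.Generator] = None) -> dict:
    """WAIC over the D1 observation cells (lower is better).

    Returns ``{"waic", "lppd", "p_waic", "n_cells"}``.
    """
    ll = _pointwise_matrix(draws, model, max_draws=max_draws, rng=rng)
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(s)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return {"waic": -2.0 * (lppd - p_waic), "lppd": lppd, "p_waic": p_waic,
            "n_cells": ll.shape[1]}


def waic_model_selection(make_model: Callable[[str], IntegratedModel],
                         forms: Sequence[str] = OVERWINTER_FORMS,
                         mcmc_kwargs: Optional[dict] = None,
                         max_draws: Optional[int] = 500) -> pd.DataFrame:
    """Fit one model per overwinter form and rank them by WAIC."""
    mcmc_kwargs = dict(mcmc_kwargs or {})
    rows = []
    for form in forms:
        model = make_model(form)
        draws = run_mcmc(model, **mcmc_kwargs)
        w = compute_waic(draws, model, max_draws=max_draws)
        rows.append({"form": form, **w})
    df = pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
    return df


def posterior_predictive_check(draws: PosteriorDraws, model: IntegratedModel,
                               discrepancy: str = "deviance",
                               max_draws: int = 400,
                               seed: int = 0) -> dict:
    """Bayesian p-value Pr(T(rep) >= T(obs)) for a discrepancy function.

    Replicate datasets are generated from the observation model conditional
    on each draw's latent trajectory.  ``discrepancy`` is ``"deviance"``
    (omnibus: -2 x removal log-likelihood) or ``"prop_zero"`` (fraction of
    zero per-trap count cells).
    """
    if discrepancy not in ("deviance", "prop_zero"):
        raise ValueError("discrepancy must be 'deviance' or 'prop_zero'")
    rng = np.random.default_rng(seed)
    flat = draws.stacked()
    idx = np.arange(flat.shape[0])
    if flat.shape[0] > max_draws:
        idx = rng.choice(flat.shape[0], size=max_draws, replace=False)
    grid = model.grid
    x = grid.midpoints

    def occasion_deviance(latent_vals, traps, counts, params):
        # relaxed likelihood (trial clamp, no support barrier: a barrier
        # spike in one marginal cell would swamp the discrepancy)
        tot = counts.sum(axis=0)
        pcap = np.atleast_1d(capture_probability(x, traps, params.traps))
        ll = float(np.sum(binom_logpmf(tot, np.maximum(latent_vals, tot),
                                       pcap)))
        if len(traps) > 1:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                pc = conditional_trap_probs(x, traps, params.traps)
            ll += float(np.sum(dirichlet_multinomial_logpmf(
                counts, params.traps.rho * pc)))
        return -2.0 * ll

    n_ge = 0
    t_obs_all, t_rep_all = [], []
    for i in idx:
        nat = dict(zip(draws.names, flat[i]))
        params = model.build_params(nat)
        lam, eps_y, _, w = model._latents(nat, params)
        n_arr = model.latent_trajectory(params, lam, eps_y, w=w)
        t_obs = t_rep = 0.0
        n_cells_obs = n_zero_obs = n_cells_rep = n_zero_rep = 0
        for (y, t), (traps, counts) in model.d1.occasions.items():
            latent = DensityVector(grid, np.clip(n_arr[t - 1, y], 0.0, None))
            tot_rep, split_rep = sample_removals(latent, traps, params.traps, rng)
            if discrepancy == "deviance":
                t_obs += occasion_deviance(latent.values, traps,
                                           counts.astype(float), params)
                t_rep += occasion_deviance(latent.values, traps,
                                           split_rep.astype(float), params)
            else:
                n_cells_obs += counts.size
                n_zero_obs += int(np.sum(counts == 0))
                n_cells_rep += split_rep.size
                n_zero_rep += int(np.sum(split_rep == 0))
        if discrepancy == "prop_zero":
            t_obs = n_zero_obs / max(n_cells_obs, 1)
            t_rep = n_zero_rep / max(n_cells_rep, 1)
        t_obs_all.append(t_obs)
        t_rep_all.append(t_rep)
        if t_rep >= t_obs:
            n_ge += 1
    return {"p_value": n_ge / len(idx),
            "t_obs": np.array(t_obs_all), "t_rep": np.array(t_rep_all)}
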