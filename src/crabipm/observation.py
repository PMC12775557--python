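"""Size-selective trapping: hazard rates, capture probabilities, and the
removal likelihood (binomial totals + Dirichlet-multinomial trap split)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .size_structure import DensityVector

__all__ = [
    "GEARS",
    "TrapParams",
    "RemovalRecord",
    "hazard",
    "capture_probability",
    "conditional_trap_probs",
    "removal_loglik",
    "sample_removals",
    "binom_logpmf",
    "dirichlet_multinomial_logpmf",
]

GEARS = ("fukui", "shrimp", "minnow")


@dataclass
class TrapParams:
    """Gear-specific hazard-rate parameters (per day) plus the
    Dirichlet-multinomial overdispersion ``rho``.

    Fukui and shrimp traps have logistic size selectivity (h_max, h_k, h_0);
    the minnow trap is bell-shaped around ``h_A`` with squared-width
    ``h_sigma`` (mm^2).
    """

    h_max: dict  # gear -> max hazard (1/day)
    h_k: dict    # gear -> logistic steepness (1/mm); fukui & shrimp only
    h_0: dict    # gear -> logistic midpoint (mm); fukui & shrimp only
    h_A: float   # minnow mode (mm)
    h_sigma: float  # minnow squared width (mm^2)
    rho: float   # DM overdispersion (> 0)

    def validate(self) -> None:
        for g in GEARS:
            if self.h_max.get(g, 0.0) < 0:
                raise ValueError(f"h_max[{g}] must be >= 0")
        if self.h_sigma <= 0 or self.rho <= 0:
            raise ValueError("h_sigma and rho must be positive")


@dataclass
class RemovalRecord:
    """One trap-soak's size-binned catch."""

    year: int
    t: int
    trap_id: str
    gear: str
    soak_days: float
    counts: np.ndarray = field(repr=False)  # per size bin

    def __post_init__(self) -> None:
        if self.gear not in GEARS:
            raise ValueError(f"unknown gear {self.gear!r}")
        if self.soak_days <= 0:
            raise ValueError("soak_days must be positive")
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def hazard(x, gear: str, p: TrapParams):
    """Instantaneous capture intensity (1/day) of one trap for size ``x``."""
    x = np.asarray(x, dtype=float)
    if gear in ("fukui", "shrimp"):
        out = p.h_max[gear] * expit(p.h_k[gear] * (x - p.h_0[gear]))
    elif gear == "minnow":
        out = p.h_max["minnow"] * np.exp(-((x - p.h_A) ** 2) / p.h_sigma)
    else:
        raise ValueError(f"unknown gear {gear!r}")
    return out if out.ndim else float(out)


def total_hazard_exposure(x, traps, p: TrapParams):
    """Sum over traps of hazard(x) * soak (dimensionless exposure).

    Identical traps are aggregated so large homogeneous fleets cost one
    hazard evaluation per gear.
    """
    x = np.asarray(x, dtype=float)
    soak_by_gear: dict = {}
    for gear, soak in traps:
        soak_by_gear[gear] = soak_by_gear.get(gear, 0.0) + soak
    tot = np.zeros_like(x)
    for gear, soak_sum in soak_by_gear.items():
        tot = tot + hazard(x, gear, p) * soak_sum
    return tot


def capture_probability(x, traps, p: TrapParams):
    """Probability of capture in >= 1 of the listed (gear, soak_days) traps:
    1 - exp(-sum_j H_j(x) * soak_j)."""
    out = -np.expm1(-total_hazard_exposure(x, traps, p))
    return out if np.ndim(out) else float(out)


def conditional_trap_probs(x, traps, p: TrapParams) -> np.ndarray:
    """Probability, given capture at size ``x``, of each trap: hazard share.

    Shape (n_traps,) for scalar x, else (n_traps, len(x)). If every hazard
    vanishes a uniform split is returned with a warning (no crab of that
    size is catchable anyway).
    """
    if not traps:
        raise ValueError("at least one trap required")
    x = np.asarray(x, dtype=float)
    hz = np.stack([hazard(x, gear, p) * soak for gear, soak in traps])
    tot = hz.sum(axis=0)
    zero = tot <= 0
    if np.any(zero):
        warnings.warn("all hazards zero at some sizes; uniform split returned",
                      RuntimeWarning)
    safe_tot = np.where(zero, 1.0, tot)
    probs = np.where(zero, 1.0 / len(traps), hz / safe_tot)
    return probs


def binom_logpmf(k, n, prob):
    """Binomial log-pmf allowing real-valued ``n`` (continuous relaxation
    via gamma functions); -inf where k > n."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    prob = np.asarray(prob, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
              + np.where(k > 0, k * np.log(prob), 0.0)
              + np.where(n - k > 0, (n - k) * np.log1p(-prob), 0.0))
    bad = (k > n + 1e-9) | ((prob <= 0) & (k > 0)) | ((prob >= 1) & (k < n - 1e-9))
    ll = np.where(bad, -np.inf, ll)
    return ll if ll.ndim else float(ll)


def dirichlet_multinomial_logpmf(counts: np.ndarray, alpha: np.ndarray):
    """DM log-pmf, vectorised over trailing axes.

    ``counts`` and ``alpha`` have the category axis first (shape
    (n_cat, ...)); returns log-pmf with shape ``counts.shape[1:]``.
    """
    counts = np.asarray(counts, dtype=float)
    # clamp: a zero-concentration category with zero count contributes 0
    alpha = np.maximum(np.asarray(alpha, dtype=float), 1e-300)
    n = counts.sum(axis=0)
    a0 = alpha.sum(axis=0)
    return (gammaln(n + 1) + gammaln(a0) - gammaln(n + a0)
            + (gammaln(counts + alpha) - gammaln(counts + 1)
               - gammaln(alpha)).sum(axis=0))


def removal_loglik(records: list[RemovalRecord], latent: DensityVector,
                   p: TrapParams) -> float:
    """Log-likelihood of one (t, y) occasion's removal data.

    Binomial for the per-bin total across traps, Dirichlet-multinomial
    (concentration rho * conditional trap probabilities) for the split of
    that total among traps.
    """
    if not records:
        return 0.0
    traps = [(r.gear, r.soak_days) for r in records]
    x = latent.grid.midpoints
    counts = np.stack([r.counts for r in records]).astype(float)  # (J, m)
    totals = counts.sum(axis=0)
    pcap = capture_probability(x, traps, p)
    ll = float(np.sum(binom_logpmf(totals, latent.values, pcap)))
    if not np.isfinite(ll):
        return -np.inf
    if len(records) > 1:
        pc = conditional_trap_probs(x, traps, p)  # (J, m)
        occupied = totals > 0
        if np.any(occupied):
            ll += float(np.sum(dirichlet_multinomial_logpmf(
                counts[:, occupied], p.rho * pc[:, occupied])))
    return ll


def sample_removals(latent: DensityVector, traps, p: TrapParams, rng,
                    split: bool = True):
    """Generate one occasion's removals from the observation model.

    Returns ``(totals, per_trap)`` with ``totals`` shape (m,) drawn
    Binomial(floor(latent), p_capture) and ``per_trap`` shape (n_traps, m)
    a Dirichlet-multinomial split of each total (skipped when ``split`` is
    false, e.g. in forecasts that only need totals).
    """
    m = latent.grid.m
    n_traps = len(traps)
    if n_traps == 0:
        z = np.zeros(m, dtype=int)
        return z, np.zeros((0, m), dtype=int)
    x = latent.grid.midpoints
    pcap = np.atleast_1d(capture_probability(x, traps, p))
    trials = np.floor(latent.values).astype(int)
    totals = rng.binomial(trials, pcap)
    if not split:
        return totals, np.zeros((0, m), dtype=int)
    per_trap = np.zeros((n_traps, m), dtype=int)
    if totals.sum() > 0:
        pc = conditional_trap_probs(x, traps, p)  # (J, m)
        for i in np.nonzero(totals)[0]:
            w = rng.dirichlet(p.rho * pc[:, i])
            per_trap[:, i] = rng.multinomial(totals[i], w)
    return totals, per_trap
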