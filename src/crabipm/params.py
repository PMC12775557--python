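"""Parameter bundles shared by the process model, observation model and
inference machinery."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .kernels import GrowthParams, MortalityParams
from .observation import TrapParams

__all__ = [
    "OverwinterParams",
    "RecruitInitParams",
    "ParameterSet",
    "OVERWINTER_FORMS",
]

# Candidate functional forms for overwinter survival (model selection):
#   density_size : exp(-alpha_o * N / x^2 + eps)   (density-size interaction)
#   size         : exp(-alpha_o / x^2 + eps)
#   density      : exp(-alpha_o * N + eps)
#   constant     : exp(-alpha_o + eps)
OVERWINTER_FORMS = ("density_size", "size", "density", "constant")


@dataclass
class OverwinterParams:
    """Overwinter density- and size-dependent mortality."""

    alpha_o: float
    sigma_o: float
    eps_y: Optional[np.ndarray] = None  # one per winter transition

    def validate(self) -> None:
        if self.alpha_o < 0 or self.sigma_o < 0:
            raise ValueError("alpha_o and sigma_o must be non-negative")


@dataclass
class RecruitInitParams:
    """Initial adult density and annual recruitment pulse parameters."""

    mu_A: float        # log-mean initial adult size (mm)
    sigma_A: float     # log-sd initial adult size
    lambda_A: float    # initial adult abundance
    mu_R: float        # mean recruit size (mm)
    sigma_R: float     # sd recruit size (mm)
    mu_lambda: float   # log-mean annual recruit abundance
    sigma_lambda: float  # log-sd annual recruit abundance
    lambda_R_y: Optional[np.ndarray] = None  # per-year recruit abundance
    t_R: int = 6       # season index at which recruits enter

    def validate(self) -> None:
        if min(self.sigma_A, self.sigma_R, self.sigma_lambda) <= 0:
            raise ValueError("scale parameters must be positive")
        if self.lambda_A < 0:
            raise ValueError("lambda_A must be non-negative")


@dataclass
class ParameterSet:
    """Union of all demographic and observation parameters."""

    growth: GrowthParams
    mortality: MortalityParams
    overwinter: OverwinterParams
    traps: TrapParams
    recruit: RecruitInitParams

    def validate(self) -> None:
        self.growth.validate()
        self.mortality.validate()
        self.overwinter.validate()
        self.traps.validate()
        self.recruit.validate()

    def replace(self, **groups) -> "ParameterSet":
        return replace(self, **groups)
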