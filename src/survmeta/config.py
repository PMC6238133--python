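"""Analysis configuration: observation-model conventions and prior settings.

All knobs that the likelihood and prior modules consult live here so that a
run can be reproduced from its manifest.  Defaults are chosen for long-lived
mammals (phocid-seal scale); everything is overridable from a YAML file or
keyword arguments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

from .hazard import LEVELS

__all__ = ["VarianceComponentConfig", "MasterPriorConfig", "AnalysisConfig"]


@dataclass(frozen=True)
class VarianceComponentConfig:
    """Gamma(shape, rate) hyperprior and MCMC initial value for one level's precision tau_k."""

    level: str
    prior_shape: float = 1.0   # alpha_k
    prior_rate: float = 0.1    # beta_k
    init_precision: float = 0.1

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.prior_shape <= 0 or self.prior_rate <= 0 or self.init_precision <= 0:
            raise ValueError("variance-component shape, rate and init precision must be > 0")


@dataclass(frozen=True)
class MasterPriorConfig:
    """Weakly informative Normal priors on the unconstrained master parameters.

    The sampler works on log(a), log(b-1) and log(c); these means/SDs cover
    mammalian-plausible U-shaped hazards while remaining diffuse.
    """

    log_a_mean: float = math.log(0.1)
    log_a_sd: float = 1.5
    log_bm1_mean: float = 0.0
    log_bm1_sd: float = 1.5
    log_c_mean: float = math.log(0.01)
    log_c_sd: float = 1.5


def _default_components() -> dict:
    return {lev: VarianceComponentConfig(level=lev) for lev in LEVELS}


@dataclass(frozen=True)
class AnalysisConfig:
    """Bundle of analysis conventions.

    Attributes
    ----------
    max_age : int
        Age at which open-ended ranges ("5+") are closed; 60 y keeps
        S(max_age) < 1e-6 for plausible phocid parameters.
    default_logit_sd : float
        Conservative logit-scale SD assigned to survival estimates reported
        with no precision information (tau = 1/sd^2).
    first_catch_age : int
        Age of the first catch-at-age cell (the reference class of the
        cohort projection).
    range_weights_use_harvest : bool
        Whether age-range weights and catch cell probabilities use
        harvest-adjusted (total) annual survival; the standing age structure
        of a harvested population reflects total mortality, hence True.
    estimate_truncation : float
        Reported estimates of exactly 0 or 1 are pulled inside (0, 1) by
        this margin so the logit stays finite.
    """

    max_age: int = 60
    default_logit_sd: float = 1.0
    first_catch_age: int = 1
    range_weights_use_harvest: bool = True
    estimate_truncation: float = 1e-6
    variance_components: dict = field(default_factory=_default_components)
    master_prior: MasterPriorConfig = field(default_factory=MasterPriorConfig)

    def component(self, level: str) -> VarianceComponentConfig:
        return self.variance_components[level]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variance_components"] = {
            lev: dataclasses.asdict(vc) for lev, vc in self.variance_components.items()
        }
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "variance_components" in d:
            d["variance_components"] = {
                lev: (vc if isinstance(vc, VarianceComponentConfig) else VarianceComponentConfig(**vc))
                for lev, vc in d["variance_components"].items()
            }
        if "master_prior" in d and not isinstance(d["master_prior"], MasterPriorConfig):
            d["master_prior"] = MasterPriorConfig(**d["master_prior"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(text))


DEFAULT_CONFIG = AnalysisConfig()
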