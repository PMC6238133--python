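"""Taxonomy-structured prior for the proportional-hazard multipliers.

Each dataset's log multiplier is the sum of random effects over the active
taxonomic levels, log psi_d = sum over k in K_d of epsilon_k, with

    epsilon_k ~ Normal(0, 1/tau_k)        (one effect per group per level)
    tau_k     ~ Gamma(alpha_k, beta_k)    (rate parameterisation)

plus a Uniform(0, 2*h~_d) prior on each dataset's harvest rate.  A model
specification is simply the subset of {subfamily, species, study, dataset}
levels whose variance component is switched on; the empty subset is the
master-only model (psi_d = 1 for every dataset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .config import AnalysisConfig, DEFAULT_CONFIG, VarianceComponentConfig
from .data import HarvestSpec, TaxonomyKey
from .hazard import LEVELS, HazardMultiplier

__all__ = [
    "ModelSpec",
    "VarianceComponentConfig",
    "TaxonomyKey",
    "log_multiplier_prior",
    "precision_hyperprior",
    "harvest_prior",
    "assemble_multiplier",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components are active (the master parameters are always present)."""

    active_levels: tuple = ()

    def __post_init__(self) -> None:
        levels = tuple(self.active_levels)
        unknown = set(levels) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown level(s): {sorted(unknown)}; expected subset of {LEVELS}")
        if len(set(levels)) != len(levels):
            raise ValueError(f"duplicate level(s) in {levels}")
        # canonical order: outermost taxonomic level first
        object.__setattr__(
            self, "active_levels", tuple(lev for lev in LEVELS if lev in levels)
        )

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse Table-style formulas like '~master + species + dataset'."""
        terms = [t.strip() for t in formula.lstrip("~").split("+") if t.strip()]
        if terms and terms[0] == "master":
            terms = terms[1:]
        return cls(active_levels=tuple(terms))

    @property
    def formula(self) -> str:
        return " + ".join(("master",) + self.active_levels)

    def __contains__(self, level: str) -> bool:
        return level in self.active_levels

    def __str__(self) -> str:
        return "~" + self.formula


def log_multiplier_prior(
    level_effects: Mapping[str, Sequence[float]],
    precisions: Mapping[str, float],
    spec: ModelSpec,
) -> float:
    """Sum of centred-Normal log-densities of all group effects.

    ``level_effects[k]`` holds one epsilon per group at active level k;
    supplying effects for an inactive level is an error (it would silently
    change the model).
    """
    inactive = set(level_effects) - set(spec.active_levels)
    if inactive:
        raise ValueError(f"effects supplied for inactive level(s): {sorted(inactive)}")
    total = 0.0
    for lev in spec.active_levels:
        eps = np.asarray(level_effects.get(lev, ()), dtype=float)
        tau = float(precisions[lev])
        if not tau > 0:
            raise ValueError(f"precision for level {lev!r} must be > 0, got {tau}")
        total += float(
            0.5 * eps.size * (np.log(tau) - _LOG_2PI) - 0.5 * tau * np.sum(eps**2)
        )
    return total


def precision_hyperprior(
    precisions: Mapping[str, float],
    config: AnalysisConfig = DEFAULT_CONFIG,
    spec: ModelSpec | None = None,
) -> float:
    """Sum of Gamma(alpha_k, beta_k) log-densities (rate parameterisation) of the tau_k."""
    levels = spec.active_levels if spec is not None else tuple(precisions)
    total = 0.0
    for lev in levels:
        tau = float(precisions[lev])
        if not tau > 0:
            raise ValueError(f"precision for level {lev!r} must be > 0, got {tau}")
        vc = config.component(lev)
        total += float(
            gamma_dist.logpdf(tau, a=vc.prior_shape, scale=1.0 / vc.prior_rate)
        )
    return total


def harvest_prior(h: float, spec: HarvestSpec) -> float:
    """Uniform(0, 2*h~_d) log-density: -log(2*h~_d) inside support, -inf outside."""
    upper = 2.0 * spec.rough_rate
    if 0.0 < h < upper:
        return float(-np.log(upper))
    return -np.inf


def assemble_multiplier(
    key: TaxonomyKey,
    spec: ModelSpec,
    effects: Mapping[str, Mapping[str, float]],
) -> HazardMultiplier:
    """Build a dataset's HazardMultiplier from per-level group effects.

    ``effects[level][group_label]`` is epsilon for that group.  Every active
    level must carry an effect for the dataset's group; a missing one is a
    model-construction error.  With no active levels psi = 1.
    """
    comps: dict[str, float] = {}
    for lev in spec.active_levels:
        group = key.label(lev)
        try:
            comps[lev] = float(effects[lev][group])
        except KeyError:
            raise KeyError(
                f"no effect for level {lev!r}, group {group!r} (dataset {key.dataset!r})"
            ) from None
    return HazardMultiplier.from_components(comps)
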