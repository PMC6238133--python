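"""Reduced additive Weibull (RAW) survival and hazard mathematics.

The RAW hazard

    lambda(t) = a*b*(a*t)**(b-1) + (a/b)*(a*t)**(1/b - 1) + c,   a > 0, b > 1, c >= 0

is U-shaped ("bathtub"): the second Weibull term diverges as t -> 0+
(juvenile mortality), the first grows without bound as t -> infinity
(senescence), and ``c`` is an age-independent floor.  Its cumulative hazard
has the closed form H(t) = (a*t)**b + (a*t)**(1/b) + c*t, so the survivorship
schedule is S(t) = exp(-H(t)).

Dataset-specific mortality is modelled with proportional hazards,
lambda_d(t) = psi_d * lambda(t), equivalently S_d(t) = S(t)**psi_d, where the
multiplier psi_d is assembled from taxonomic random effects on the log scale.

Everything here is deterministic, vectorised numerics; survival is always
computed through the log scale to avoid underflow at old ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LEVELS",
    "RAWParams",
    "HazardMultiplier",
    "raw_cumulative_hazard",
    "raw_survival",
    "log_raw_survival",
    "raw_hazard",
    "adjusted_survival",
    "log_adjusted_survival",
    "annual_survival",
    "density",
    "bias_corrected_multiplier",
]

#: Taxonomic levels, outermost first.  Every dataset maps to one group per level.
LEVELS = ("subfamily", "species", "study", "dataset")

IDENTITY_MULTIPLIER: "HazardMultiplier"


@dataclass(frozen=True)
class RAWParams:
    """The three master parameters (a, b, c) of the RAW hazard.

    Parameters
    ----------
    a : float
        Rate-like scale, per year; must be strictly positive.
    b : float
        Shape; must exceed 1 (b = 1 collapses the two Weibull terms).
    c : float
        Age-independent baseline hazard, per year; non-negative.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"RAW parameter a must be > 0, got {self.a}")
        if not (self.b > 1):
            raise ValueError(f"RAW parameter b must be > 1, got {self.b}")
        if not (self.c >= 0):
            raise ValueError(f"RAW parameter c must be >= 0, got {self.c}")


@dataclass(frozen=True)
class HazardMultiplier:
    """Proportional-hazard multiplier psi_d and its log-scale components.

    ``psi`` is exp of the sum of the per-level effects ``log_components``
    (a mapping from level name to epsilon_k).  The identity multiplier
    (psi = 1, no components) recovers the master hazard.
    """

    psi: float
    log_components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.psi > 0):
            raise ValueError(f"hazard multiplier psi must be > 0, got {self.psi}")
        if self.log_components:
            unknown = set(self.log_components) - set(LEVELS)
            if unknown:
                raise ValueError(f"unknown taxonomic level(s): {sorted(unknown)}")
            total = float(sum(self.log_components.values()))
            if not np.isclose(np.log(self.psi), total, atol=1e-10):
                raise ValueError(
                    "psi inconsistent with log components: "
                    f"log(psi)={np.log(self.psi):.12g} vs sum={total:.12g}"
                )

    @classmethod
    def from_components(cls, log_components: Mapping[str, float]) -> "HazardMultiplier":
        total = float(sum(log_components.values()))
        return cls(psi=float(np.exp(total)), log_components=dict(log_components))

    @classmethod
    def identity(cls) -> "HazardMultiplier":
        return cls(psi=1.0)


def _as_nonneg_age(t, name: str = "t"):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"{name} must be non-negative")
    return t


def raw_cumulative_hazard(params: RAWParams, t) -> np.ndarray:
    """Integrated master hazard H(t) = (at)^b + (at)^(1/b) + ct, H(0) = 0."""
    t = _as_nonneg_age(t)
    at = params.a * t
    return at**params.b + at ** (1.0 / params.b) + params.c * t


def log_raw_survival(params: RAWParams, t) -> np.ndarray:
    return -raw_cumulative_hazard(params, t)


def raw_survival(params: RAWParams, t) -> np.ndarray:
    """Master survivorship S(t) = exp(-(at)^b - (at)^(1/b) - ct)."""
    return np.exp(log_raw_survival(params, t))


def raw_hazard(params: RAWParams, t) -> np.ndarray:
    """Instantaneous master mortality rate at age t > 0 (per year).

    The term (at)^(1/b - 1) diverges as t -> 0+, so t = 0 is a domain
    error rather than a silent infinity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard is defined for t > 0 only (diverges at t = 0)")
    a, b, c = params.a, params.b, params.c
    at = a * t
    # d/dt [(at)^b + (at)^(1/b) + ct]: the Weibull terms differentiate to
    # a*b*(at)^(b-1) and (a/b)*(at)^(1/b-1)
    return a * b * at ** (b - 1.0) + (a / b) * at ** (1.0 / b - 1.0) + c


def _psi_of(mult: "HazardMultiplier | float | None") -> float:
    if mult is None:
        return 1.0
    if isinstance(mult, HazardMultiplier):
        return mult.psi
    psi = float(mult)
    if not psi > 0:
        raise ValueError(f"psi must be > 0, got {psi}")
    return psi


def log_adjusted_survival(params: RAWParams, mult, t) -> np.ndarray:
    return _psi_of(mult) * log_raw_survival(params, t)


def adjusted_survival(params: RAWParams, mult, t) -> np.ndarray:
    """Dataset survivorship S_d(t) = S(t)**psi_d under proportional hazards."""
    return np.exp(log_adjusted_survival(params, mult, t))


def annual_survival(params: RAWParams, mult, t) -> np.ndarray:
    """Natural annual survival phi_t = S_d(t+1) / S_d(t) for integer age t >= 0.

    Computed as exp(-psi * (H(t+1) - H(t))) so that very old ages do not
    underflow in the ratio.
    """
    t = _as_nonneg_age(t)
    psi = _psi_of(mult)
    dH = raw_cumulative_hazard(params, t + 1.0) - raw_cumulative_hazard(params, t)
    return np.exp(-psi * dH)


def density(params: RAWParams, mult, t) -> np.ndarray:
    """Age-at-death density f_d(t) = lambda_d(t) * S_d(t), t > 0."""
    psi = _psi_of(mult)
    lam = psi * raw_hazard(params, t)  # validates t > 0
    return lam * adjusted_survival(params, mult, t)


def bias_corrected_multiplier(
    log_components: Mapping[str, float] | float,
    omitted_variance: float,
) -> float:
    """Real-scale expected multiplier at a higher taxonomic level.

    When a fitted model carries effects at levels deeper than the one being
    reported (e.g. reporting a species mean while the model has dataset
    effects), exponentiating only the retained components understates the
    real-scale mean; the lognormal correction adds half the omitted-level
    variance inside the exponential:

        psi_level = exp(sum of retained epsilon + 0.5 * sum of 1/tau_omitted).

    Parameters
    ----------
    log_components : mapping or float
        Retained log-scale effects (or their pre-summed total).
    omitted_variance : float
        Sum of 1/tau_k over the omitted deeper levels; must be >= 0.
    """
    if omitted_variance < 0:
        raise ValueError("omitted variance must be non-negative")
    if isinstance(log_components, Mapping):
        total = float(sum(log_components.values()))
    else:
        total = float(log_components)
    return float(np.exp(total + 0.5 * omitted_variance))


IDENTITY_MULTIPLIER = HazardMultiplier.identity()
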