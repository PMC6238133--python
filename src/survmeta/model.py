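"""Joint posterior assembly and the user-facing model object.

:class:`NaturalMortalityModel` bundles a dataset collection, a model
specification (which taxonomic variance components are active) and an
analysis configuration into a single log-posterior over an unconstrained
parameter vector, and hands that to the adaptive MCMC sampler via
``fit()``.

Parameterisation handed to the sampler (all unconstrained, with Jacobians):

* ``log a``, ``log(b-1)``, ``log c`` — the master RAW parameters;
* one effect per group per active level (centred by default; a
  non-centred variant, epsilon = z / sqrt(tau), is available for sparse
  groups);
* ``log tau_k`` per active level;
* one logit-scaled harvest rate per dataset, h_d = 2 h~_d sigmoid(u_d).

Out-of-support states return -inf rather than raising, so samplers can
simply reject.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import AnalysisConfig, DEFAULT_CONFIG
from .data import Dataset, DatasetCollection, read_collection
from .hazard import LEVELS
from .hierarchy import ModelSpec
from .likelihoods import CollectionLikelihood

__all__ = ["enumerate_specs", "ParamView", "NaturalMortalityModel"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def enumerate_specs() -> list[ModelSpec]:
    """All 2^4 = 16 candidate specifications, ordered by subset size then lexically."""
    specs = []
    for r in range(len(LEVELS) + 1):
        combos = sorted(itertools.combinations(sorted(LEVELS), r))
        for combo in combos:
            specs.append(ModelSpec(active_levels=combo))
    return specs


@dataclass
class ParamView:
    """A parameter vector unpacked to interpretable pieces."""

    a: float
    b: float
    c: float
    effects: dict          # level -> np.ndarray of group effects (epsilon scale)
    precisions: dict       # level -> tau_k
    harvest: np.ndarray    # per-dataset h_d
    psi: np.ndarray        # per-dataset multiplier
    log_psi: np.ndarray


class NaturalMortalityModel:
    """Hierarchical Bayesian model of age-specific natural mortality.

    Parameters
    ----------
    collection : DatasetCollection
        The data: age-specific, age-range and catch-at-age records grouped
        into taxonomically labelled datasets.
    spec : ModelSpec
        Active variance components; defaults to the full four-level model.
    config : AnalysisConfig
        Observation-model conventions and prior hyperparameters.
    non_centered : bool
        Sample group effects as z ~ Normal(0,1) with epsilon = z/sqrt(tau),
        which can mix better when group counts are small.
    """

    def __init__(
        self,
        collection: DatasetCollection,
        spec: ModelSpec | str | None = None,
        config: AnalysisConfig = DEFAULT_CONFIG,
        non_centered: bool = False,
    ):
        if spec is None:
            spec = ModelSpec(active_levels=LEVELS)
        elif isinstance(spec, str):
            spec = ModelSpec.from_formula(spec)
        self.collection = collection
        self.spec = spec
        self.config = config
        self.non_centered = bool(non_centered)
        self.likelihood = CollectionLikelihood(collection, config)
        n_d = len(collection)

        # parameter layout
        names = ["log_a", "log_bm1", "log_c"]
        self.master_slice = slice(0, 3)
        self.effect_slices: dict[str, slice] = {}
        self.group_labels: dict[str, list[str]] = {}
        self._design: dict[str, np.ndarray] = {}  # level -> per-dataset group index
        pos = 3
        for lev in spec.active_levels:
            groups = collection.groups(lev)
            self.group_labels[lev] = groups
            gidx = {g: j for j, g in enumerate(groups)}
            self._design[lev] = np.array(
                [gidx[ds.key.label(lev)] for ds in collection], dtype=int
            )
            self.effect_slices[lev] = slice(pos, pos + len(groups))
            prefix = "z" if self.non_centered else "eps"
            names += [f"{prefix}_{lev}[{g}]" for g in groups]
            pos += len(groups)
        self.tau_index: dict[str, int] = {}
        for lev in spec.active_levels:
            self.tau_index[lev] = pos
            names.append(f"log_tau_{lev}")
            pos += 1
        self.harvest_slice = slice(pos, pos + n_d)
        names += [f"u_h[{ds.dataset_id}]" for ds in collection]
        pos += n_d
        self.param_names: list[str] = names
        self.n_params = pos
        self._h_upper = np.array([2.0 * ds.harvest.rough_rate for ds in collection])

        # precompute prior constants
        mp = config.master_prior
        self._mp_mean = np.array([mp.log_a_mean, mp.log_bm1_mean, mp.log_c_mean])
        self._mp_sd = np.array([mp.log_a_sd, mp.log_bm1_sd, mp.log_c_sd])
        self._gamma_shape = np.array(
            [config.component(lev).prior_shape for lev in spec.active_levels]
        )
        self._gamma_rate = np.array(
            [config.component(lev).prior_rate for lev in spec.active_levels]
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec | str | None = None,
        config: AnalysisConfig = DEFAULT_CONFIG,
        **kwargs,
    ) -> "NaturalMortalityModel":
        """Build from a DataFrame in the canonical flat schema."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        collection = read_collection(buf, estimate_truncation=config.estimate_truncation)
        return cls(collection, spec=spec, config=config, **kwargs)

    @classmethod
    def from_csv(
        cls,
        path,
        spec: ModelSpec | str | None = None,
        config: AnalysisConfig = DEFAULT_CONFIG,
        **kwargs,
    ) -> "NaturalMortalityModel":
        collection = read_collection(path, estimate_truncation=config.estimate_truncation)
        return cls(collection, spec=spec, config=config, **kwargs)

    # -- parameter plumbing -------------------------------------------------

    def split(self, x: np.ndarray) -> ParamView:
        """Unpack an unconstrained vector into natural-scale quantities."""
        x = np.asarray(x, dtype=float)
        a = float(np.exp(x[0]))
        b = 1.0 + float(np.exp(x[1]))
        c = float(np.exp(x[2]))
        precisions = {
            lev: float(np.exp(x[self.tau_index[lev]])) for lev in self.spec.active_levels
        }
        effects = {}
        n_d = len(self.collection)
        log_psi = np.zeros(n_d)
        for lev in self.spec.active_levels:
            raw = x[self.effect_slices[lev]]
            eps = raw / np.sqrt(precisions[lev]) if self.non_centered else raw
            effects[lev] = eps
            log_psi = log_psi + eps[self._design[lev]]
        psi = np.exp(log_psi)
        h = self._h_upper * expit(x[self.harvest_slice])
        return ParamView(a=a, b=b, c=c, effects=effects, precisions=precisions,
                         harvest=h, psi=psi, log_psi=log_psi)

    # -- densities ----------------------------------------------------------

    def log_likelihood(self, x: np.ndarray) -> float:
        v = self.split(x)
        if not np.all(np.isfinite(v.psi)):
            return -np.inf
        return self.likelihood.loglik(v.a, v.b, v.c, v.psi, v.harvest)

    def deviance(self, x: np.ndarray) -> float:
        return -2.0 * self.log_likelihood(x)

    def log_prior(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            return -np.inf
        # master parameters (Normal on the unconstrained scale; no Jacobian needed)
        z = (x[self.master_slice] - self._mp_mean) / self._mp_sd
        total = float(-0.5 * np.sum(z**2) - np.sum(np.log(self._mp_sd)) - 1.5 * _LOG_2PI)
        # level effects and precisions
        for j, lev in enumerate(self.spec.active_levels):
            log_tau = float(x[self.tau_index[lev]])
            if abs(log_tau) > 700:  # exp would over/underflow
                return -np.inf
            tau = np.exp(log_tau)
            raw = x[self.effect_slices[lev]]
            n_g = raw.size
            if self.non_centered:
                total += float(-0.5 * np.sum(raw**2) - 0.5 * n_g * _LOG_2PI)
            else:
                total += float(
                    0.5 * n_g * (np.log(tau) - _LOG_2PI) - 0.5 * tau * np.sum(raw**2)
                )
            # Gamma(shape, rate) on tau plus log-Jacobian of the log transform
            al, be = self._gamma_shape[j], self._gamma_rate[j]
            total += float(al * np.log(be) - _lgamma(al) + al * log_tau - be * tau)
        # harvest: Uniform(0, 2h~) density with the sigmoid Jacobian
        u = x[self.harvest_slice]
        s = expit(u)
        total += float(np.sum(np.log(s) + np.log1p(-s)))
        return total

    def log_posterior(self, x: np.ndarray) -> float:
        lp = self.log_prior(x)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.log_likelihood(x)
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    # -- initialisation -----------------------------------------------------

    def initial_state(self, rng: np.random.Generator, jitter: float = 0.2) -> np.ndarray:
        """Prior-median start, jittered per chain; effects at ~0, tau at its configured init."""
        x = np.zeros(self.n_params)
        x[self.master_slice] = self._mp_mean + jitter * rng.standard_normal(3)
        for lev in self.spec.active_levels:
            sl = self.effect_slices[lev]
            x[sl] = 0.1 * jitter * rng.standard_normal(sl.stop - sl.start)
            x[self.tau_index[lev]] = np.log(self.config.component(lev).init_precision)
        nh = self.harvest_slice.stop - self.harvest_slice.start
        x[self.harvest_slice] = 0.2 * jitter * rng.standard_normal(nh)
        return x

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_chains: int = 3,
        n_iter: int = 15_000,
        burn_in: int = 5_000,
        thin: int = 10,
        seed: int | None = None,
        **kwargs,
    ):
        """Run the adaptive MCMC sampler; returns a NaturalMortalityResults."""
        from .inference import run_mcmc

        return run_mcmc(self, n_chains=n_chains, n_iter=n_iter, burn_in=burn_in,
                        thin=thin, seed=seed, **kwargs)

    def __repr__(self) -> str:
        return (
            f"NaturalMortalityModel(spec={self.spec}, n_datasets={len(self.collection)}, "
            f"n_params={self.n_params})"
        )


def _lgamma(x: float) -> float:
    from scipy.special import gammaln

    return float(gammaln(x))
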