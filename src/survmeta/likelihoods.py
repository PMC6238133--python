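"""Observation models linking literature survival data to RAW survival curves.

Three record types share one currency, the dataset-specific survival
function S_d(t) = S(t)**psi_d:

* age-specific estimates: logit(phi~_{t,d}) ~ Normal(logit phi_{t,d}, 1/tau),
  where phi_{t,d} = (1 - h_d) * S_d(t+1)/S_d(t) is natural annual survival
  discounted by a pulse harvest at rate h_d;
* age-range estimates: the same logit-normal form around a weighted average
  of the per-age phi_{t,d}, weights proportional to the expected number of
  animals alive at each age in the range (a cohort projection);
* catch-at-age counts: multinomial over ages with cell probabilities from
  the same cohort projection.

Reported precision is converted to a logit-scale precision tau by the delta
method, tau = phi~^2 (1-phi~)^2 / SE^2, with binomial-based fallbacks when
only a confidence interval or a sample size is given, and a conservative
default when nothing is.

The scalar functions mirror this structure one datum at a time; the
:class:`CollectionLikelihood` evaluator vectorises the whole collection for
the sampler and must agree with them exactly (that agreement is tested).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logit, logsumexp
from scipy.stats import norm

from .config import AnalysisConfig, DEFAULT_CONFIG
from .data import (
    AgeRangeDatum,
    AgeSpecificDatum,
    CatchAtAgeDatum,
    Dataset,
    DatasetCollection,
)
from .hazard import RAWParams, raw_cumulative_hazard

__all__ = [
    "logit_precision_from_se",
    "precision_from_fallbacks",
    "resolve_tau",
    "harvest_adjusted_annual_survival",
    "age_specific_loglik",
    "range_weights",
    "range_survival",
    "age_range_loglik",
    "catch_cell_probs",
    "catch_at_age_loglik",
    "CollectionLikelihood",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# precision (tau) rules


def logit_precision_from_se(estimate: float, se: float) -> float:
    """Delta-method logit-scale precision tau = phi^2 (1-phi)^2 / SE^2."""
    if not (0.0 < estimate < 1.0):
        raise ValueError(f"estimate must lie strictly in (0, 1), got {estimate}")
    if not se > 0:
        raise ValueError(f"standard error must be > 0, got {se}")
    return float((estimate * (1.0 - estimate)) ** 2 / se**2)


def precision_from_fallbacks(datum, config: AnalysisConfig = DEFAULT_CONFIG) -> float:
    """Resolve tau for a datum that lacks a directly reported standard error.

    Confidence interval: SE = (hi - lo) / (2 z_level), then the delta method.
    Sample size: binomial SE = sqrt(phi (1-phi) / n), then the delta method.
    Nothing: the conservative default tau = 1 / default_logit_sd^2.
    """
    p = datum.precision
    kind = p.kind()
    if kind == "se":
        raise ValueError("datum has a direct standard error; use logit_precision_from_se")
    if kind == "ci":
        lo, hi, level = p.ci_lo, p.ci_hi, p.ci_level
        if lo is None or hi is None or lo >= hi:
            raise ValueError(f"inconsistent confidence interval ({lo}, {hi})")
        if not (lo <= datum.estimate <= hi):
            raise ValueError(
                f"estimate {datum.estimate} lies outside its confidence interval ({lo}, {hi})"
            )
        level = 0.95 if level is None else float(level)
        if level > 1.0:  # accept percent notation (95 for 0.95)
            level /= 100.0
        z = norm.ppf(0.5 + level / 2.0)
        se = (hi - lo) / (2.0 * z)
        return logit_precision_from_se(datum.estimate, se)
    if kind == "n":
        se = float(np.sqrt(datum.estimate * (1.0 - datum.estimate) / p.n))
        return logit_precision_from_se(datum.estimate, se)
    return 1.0 / config.default_logit_sd**2


def resolve_tau(datum, config: AnalysisConfig = DEFAULT_CONFIG) -> float:
    """Logit-scale precision for any survival datum, by the best available route."""
    if datum.tau is not None:
        return float(datum.tau)
    if datum.precision.kind() == "se":
        return logit_precision_from_se(datum.estimate, datum.precision.se)
    return precision_from_fallbacks(datum, config)


# ---------------------------------------------------------------------------
# scalar observation-model quantities


def _annual_log_survival(params: RAWParams, psi: float, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    dH = raw_cumulative_hazard(params, t + 1.0) - raw_cumulative_hazard(params, t)
    return -psi * dH


def _psi(mult) -> float:
    from .hazard import _psi_of

    return _psi_of(mult)


def harvest_adjusted_annual_survival(params: RAWParams, mult, h: float, t) -> np.ndarray:
    """phi_{t,d} = (1 - h) * S_d(t+1)/S_d(t): pulse harvest times natural annual survival."""
    if not (0.0 <= h < 1.0):
        raise ValueError(f"harvest rate must lie in [0, 1), got {h}")
    return (1.0 - h) * np.exp(_annual_log_survival(params, _psi(mult), t))


def _normal_logpdf(y: float, mu: float, tau: float) -> float:
    return 0.5 * (np.log(tau) - _LOG_2PI) - 0.5 * tau * (y - mu) ** 2


def age_specific_loglik(
    datum: AgeSpecificDatum,
    params: RAWParams,
    mult,
    h: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Logit-normal log-density of one age-specific survival estimate."""
    tau = resolve_tau(datum, config)
    phi = harvest_adjusted_annual_survival(params, mult, h, datum.age)
    return float(_normal_logpdf(logit(datum.estimate), logit(phi), tau))


def range_weights(
    params: RAWParams,
    mult,
    h: float,
    t1: int,
    t2: int,
    use_harvest: bool = True,
) -> np.ndarray:
    """Cohort-projection weights over ages t1..t2 (inclusive); sum to 1.

    The weight of age t is proportional to the expected number of the cohort
    still alive at t relative to the t1 class (empty product = 1 at t1):
    the cumulative product of annual survivals phi_{t1..t-1}.  Whether those
    annual survivals include the harvest pulse is configurable; the standing
    age structure of a harvested population reflects total mortality, so
    harvest-adjusted is the default.
    """
    if t2 < t1:
        raise ValueError(f"age range requires t1 <= t2, got [{t1}, {t2}]")
    ages = np.arange(t1, t2 + 1)
    lphi = _annual_log_survival(params, _psi(mult), ages)
    if use_harvest:
        if not (0.0 <= h < 1.0):
            raise ValueError(f"harvest rate must lie in [0, 1), got {h}")
        lphi = lphi + np.log1p(-h)
    log_alive = np.concatenate([[0.0], np.cumsum(lphi[:-1])])
    w = np.exp(log_alive - logsumexp(log_alive))
    return w / w.sum()


def range_survival(
    params: RAWParams,
    mult,
    h: float,
    t1: int,
    t2: int,
    use_harvest: bool = True,
) -> float:
    """Abundance-weighted mean of per-age (harvest-adjusted) annual survival over [t1, t2]."""
    w = range_weights(params, mult, h, t1, t2, use_harvest=use_harvest)
    phis = harvest_adjusted_annual_survival(params, mult, h, np.arange(t1, t2 + 1))
    return float(np.sum(w * phis))


def age_range_loglik(
    datum: AgeRangeDatum,
    params: RAWParams,
    mult,
    h: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Logit-normal log-density of one age-range survival estimate."""
    tau = resolve_tau(datum, config)
    t2 = datum.age_hi if datum.age_hi is not None else config.max_age
    phi = range_survival(params, mult, h, datum.age_lo, t2,
                         use_harvest=config.range_weights_use_harvest)
    return float(_normal_logpdf(logit(datum.estimate), logit(phi), tau))


def catch_cell_probs(
    params: RAWParams,
    mult,
    h: float,
    T: int,
    first_catch_age: int = 1,
    use_harvest: bool = True,
) -> np.ndarray:
    """Multinomial cell probabilities over ages first_catch_age .. first_catch_age+T-1.

    Assuming age- and time-invariant harvest rates, the probability a
    harvested animal is aged t is proportional to the expected number of its
    cohort alive at t — the same cohort projection as the age-range weights.
    """
    if T < 1:
        raise ValueError(f"need at least one age class, got T={T}")
    return range_weights(params, mult, h, first_catch_age,
                         first_catch_age + T - 1, use_harvest=use_harvest)


def catch_at_age_loglik(
    datum: CatchAtAgeDatum,
    params: RAWParams,
    mult,
    h: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Multinomial log-pmf of one cohort's catch-at-age vector."""
    counts = np.asarray(datum.counts, dtype=float)
    T = counts.size
    if config.first_catch_age + T - 1 > config.max_age:
        raise ValueError(
            f"catch vector spans ages up to {config.first_catch_age + T - 1}, "
            f"beyond the configured max_age={config.max_age}"
        )
    p = catch_cell_probs(params, mult, h, T, first_catch_age=config.first_catch_age,
                         use_harvest=config.range_weights_use_harvest)
    logcoef = gammaln(counts.sum() + 1.0) - gammaln(counts + 1.0).sum()
    return float(logcoef + np.sum(counts * np.log(p)))


def dataset_loglik(
    ds: Dataset,
    params: RAWParams,
    mult,
    h: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Sum of all per-datum log-densities for one dataset (additivity reference)."""
    total = 0.0
    for d in ds.age_data:
        total += age_specific_loglik(d, params, mult, h, config)
    for d in ds.range_data:
        total += age_range_loglik(d, params, mult, h, config)
    for d in ds.catch_data:
        total += catch_at_age_loglik(d, params, mult, h, config)
    return total


# ---------------------------------------------------------------------------
# vectorised collection evaluator (sampler hot path)


class CollectionLikelihood:
    """Vectorised joint log-likelihood of a dataset collection.

    Precomputes index arrays once; ``loglik(a, b, c, psi, h)`` then costs a
    handful of small matrix operations.  ``psi`` and ``h`` are per-dataset
    vectors in collection order.  Agrees with the scalar per-datum functions
    to floating-point accuracy.
    """

    def __init__(self, collection: DatasetCollection, config: AnalysisConfig = DEFAULT_CONFIG):
        self.collection = collection
        self.config = config
        self.n_datasets = len(collection)
        A = config.max_age
        for ds in collection:
            if ds.max_observed_age(config.first_catch_age) > A:
                raise ValueError(
                    f"dataset {ds.dataset_id!r} has observations beyond max_age={A}"
                )
        self.n_ages = A + 1  # annual survivals for ages 0..A

        age_ds, age_t, age_y, age_tau = [], [], [], []
        rng_ds, rng_t1, rng_t2, rng_y, rng_tau = [], [], [], [], []
        cat_ds, cat_counts = [], []
        for i, ds in enumerate(collection):
            for d in ds.age_data:
                age_ds.append(i)
                age_t.append(d.age)
                age_y.append(logit(d.estimate))
                age_tau.append(resolve_tau(d, config))
            for d in ds.range_data:
                rng_ds.append(i)
                rng_t1.append(d.age_lo)
                rng_t2.append(d.age_hi if d.age_hi is not None else A)
                rng_y.append(logit(d.estimate))
                rng_tau.append(resolve_tau(d, config))
            for d in ds.catch_data:
                cat_ds.append(i)
                cat_counts.append(np.asarray(d.counts, dtype=float))

        self.age_ds = np.asarray(age_ds, dtype=int)
        self.age_t = np.asarray(age_t, dtype=int)
        self.age_y = np.asarray(age_y, dtype=float)
        self.age_tau = np.asarray(age_tau, dtype=float)

        self.rng_ds = np.asarray(rng_ds, dtype=int)
        self.rng_t1 = np.asarray(rng_t1, dtype=int)
        self.rng_t2 = np.asarray(rng_t2, dtype=int)
        self.rng_y = np.asarray(rng_y, dtype=float)
        self.rng_tau = np.asarray(rng_tau, dtype=float)
        ages = np.arange(self.n_ages)
        self.rng_mask = (ages[None, :] >= self.rng_t1[:, None]) & (
            ages[None, :] <= self.rng_t2[:, None]
        )

        self.cat_ds = np.asarray(cat_ds, dtype=int)
        Tc = max((c.size for c in cat_counts), default=1)
        self.cat_counts = np.zeros((len(cat_counts), Tc))
        self.cat_mask = np.zeros((len(cat_counts), Tc), dtype=bool)
        for j, c in enumerate(cat_counts):
            self.cat_counts[j, : c.size] = c
            self.cat_mask[j, : c.size] = True
        self.cat_logcoef = (
            gammaln(self.cat_counts.sum(axis=1) + 1.0)
            - gammaln(self.cat_counts + 1.0).sum(axis=1)
            if len(cat_counts)
            else np.zeros(0)
        )
        f = config.first_catch_age
        self.cat_age_cols = f + np.arange(Tc)  # ages of the catch cells

        self._t_grid = np.arange(self.n_ages + 1, dtype=float)
        self.cat_len = self.cat_mask.sum(axis=1).astype(np.int64)
        from ._kernels import HAVE_NUMBA, collection_loglik

        self._kernel = collection_loglik if HAVE_NUMBA else None

    # -- hot path -----------------------------------------------------------

    def loglik_parts(self, a: float, b: float, c: float, psi: np.ndarray, h: np.ndarray):
        """Per-dataset log-likelihood vector (length n_datasets)."""
        at = a * self._t_grid
        H = at**b + at ** (1.0 / b) + c * self._t_grid
        dH = np.diff(H)  # ages 0..A
        lphi_nat = -np.outer(psi, dH)  # (n_d, A+1)
        log1mh = np.log1p(-h)
        lphi_adj = lphi_nat + log1mh[:, None]
        lphi_w = lphi_adj if self.config.range_weights_use_harvest else lphi_nat

        out = np.zeros(self.n_datasets)

        if self.age_ds.size:
            lphi = lphi_adj[self.age_ds, self.age_t]
            mu = lphi - np.log(-np.expm1(lphi))
            terms = 0.5 * (np.log(self.age_tau) - _LOG_2PI) - 0.5 * self.age_tau * (
                self.age_y - mu
            ) ** 2
            np.add.at(out, self.age_ds, terms)

        # cumulative log cohort size: CL[:, t] = sum_{i<t} lphi_w[:, i]
        if self.rng_ds.size or self.cat_ds.size:
            CL = np.concatenate(
                [np.zeros((self.n_datasets, 1)), np.cumsum(lphi_w, axis=1)], axis=1
            )

        if self.rng_ds.size:
            L = CL[self.rng_ds, : self.n_ages] - CL[self.rng_ds, self.rng_t1][:, None]
            L = np.where(self.rng_mask, L, -np.inf)
            logZ = logsumexp(L, axis=1)
            logw = L - logZ[:, None]
            phibar = np.sum(np.where(self.rng_mask, np.exp(logw + lphi_adj[self.rng_ds, :]), 0.0), axis=1)
            mu = logit(phibar)
            terms = 0.5 * (np.log(self.rng_tau) - _LOG_2PI) - 0.5 * self.rng_tau * (
                self.rng_y - mu
            ) ** 2
            np.add.at(out, self.rng_ds, terms)

        if self.cat_ds.size:
            f = self.config.first_catch_age
            LW = CL[self.cat_ds][:, self.cat_age_cols] - CL[self.cat_ds, f][:, None]
            LW = np.where(self.cat_mask, LW, -np.inf)
            logp = LW - logsumexp(LW, axis=1)[:, None]
            terms = self.cat_logcoef + np.sum(
                np.where(self.cat_mask, self.cat_counts * logp, 0.0), axis=1
            )
            np.add.at(out, self.cat_ds, terms)

        return out

    def loglik(self, a: float, b: float, c: float, psi: np.ndarray, h: np.ndarray) -> float:
        if self._kernel is not None:
            total = self._kernel(
                float(a), float(b), float(c),
                np.ascontiguousarray(psi, dtype=float),
                np.ascontiguousarray(h, dtype=float),
                self._t_grid,
                self.age_ds, self.age_t, self.age_y, self.age_tau,
                self.rng_ds, self.rng_t1, self.rng_t2, self.rng_y, self.rng_tau,
                self.cat_ds, self.cat_counts, self.cat_len, self.cat_logcoef,
                self.config.first_catch_age,
                self.config.range_weights_use_harvest,
            )
        else:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                total = self.loglik_parts(a, b, c, psi, h).sum()
        return float(total) if np.isfinite(total) else -np.inf
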