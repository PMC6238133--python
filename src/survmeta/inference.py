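"""MCMC sampling, convergence diagnostics and DIC model comparison.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme:

* parameters are grouped into blocks (master RAW parameters, one block of
  group effects per active level, harvest rates); each block takes a joint
  Gaussian random-walk proposal whose scale follows a Robbins-Monro
  recursion towards a target acceptance rate and whose shape tracks the
  running empirical covariance of the chain (diminishing adaptation);
* in the centred parameterisation the level precisions tau_k are updated by
  their exact conjugate Gibbs draw, tau_k | eps ~ Gamma(alpha + n_k/2,
  beta + sum(eps^2)/2); in the non-centred parameterisation they get their
  own adaptive random-walk block.

The contract is the posterior, not the sampler: everything is seeded and
bit-reproducible for fixed (seed, settings, data).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "run_mcmc",
    "gelman_rubin",
    "dic",
    "model_select",
    "NaturalMortalityResults",
]


# ---------------------------------------------------------------------------
# adaptive blocks


class _AdaptiveBlock:
    """Joint Gaussian RW proposal on a subset of coordinates with
    Robbins-Monro step-size and running-covariance adaptation."""

    def __init__(self, indices: np.ndarray, target: float, init_step: float = 0.1):
        self.idx = np.asarray(indices, dtype=int)
        d = self.idx.size
        self.d = d
        self.target = target
        self.log_step = float(np.log(init_step / np.sqrt(max(d, 1))))
        self.mean = np.zeros(d)
        self.cov = np.eye(d)
        self.chol = np.eye(d)
        self.count = 0

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = x.copy()
        z = rng.standard_normal(self.d)
        y[self.idx] = x[self.idx] + np.exp(self.log_step) * (self.chol @ z)
        return y

    def adapt(self, x: np.ndarray, acc_prob: float) -> None:
        self.count += 1
        t = self.count
        # Robbins-Monro on the scalar step; full-history averaging for the
        # covariance shape (classic adaptive-Metropolis estimator)
        self.log_step += t**-0.6 * (acc_prob - self.target)
        w = 1.0 / (t + 10.0)
        xb = x[self.idx]
        delta = xb - self.mean
        self.mean += w * delta
        self.cov += w * (np.outer(delta, delta) - self.cov)
        if t >= 10 * self.d and t % 25 == 0:
            try:
                self.chol = np.linalg.cholesky(self.cov + 1e-12 * np.trace(self.cov) / self.d * np.eye(self.d) + 1e-12 * np.eye(self.d))
            except np.linalg.LinAlgError:
                pass


def _make_blocks(model, scheme: str = "global") -> list[_AdaptiveBlock]:
    """Proposal blocks.

    ``scheme='global'`` uses one joint adaptive block over everything the
    Gibbs step does not handle (all parameters except the centred-model
    precisions); the adapted covariance then captures the strong
    master-effect correlations.  ``scheme='per-level'`` falls back to
    separate master / per-level / harvest blocks.
    """
    non_tau = [i for i in range(model.n_params)
               if i not in set(model.tau_index.values())]
    tau_idx = sorted(model.tau_index.values())
    blocks = []
    if scheme in ("global", "hybrid"):
        blocks.append(_AdaptiveBlock(np.asarray(non_tau), target=0.25, init_step=0.2))
        if model.non_centered and tau_idx:
            blocks.append(_AdaptiveBlock(np.asarray(tau_idx), target=0.3, init_step=0.3))
        if scheme == "global":
            return blocks
    ms = model.master_slice
    blocks.append(_AdaptiveBlock(np.arange(ms.start, ms.stop), target=0.3, init_step=0.05))
    for lev in model.spec.active_levels:
        sl = model.effect_slices[lev]
        idx = np.arange(sl.start, sl.stop)
        blocks.append(_AdaptiveBlock(idx, target=0.3 if idx.size > 1 else 0.44, init_step=0.1))
        if model.non_centered:
            blocks.append(_AdaptiveBlock(np.array([model.tau_index[lev]]),
                                         target=0.44, init_step=0.3))
    hs = model.harvest_slice
    if hs.stop > hs.start:
        blocks.append(_AdaptiveBlock(np.arange(hs.start, hs.stop), target=0.3, init_step=0.2))
    return blocks


def _gibbs_precisions(model, x: np.ndarray, rng: np.random.Generator) -> None:
    """Exact conjugate update of tau_k given centred effects (in place)."""
    for lev in model.spec.active_levels:
        sl = model.effect_slices[lev]
        eps = x[sl]
        vc = model.config.component(lev)
        shape = vc.prior_shape + 0.5 * eps.size
        rate = vc.prior_rate + 0.5 * float(np.sum(eps**2))
        tau = rng.gamma(shape, 1.0 / rate)
        x[model.tau_index[lev]] = np.log(tau)


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(draws: np.ndarray) -> float | np.ndarray:
    """Split-chain potential scale reduction factor R-hat.

    ``draws`` has shape (n_chains, n_draws) or (n_chains, n_draws, n_params);
    each chain is split in half and the classic between/within formula

        R = sqrt( ((n-1)/n * W + B/n) / W )

    is applied to the 2*n_chains half-chains.  Requires at least two chains
    with at least two retained draws each.
    """
    draws = np.asarray(draws, dtype=float)
    scalar = draws.ndim == 2
    if scalar:
        draws = draws[:, :, None]
    m, n = draws.shape[0], draws.shape[1]
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    if n < 4:
        raise ValueError("Gelman-Rubin requires at least 4 draws per chain to split")
    half = n // 2
    split = np.concatenate([draws[:, :half], draws[:, n - half:]], axis=0)
    n2 = half
    chain_means = split.mean(axis=1)                      # (2m, p)
    chain_vars = split.var(axis=1, ddof=1)                # (2m, p)
    W = chain_vars.mean(axis=0)
    B = n2 * chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n2 - 1) / n2 * W + B / n2
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W <= 0, 1.0, rhat)
    return float(rhat[0]) if scalar else rhat


def dic(deviance_draws: np.ndarray, deviance_at_mean: float | None,
        method: str = "mean") -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    ``method='mean'`` (Spiegelhalter): pD = mean(D) - D(theta-bar);
    ``method='variance'`` (the JAGS/R2jags convention): pD = var(D)/2.
    Returns (DIC, pD) with DIC = mean(D) + pD.
    """
    D = np.asarray(deviance_draws, dtype=float).ravel()
    Dbar = float(D.mean())
    if method == "variance" or deviance_at_mean is None or not np.isfinite(deviance_at_mean):
        pd_ = float(np.var(D, ddof=1) / 2.0)
    elif method == "mean":
        pd_ = Dbar - float(deviance_at_mean)
    else:
        raise ValueError(f"unknown pD method {method!r}")
    return Dbar + pd_, pd_


# ---------------------------------------------------------------------------
# results container


@dataclass
class NaturalMortalityResults:
    """Posterior draws, diagnostics and model-comparison statistics for one fit."""

    model: object
    draws: np.ndarray            # (n_chains, n_kept, n_params), unconstrained scale
    deviance_draws: np.ndarray   # (n_chains, n_kept)
    seed: int | None
    settings: dict
    pd_method: str = "mean"
    _cache: dict = field(default_factory=dict, repr=False)

    # -- derived quantities -------------------------------------------------

    @property
    def spec(self):
        return self.model.spec

    @property
    def n_kept(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def natural_draws(self) -> dict:
        """Natural-scale draws: a, b, c, per-level effects/precisions, harvest rates."""
        if "natural" in self._cache:
            return self._cache["natural"]
        m = self.model
        out: dict[str, np.ndarray] = {
            "a": np.exp(self.draws[:, :, 0]),
            "b": 1.0 + np.exp(self.draws[:, :, 1]),
            "c": np.exp(self.draws[:, :, 2]),
        }
        for lev in m.spec.active_levels:
            tau = np.exp(self.draws[:, :, m.tau_index[lev]])
            out[f"tau_{lev}"] = tau
            sl = m.effect_slices[lev]
            for j, g in enumerate(m.group_labels[lev]):
                raw = self.draws[:, :, sl.start + j]
                out[f"eps_{lev}[{g}]"] = raw / np.sqrt(tau) if m.non_centered else raw
        from scipy.special import expit

        hs = m.harvest_slice
        for j, ds in enumerate(m.collection):
            out[f"h[{ds.dataset_id}]"] = m._h_upper[j] * expit(
                self.draws[:, :, hs.start + j]
            )
        self._cache["natural"] = out
        return out

    def psi_draws(self) -> np.ndarray:
        """Per-dataset multiplier draws, shape (n_datasets, n_chains, n_kept)."""
        m = self.model
        nat = self.natural_draws()
        n_d = len(m.collection)
        log_psi = np.zeros((n_d,) + self.draws.shape[:2])
        for lev in m.spec.active_levels:
            for i, ds in enumerate(m.collection):
                log_psi[i] += nat[f"eps_{lev}[{ds.key.label(lev)}]"]
        return np.exp(log_psi)

    @property
    def rhat(self) -> dict:
        if "rhat" not in self._cache:
            nat = self.natural_draws()
            self._cache["rhat"] = {k: float(gelman_rubin(v)) for k, v in nat.items()}
        return self._cache["rhat"]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def _dic_pair(self) -> tuple[float, float]:
        key = ("dic", self.pd_method)
        if key not in self._cache:
            theta_bar = self.draws.reshape(-1, self.draws.shape[-1]).mean(axis=0)
            d_at_mean = self.model.deviance(theta_bar)
            if not np.isfinite(d_at_mean) and self.pd_method == "mean":
                warnings.warn(
                    "posterior-mean parameters fell outside the support; "
                    "falling back to variance-based pD"
                )
            self._cache[key] = dic(self.deviance_draws, d_at_mean, method=self.pd_method)
        return self._cache[key]

    @property
    def dic(self) -> float:
        return self._dic_pair()[0]

    @property
    def pd(self) -> float:
        return self._dic_pair()[1]

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/2.5%/97.5% and R-hat per natural-scale parameter."""
        nat = self.natural_draws()
        rows = []
        for name, v in nat.items():
            flat = v.ravel()
            rows.append({
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(np.percentile(flat, 2.5)),
                "q97.5": float(np.percentile(flat, 97.5)),
                "rhat": self.rhat[name],
            })
        return pd.DataFrame(rows).set_index("parameter")

    def __str__(self) -> str:
        head = (
            f"NaturalMortalityResults  spec={self.spec}  "
            f"kept draws={self.n_kept}  DIC={self.dic:.1f}  pD={self.pd:.1f}  "
            f"max R-hat={self.max_rhat:.3f}\n"
        )
        return head + self.summary().to_string(float_format=lambda v: f"{v:.4f}")

    # -- prediction hooks ---------------------------------------------------

    def curve_at_level(self, level: str, key=None, ages=None):
        from .prediction import curve_at_level

        return curve_at_level(self, level, key=key, ages=ages)

    def predict_prior_population(self, species: str, harvest_spec=None, ages=None,
                                 seed: int | None = None):
        from .prediction import predict_prior_population

        return predict_prior_population(self, species, harvest_spec=harvest_spec,
                                        ages=ages, seed=seed)

    # -- export -------------------------------------------------------------

    def draws_frame(self) -> pd.DataFrame:
        """Natural-scale draws as a tidy frame with chain and iter columns."""
        nat = self.natural_draws()
        nc, nk = self.draws.shape[:2]
        base = {
            "chain": np.repeat(np.arange(nc), nk),
            "iter": np.tile(np.arange(nk), nc),
        }
        for name, v in nat.items():
            base[name] = v.reshape(-1)
        base["deviance"] = self.deviance_draws.reshape(-1)
        return pd.DataFrame(base)

    def export_draws(self, path) -> None:
        self.draws_frame().to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "spec": str(self.spec),
            "seed": self.seed,
            "settings": self.settings,
            "n_datasets": len(self.model.collection),
            "n_params": self.model.n_params,
            "dic": float(self.dic),
            "pd": float(self.pd),
            "pd_method": self.pd_method,
            "max_rhat": float(self.max_rhat),
        }

    def export_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


# ---------------------------------------------------------------------------
# main driver


def run_mcmc(
    model,
    n_chains: int = 3,
    n_iter: int = 15_000,
    burn_in: int = 5_000,
    thin: int = 10,
    seed: int | None = None,
    pd_method: str = "mean",
    scheme: str = "hybrid",
    max_init_retries: int = 10,
) -> NaturalMortalityResults:
    """Sample the joint posterior with the adaptive blockwise sampler.

    Retains ``n_chains * (n_iter - burn_in) / thin`` draws.  A non-finite
    posterior at initialisation triggers re-initialisation up to
    ``max_init_retries`` times before failing with diagnostics.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    n_keep = (n_iter - burn_in) // thin
    if n_keep < 1:
        raise ValueError("settings retain no draws")

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    chain_seeds = ss.spawn(n_chains)

    all_draws = np.empty((n_chains, n_keep, model.n_params))
    all_dev = np.empty((n_chains, n_keep))

    for ci in range(n_chains):
        rng = np.random.default_rng(chain_seeds[ci])
        x = None
        for attempt in range(max_init_retries):
            cand = model.initial_state(rng, jitter=0.2 * (1 + attempt))
            lp = model.log_prior(cand)
            ll = model.log_likelihood(cand)
            if np.isfinite(lp) and np.isfinite(ll):
                x, cur_lp, cur_ll = cand, lp, ll
                break
        if x is None:
            raise RuntimeError(
                f"chain {ci}: could not find a finite starting point after "
                f"{max_init_retries} attempts (spec={model.spec}, "
                f"n_params={model.n_params})"
            )

        blocks = _make_blocks(model, scheme=scheme)
        kept = 0
        for it in range(n_iter):
            for blk in blocks:
                y = blk.propose(x, rng)
                prop_lp = model.log_prior(y)
                if np.isfinite(prop_lp):
                    prop_ll = model.log_likelihood(y)
                else:
                    prop_ll = -np.inf
                log_alpha = (prop_lp + prop_ll) - (cur_lp + cur_ll)
                acc_prob = float(np.exp(min(0.0, log_alpha))) if np.isfinite(log_alpha) else 0.0
                if rng.random() < acc_prob:
                    x, cur_lp, cur_ll = y, prop_lp, prop_ll
                blk.adapt(x, acc_prob)
            if not model.non_centered and model.spec.active_levels:
                _gibbs_precisions(model, x, rng)
                cur_lp = model.log_prior(x)  # likelihood unchanged by tau
            if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
                all_draws[ci, kept] = x
                all_dev[ci, kept] = -2.0 * cur_ll
                kept += 1

    settings = {
        "n_chains": n_chains, "n_iter": n_iter, "burn_in": burn_in, "thin": thin,
        "non_centered": model.non_centered,
    }
    return NaturalMortalityResults(
        model=model, draws=all_draws, deviance_draws=all_dev, seed=seed,
        settings=settings, pd_method=pd_method,
    )


# ---------------------------------------------------------------------------
# model selection


def model_select(
    collection,
    specs=None,
    config=None,
    seed: int | None = None,
    pd_method: str = "mean",
    **mcmc_settings,
) -> pd.DataFrame:
    """Fit each candidate spec to the same data and rank by DIC (best first).

    Failed fits are recorded with their error message, never silently
    dropped.  Returns a frame with columns formula, pd, dic, max_rhat,
    status, sorted ascending by DIC.
    """
    from .config import DEFAULT_CONFIG
    from .model import NaturalMortalityModel, enumerate_specs

    if specs is None:
        specs = enumerate_specs()
    if config is None:
        config = DEFAULT_CONFIG
    rows = []
    results = {}
    for k, spec in enumerate(specs):
        sub_seed = None if seed is None else seed + 1000 * k
        try:
            m = NaturalMortalityModel(collection, spec=spec, config=config)
            res = m.fit(seed=sub_seed, pd_method=pd_method, **mcmc_settings)
            rows.append({
                "formula": str(spec), "pd": res.pd, "dic": res.dic,
                "max_rhat": res.max_rhat, "status": "ok",
            })
            results[str(spec)] = res
        except Exception as e:  # a failed fit is a ranked-table row, not a crash
            rows.append({
                "formula": str(spec), "pd": np.nan, "dic": np.nan,
                "max_rhat": np.nan, "status": f"failed: {e}",
            })
    table = pd.DataFrame(rows).sort_values("dic", na_position="last").reset_index(drop=True)
    table.attrs["results"] = results
    return table
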