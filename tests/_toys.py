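"""Tiny models with closed-form posteriors, used as sampler oracles."""

import numpy as np

from survmeta.hierarchy import ModelSpec


class ConjugateToy:
    """Normal data with known variance and a Normal prior on the mean:
    the posterior is available in closed form, so the sampler can be
    checked against an exact oracle.  Exposes the model surface the
    sampler driver expects."""

    def __init__(self, y, sigma=1.0, m0=0.0, s0=10.0):
        self.y = np.asarray(y, dtype=float)
        self.sigma, self.m0, self.s0 = sigma, m0, s0
        self.n_params = 1
        self.non_centered = False
        self.master_slice = slice(0, 1)
        self.effect_slices = {}
        self.tau_index = {}
        self.harvest_slice = slice(1, 1)
        self.spec = ModelSpec(())

    def posterior_moments(self):
        n = self.y.size
        prec = n / self.sigma**2 + 1.0 / self.s0**2
        mean = (self.y.sum() / self.sigma**2 + self.m0 / self.s0**2) / prec
        return mean, 1.0 / prec

    def initial_state(self, rng, jitter=0.2):
        return np.array([self.m0 + jitter * rng.standard_normal()])

    def log_prior(self, x):
        return float(-0.5 * ((x[0] - self.m0) / self.s0) ** 2)

    def log_likelihood(self, x):
        return float(-0.5 * np.sum((self.y - x[0]) ** 2) / self.sigma**2)
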