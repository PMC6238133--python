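"""Observation models: precision rules, harvest adjustment, range weighting,
catch-at-age multinomial, and the vectorised evaluator's agreement with the
scalar route."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit
from scipy.stats import multinomial, norm

import survmeta as sm
from survmeta.config import AnalysisConfig
from survmeta.data import PrecisionInfo
from survmeta.likelihoods import (
    CollectionLikelihood,
    dataset_loglik,
    precision_from_fallbacks,
    resolve_tau,
)


class TestPrecisionRules:
    def test_delta_method_value(self):
        # tau = 0.8^2 * 0.2^2 / 0.05^2
        assert sm.logit_precision_from_se(0.8, 0.05) == pytest.approx(10.24)

    def test_symmetric_midpoint(self):
        se = 0.123
        assert sm.logit_precision_from_se(0.5, se) == pytest.approx(0.0625 / se**2)

    def test_vague_limit(self):
        assert sm.logit_precision_from_se(0.8, 1e6) < 1e-10

    def test_boundary_estimate_rejected(self):
        with pytest.raises(ValueError):
            sm.logit_precision_from_se(1.0, 0.05)

    def test_sample_size_fallback(self):
        d = sm.AgeSpecificDatum(age=3, estimate=0.8, precision=PrecisionInfo(n=100))
        # binomial SE = sqrt(0.8*0.2/100) = 0.04, then the delta method
        assert precision_from_fallbacks(d) == pytest.approx(16.0)

    def test_ci_fallback(self):
        d = sm.AgeSpecificDatum(
            age=3, estimate=0.7,
            precision=PrecisionInfo(ci_lo=0.6, ci_hi=0.8, ci_level=0.95))
        # SE = 0.1/1.959964, tau = 0.21^2/SE^2
        assert precision_from_fallbacks(d) == pytest.approx(16.9408, abs=5e-3)

    def test_no_information_default(self):
        d = sm.AgeSpecificDatum(age=3, estimate=0.7)
        assert precision_from_fallbacks(d) == pytest.approx(1.0)
        cfg = AnalysisConfig(default_logit_sd=2.0)
        assert precision_from_fallbacks(d, cfg) == pytest.approx(0.25)

    def test_inconsistent_ci_rejected(self):
        d = sm.AgeSpecificDatum(
            age=1, estimate=0.9,
            precision=PrecisionInfo(ci_lo=0.6, ci_hi=0.8, ci_level=0.95))
        with pytest.raises(ValueError):
            precision_from_fallbacks(d)

    @pytest.mark.parametrize("phi,se", [(0.5, 0.05), (0.7, 0.05), (0.8, 0.02)])
    def test_delta_method_against_monte_carlo(self, phi, se, rng):
        """SD of logit(x), x ~ Normal(phi, SE) truncated to (0,1), matches
        tau^-1/2 within 5% (the linearisation degrades for extreme phi)."""
        x = rng.normal(phi, se, size=200_000)
        x = x[(x > 0) & (x < 1)]
        mc_sd = np.std(logit(x))
        tau = sm.logit_precision_from_se(phi, se)
        assert mc_sd == pytest.approx(tau**-0.5, rel=0.05)


class TestHarvestAdjustment:
    def test_unharvested_identity(self, master_params):
        t = 4
        assert sm.harvest_adjusted_annual_survival(master_params, 1.2, 0.0, t) == \
            pytest.approx(float(sm.annual_survival(master_params, 1.2, t)), rel=1e-14)

    def test_pulse_harvest_halves_survival(self, master_params):
        t = 4
        full = float(sm.annual_survival(master_params, None, t))
        assert sm.harvest_adjusted_annual_survival(master_params, None, 0.5, t) == \
            pytest.approx(0.5 * full, rel=1e-14)

    def test_invalid_rate_rejected(self, master_params):
        with pytest.raises(ValueError):
            sm.harvest_adjusted_annual_survival(master_params, None, 1.0, 4)


def _brute_force_weights(params, psi, h, t1, t2, use_harvest=True):
    """Cohort projection: start 1 animal at t1, multiply forward, normalise."""
    sizes = [1.0]
    for t in range(t1, t2):
        phi = float(sm.annual_survival(params, psi, t))
        if use_harvest:
            phi *= (1.0 - h)
        sizes.append(sizes[-1] * phi)
    w = np.array(sizes)
    return w / w.sum()


class TestRangeWeights:
    def test_degenerate_range(self, master_params):
        w = sm.range_weights(master_params, None, 0.1, 5, 5)
        assert w.shape == (1,) and w[0] == 1.0

    def test_constant_survival_geometric(self):
        p = sm.RAWParams(a=1e-12, b=2.0, c=0.1)
        h = 0.2
        phi = (1 - h) * np.exp(-0.1)
        w = sm.range_weights(p, None, h, 2, 7)
        expected = phi ** np.arange(6)
        expected /= expected.sum()
        assert np.allclose(w, expected, atol=1e-6)

    @given(a=st.floats(0.02, 0.3), b=st.floats(1.3, 3.5), c=st.floats(0.0, 0.05),
           psi=st.floats(0.5, 2.0), h=st.floats(0.0, 0.3),
           t1=st.integers(0, 10), width=st.integers(0, 15))
    @settings(max_examples=40, deadline=None)
    def test_matches_cohort_projection_oracle(self, a, b, c, psi, h, t1, width):
        params = sm.RAWParams(a, b, c)
        w = sm.range_weights(params, psi, h, t1, t1 + width)
        expected = _brute_force_weights(params, psi, h, t1, t1 + width)
        assert np.allclose(w, expected, atol=1e-10)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_range_survival_constant_phi(self):
        p = sm.RAWParams(a=1e-12, b=2.0, c=0.08)
        h = 0.1
        phi = (1 - h) * np.exp(-0.08)
        assert sm.range_survival(p, None, h, 1, 6) == pytest.approx(phi, abs=1e-6)

    def test_range_survival_brute_force(self, master_params):
        psi, h, t1, t2 = 1.4, 0.15, 2, 9
        w = _brute_force_weights(master_params, psi, h, t1, t2)
        phis = np.array([
            sm.harvest_adjusted_annual_survival(master_params, psi, h, t)
            for t in range(t1, t2 + 1)
        ]).ravel()
        assert sm.range_survival(master_params, psi, h, t1, t2) == pytest.approx(
            float(np.sum(w * phis)), rel=1e-12)
        assert min(phis) <= sm.range_survival(master_params, psi, h, t1, t2) <= max(phis)


class TestCatchCellProbs:
    def test_single_cell(self, master_params):
        assert sm.catch_cell_probs(master_params, None, 0.1, 1) == pytest.approx([1.0])

    def test_constant_survival_geometric(self):
        p = sm.RAWParams(a=1e-12, b=2.0, c=0.1)
        h = 0.1
        phi = (1 - h) * np.exp(-0.1)
        pr = sm.catch_cell_probs(p, None, h, 8)
        expected = phi ** np.arange(8)
        expected /= expected.sum()
        assert np.allclose(pr, expected, atol=1e-6)

    def test_matches_cohort_projection(self, master_params):
        pr = sm.catch_cell_probs(master_params, 0.8, 0.12, 12)
        expected = _brute_force_weights(master_params, 0.8, 0.12, 1, 12)
        assert np.allclose(pr, expected, atol=1e-12)


class TestLogDensities:
    def test_age_specific_mode_value(self, master_params):
        """A datum equal to the model value attains the Normal mode 0.5*log(tau/2pi)."""
        psi, h, t = 1.1, 0.05, 3
        phi = float(sm.harvest_adjusted_annual_survival(master_params, psi, h, t))
        d = sm.AgeSpecificDatum(age=t, estimate=phi, precision=PrecisionInfo(se=0.03))
        tau = resolve_tau(d)
        assert sm.age_specific_loglik(d, master_params, psi, h) == pytest.approx(
            0.5 * np.log(tau / (2 * np.pi)))

    def test_precision_scaling(self, master_params):
        psi, h, t = 1.0, 0.0, 2
        d1 = sm.AgeSpecificDatum(age=t, estimate=0.8, tau=4.0)
        d2 = sm.AgeSpecificDatum(age=t, estimate=0.8, tau=8.0)
        phi = float(sm.harvest_adjusted_annual_survival(master_params, psi, h, t))
        r2 = (logit(0.8) - logit(phi)) ** 2
        delta = sm.age_specific_loglik(d2, master_params, psi, h) - \
            sm.age_specific_loglik(d1, master_params, psi, h)
        assert delta == pytest.approx(0.5 * np.log(2) - r2 * 4.0 / 2.0)

    def test_age_specific_reference_density(self, master_params, rng):
        """Sum over a simulated dataset matches scipy's Normal log-density."""
        psi, h = 1.3, 0.08
        total, ref = 0.0, 0.0
        for _ in range(30):
            t = int(rng.integers(0, 15))
            est = float(expit(rng.normal(0, 1.5)))
            d = sm.AgeSpecificDatum(age=t, estimate=est, tau=float(rng.uniform(0.5, 20)))
            total += sm.age_specific_loglik(d, master_params, psi, h)
            phi = float(sm.harvest_adjusted_annual_survival(master_params, psi, h, t))
            ref += norm.logpdf(logit(est), loc=logit(phi), scale=d.tau**-0.5)
        assert total == pytest.approx(ref, rel=1e-12)

    def test_age_range_reference_density(self, master_params):
        psi, h = 0.9, 0.1
        d = sm.AgeRangeDatum(age_lo=1, age_hi=4, estimate=0.75, tau=9.0)
        phi = sm.range_survival(master_params, psi, h, 1, 4)
        expected = norm.logpdf(logit(0.75), loc=logit(phi), scale=1.0 / 3.0)
        assert sm.age_range_loglik(d, master_params, psi, h) == pytest.approx(
            float(expected), rel=1e-12)

    def test_open_range_closed_at_max_age(self, master_params):
        cfg = AnalysisConfig(max_age=30)
        d = sm.AgeRangeDatum(age_lo=5, age_hi=None, estimate=0.8, tau=4.0)
        phi = sm.range_survival(master_params, 1.0, 0.0, 5, 30)
        expected = norm.logpdf(logit(0.8), loc=logit(phi), scale=0.5)
        assert sm.age_range_loglik(d, master_params, 1.0, 0.0, cfg) == pytest.approx(
            float(expected), rel=1e-12)

    def test_catch_loglik_against_scipy(self, master_params, rng):
        for _ in range(10):
            T = int(rng.integers(2, 15))
            counts = rng.integers(0, 40, size=T)
            counts[0] += 1  # ensure positive total
            d = sm.CatchAtAgeDatum(cohort="c1", counts=tuple(int(x) for x in counts))
            p = sm.catch_cell_probs(master_params, 1.2, 0.1, T)
            expected = multinomial.logpmf(np.asarray(d.counts), n=d.total, p=p)
            got = sm.catch_at_age_loglik(d, master_params, 1.2, 0.1)
            assert got == pytest.approx(float(expected), rel=1e-10)

    def test_catch_all_one_cell(self, master_params):
        d = sm.CatchAtAgeDatum(cohort="c", counts=(0, 25, 0, 0))
        p = sm.catch_cell_probs(master_params, 1.0, 0.0, 4)
        assert sm.catch_at_age_loglik(d, master_params, 1.0, 0.0) == pytest.approx(
            25 * np.log(p[1]))

    def test_catch_beyond_max_age_rejected(self, master_params):
        cfg = AnalysisConfig(max_age=10)
        d = sm.CatchAtAgeDatum(cohort="c", counts=tuple([1] * 15))
        with pytest.raises(ValueError):
            sm.catch_at_age_loglik(d, master_params, 1.0, 0.0, cfg)


class TestVectorisedEvaluator:
    def test_matches_scalar_route(self, fixture_collection, rng):
        """Kernel and numpy paths both equal the per-datum scalar sum."""
        col, _ = fixture_collection
        L = CollectionLikelihood(col)
        for _ in range(5):
            a = float(rng.uniform(0.03, 0.1))
            b = float(rng.uniform(1.5, 3.5))
            c = float(rng.uniform(0.0, 0.02))
            psi = np.exp(0.3 * rng.standard_normal(len(col)))
            h = 0.3 * rng.random(len(col))
            params = sm.RAWParams(a, b, c)
            scalar = np.array([
                dataset_loglik(ds, params, psi[i], h[i]) for i, ds in enumerate(col)
            ])
            with np.errstate(all="ignore"):
                vec = L.loglik_parts(a, b, c, psi, h)
            assert np.allclose(vec, scalar, rtol=1e-9)
            assert L.loglik(a, b, c, psi, h) == pytest.approx(scalar.sum(), rel=1e-9)

    def test_pure_raw_reduction(self, fixture_collection, master_params):
        """h = 0 and psi = 1 reduce every observation-model mean to RAW quantities."""
        col, _ = fixture_collection
        ds = col[0]
        t = ds.age_data[0].age
        phi = sm.harvest_adjusted_annual_survival(master_params, 1.0, 0.0, t)
        assert phi == pytest.approx(float(sm.annual_survival(master_params, None, t)), rel=1e-14)
        w = sm.range_weights(master_params, 1.0, 0.0, 2, 6)
        w_nat = _brute_force_weights(master_params, 1.0, 0.0, 2, 6, use_harvest=False)
        assert np.allclose(w, w_nat, atol=1e-12)
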