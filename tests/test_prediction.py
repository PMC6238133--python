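"""Level curves, lognormal bias correction, and priors for data-free
populations (including the route-equivalence and shrinkage behaviour)."""

import copy

import numpy as np
import pytest

import survmeta as sm
from survmeta.prediction import _logpsi_at_level, default_ages


class TestCurveAtLevel:
    def test_dataset_level_plain_psi(self, fixture_fit):
        """At the deepest level no bias correction applies: the curve is the
        per-draw psi_d survival."""
        res, _ = fixture_fit
        nat = res.natural_draws()
        log_psi = _logpsi_at_level(res, "dataset", "ds1")
        manual = (nat["eps_species[Phoca_hispida]"] + nat["eps_dataset[ds1]"]).ravel()
        assert np.allclose(log_psi, manual)
        curve = res.curve_at_level("dataset", "ds1", ages=[0.0, 1.0, 10.0])
        a = nat["a"].ravel(); b = nat["b"].ravel(); c = nat["c"].ravel()
        S10 = np.exp(-np.exp(manual) * ((a * 10) ** b + (a * 10) ** (1 / b) + 10 * c))
        assert curve.loc[curve.age == 10.0, "S_mean"].iloc[0] == pytest.approx(
            S10.mean(), rel=1e-10)
        assert curve.loc[curve.age == 0.0, "S_mean"].iloc[0] == 1.0

    def test_species_level_bias_correction(self, fixture_fit):
        """Reporting a species while the fit carries dataset effects adds
        half the dataset-level variance inside the exponential."""
        res, _ = fixture_fit
        nat = res.natural_draws()
        log_psi = _logpsi_at_level(res, "species", "Phoca_hispida")
        manual = (nat["eps_species[Phoca_hispida]"] + 0.5 / nat["tau_dataset"]).ravel()
        assert np.allclose(log_psi, manual)

    def test_bias_correction_direction(self, fixture_fit):
        """Real-scale expected psi at a higher level exceeds the exponential
        of the retained components whenever omitted variance > 0."""
        res, _ = fixture_fit
        nat = res.natural_draws()
        corrected = np.exp(_logpsi_at_level(res, "species", "Phoca_hispida"))
        retained = np.exp(nat["eps_species[Phoca_hispida]"].ravel())
        assert np.all(corrected > retained)

    def test_master_level_matches_monte_carlo_marginalisation(self, fixture_fit, rng):
        """The per-draw correction exp(0.5*sum 1/tau) agrees with brute-force
        simulation of the omitted effects."""
        res, _ = fixture_fit
        nat = res.natural_draws()
        corrected = np.exp(_logpsi_at_level(res, "master", None))
        tau_s = nat["tau_species"].ravel()
        tau_d = nat["tau_dataset"].ravel()
        n_mc = 400
        z1 = rng.standard_normal((n_mc, 1))
        z2 = rng.standard_normal((n_mc, 1))
        mc = np.exp(z1 / np.sqrt(tau_s) + z2 / np.sqrt(tau_d)).mean(axis=0)
        # both are draws-level means of the same lognormal expectation
        assert np.mean(mc) == pytest.approx(np.mean(corrected), rel=0.05)

    def test_unknown_key_rejected(self, fixture_fit):
        res, _ = fixture_fit
        with pytest.raises(KeyError):
            res.curve_at_level("species", "Phoca_imaginaria")

    def test_curve_table_schema(self, fixture_fit):
        res, _ = fixture_fit
        c = res.curve_at_level("master")
        assert list(c.columns) == ["level", "key", "age", "S_mean", "S_lo", "S_hi",
                                   "hazard_mean", "hazard_lo", "hazard_hi"]
        assert len(c) == len(default_ages())
        assert np.isnan(c.loc[c.age == 0.0, "hazard_mean"]).all()
        interior = c[c.age > 0]
        assert (interior["hazard_lo"] <= interior["hazard_hi"]).all()
        assert (np.diff(c["S_mean"]) <= 0).all()


class TestPriorPrediction:
    def test_intervals_strictly_contain_species_level(self, fixture_fit):
        """Simulating a fresh dataset effect widens the interval at every
        age (the data-free-population prior is less precise than the
        species mean)."""
        res, _ = fixture_fit
        ages = np.arange(1.0, 31.0)
        spec_curve = res.curve_at_level("species", "Phoca_hispida", ages=ages)
        prior_curve = res.predict_prior_population("Phoca_hispida", ages=ages, seed=0)
        assert (prior_curve["S_lo"].values <= spec_curve["S_lo"].values + 1e-12).all()
        assert (prior_curve["S_hi"].values >= spec_curve["S_hi"].values - 1e-12).all()
        w_prior = prior_curve["S_hi"].values - prior_curve["S_lo"].values
        w_spec = spec_curve["S_hi"].values - spec_curve["S_lo"].values
        assert (w_prior >= w_spec - 1e-12).all()
        assert (w_prior[4:15] > w_spec[4:15]).all()  # strictly wider mid-life

    def test_unknown_species_rejected(self, fixture_fit):
        res, _ = fixture_fit
        with pytest.raises(KeyError):
            res.predict_prior_population("Pusa_caspica")

    def test_infinite_precision_collapses_to_species_curve(self, fixture_fit):
        """tau_dataset -> infinity removes the extra variance component."""
        res, _ = fixture_fit
        frozen = copy.copy(res)
        frozen._cache = {}
        frozen.draws = res.draws.copy()
        m = res.model
        frozen.draws[:, :, m.tau_index["dataset"]] = 60.0  # tau = e^60
        ages = np.array([1.0, 5.0, 10.0, 20.0])
        spec_curve = frozen.curve_at_level("species", "Phoca_hispida", ages=ages)
        prior_curve = frozen.predict_prior_population("Phoca_hispida", ages=ages, seed=1)
        assert np.allclose(prior_curve["S_mean"], spec_curve["S_mean"], atol=1e-8)
        assert np.allclose(prior_curve["S_lo"], spec_curve["S_lo"], atol=1e-8)

    def test_refit_route_agrees_with_simulation_route(self, fixture_collection,
                                                      fixture_fit):
        """Appending an all-missing dataset and refitting gives the same
        prior curves (within MC error) as post-hoc simulation of the
        dataset effect from the fitted hierarchy."""
        col, _ = fixture_collection
        res, _ = fixture_fit
        ages = np.array([1.0, 5.0, 10.0])
        sim_route = res.predict_prior_population("Phoca_hispida", ages=ages, seed=2)
        refit_route = sm.predict_prior_population_refit(
            col, "Phoca_hispida", spec="~master + species + dataset",
            ages=ages, seed=21, n_chains=3, n_iter=12_000, burn_in=4_000, thin=8,
        )
        assert np.allclose(sim_route["S_mean"], refit_route["S_mean"], atol=0.06)
        w_sim = sim_route["S_hi"] - sim_route["S_lo"]
        w_refit = refit_route["S_hi"] - refit_route["S_lo"]
        assert np.allclose(w_sim, w_refit, atol=0.12)


class TestShrinkage:
    def test_sparse_dataset_pulled_toward_species_mean(self):
        """Hierarchical pooling shrinks a sparse dataset's multiplier toward
        its species mean relative to a no-pooling fit (vague tau prior
        concentrated near zero precision)."""
        from survmeta.config import AnalysisConfig, VarianceComponentConfig
        from survmeta.simulate import DatumMix

        # one dataset gets a single imprecise datum, its species-mates are rich
        mixes = {f"ds{i}": DatumMix() for i in range(1, 9)}
        mixes["ds2"] = DatumMix(ages=(1,), range_specs=(), n_cohorts=0,
                                obs_logit_sd=0.8)
        col, truth = sm.simulate_study(seed=77, datum_mix=mixes)

        pooled = sm.NaturalMortalityModel(col, spec="~master + species + dataset")
        res_p = pooled.fit(n_chains=2, n_iter=8000, burn_in=3000, thin=5, seed=5)

        # no pooling: dataset precision pinned tiny (prior variance ~ 1e4)
        vcs = {lev: VarianceComponentConfig(level=lev) for lev in
               ("subfamily", "species", "study")}
        vcs["dataset"] = VarianceComponentConfig(
            level="dataset", prior_shape=100.0, prior_rate=1e6, init_precision=1e-4)
        cfg = AnalysisConfig(variance_components=vcs)
        unpooled = sm.NaturalMortalityModel(col, spec="~master + species + dataset",
                                            config=cfg)
        res_u = unpooled.fit(n_chains=2, n_iter=8000, burn_in=3000, thin=5, seed=5)

        eps_p = abs(res_p.summary().loc["eps_dataset[ds2]", "mean"])
        eps_u = abs(res_u.summary().loc["eps_dataset[ds2]", "mean"])
        assert eps_p < eps_u
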