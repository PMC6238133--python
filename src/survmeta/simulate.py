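"""Synthetic dataset generation under the model's own generative process.

The generator inverts the analysis: draw taxonomic effects
epsilon ~ Normal(0, sd_k^2) per group, form psi_d, compute true
harvest-adjusted annual survivals from the RAW baseline, then emit

* age-specific estimates with logit-normal observation noise (the reported
  SE is the delta-method image of the logit-scale SD, so the reader's
  precision rule recovers the generating tau exactly);
* age-range estimates the same way, around the cohort-weighted mean;
* catch-at-age vectors as multinomial draws with cohort totals ~ Poisson.

Noise is applied on the logit scale, matching the observation model, so
emitted estimates can never leave (0, 1).  Every run is fully determined by
its seed, and the ground truth (parameters, effects, multipliers, harvest
rates) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .config import AnalysisConfig, DEFAULT_CONFIG
from .data import (
    AgeRangeDatum,
    AgeSpecificDatum,
    CatchAtAgeDatum,
    Dataset,
    DatasetCollection,
    HarvestSpec,
    PrecisionInfo,
    TaxonomyKey,
)
from .hazard import LEVELS, RAWParams, raw_cumulative_hazard
from .likelihoods import catch_cell_probs, range_survival

__all__ = [
    "DatumMix",
    "generate_collection",
    "simulate_study",
    "phocid_fixture",
    "DEFAULT_TRUE_PARAMS",
]

#: Master RAW parameters used as simulation truth: the posterior means
#: estimated for phocid seals (a U-shaped curve with ~64% yearling survival).
DEFAULT_TRUE_PARAMS = RAWParams(a=0.054, b=2.6, c=0.006)


@dataclass(frozen=True)
class DatumMix:
    """What each synthetic dataset contains.

    ``ages`` are the candidate ages for age-specific records; each is kept
    independently with probability ``age_keep_prob`` (sparse literature
    coverage).  ``range_specs`` are (t1, t2) pairs, t2=None meaning
    open-ended.  ``obs_logit_sd`` is the logit-scale observation SD (0
    disables noise and emits estimates with no precision information).
    """

    ages: tuple = tuple(range(0, 10))
    range_specs: tuple = ((1, 4), (5, None))
    age_keep_prob: float = 1.0
    n_cohorts: int = 1
    catch_ages: int = 20
    catch_total_mean: float = 200.0
    obs_logit_sd: float = 0.15


@dataclass(frozen=True)
class HarvestTruth:
    """True harvest rate plus the rough rate handed to the analysis."""

    true_rate: float
    rough_rate: float


def _true_annual_survival(params: RAWParams, psi: float, h: float, ages) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    dH = raw_cumulative_hazard(params, ages + 1.0) - raw_cumulative_hazard(params, ages)
    return (1.0 - h) * np.exp(-psi * dH)


def _noisy_datum(true_value: float, sd: float, rng) -> tuple[float, PrecisionInfo]:
    if sd <= 0:
        return float(true_value), PrecisionInfo()
    y = logit(true_value) + sd * rng.standard_normal()
    est = float(expit(y))
    se = est * (1.0 - est) * sd  # delta-method image: reader recovers tau = 1/sd^2
    return est, PrecisionInfo(se=float(se))


def generate_collection(
    true_params: RAWParams,
    taxonomy: list[TaxonomyKey],
    level_sds: dict,
    harvest_rates: dict,
    datum_mix: DatumMix | dict | None = None,
    seed: int | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[DatasetCollection, dict]:
    """Simulate a dataset collection plus its ground-truth record.

    Parameters
    ----------
    taxonomy : list of TaxonomyKey
        One key per dataset; defines the nesting.
    level_sds : dict
        Level name -> SD of the log-scale effects; levels absent or at 0
        contribute no variation (the generating spec is the set of levels
        with positive SD).
    harvest_rates : dict
        dataset label -> HarvestTruth (or a float used as both true and
        rough rate).
    datum_mix : DatumMix or dict
        Record mix per dataset; a dict maps dataset label -> DatumMix for
        heterogeneous (sparse) designs.
    """
    rng = np.random.default_rng(seed)
    if datum_mix is None:
        datum_mix = DatumMix()

    unknown = set(level_sds) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown level(s) in level_sds: {sorted(unknown)}")

    # one effect per group per level with positive SD, in taxonomy order
    effects: dict[str, dict[str, float]] = {}
    for lev in LEVELS:
        sd = float(level_sds.get(lev, 0.0))
        if sd < 0:
            raise ValueError(f"level SD must be >= 0, got {sd} for {lev!r}")
        if sd == 0.0:
            continue
        effects[lev] = {}
        for key in taxonomy:
            g = key.label(lev)
            if g not in effects[lev]:
                effects[lev][g] = float(sd * rng.standard_normal())

    datasets = []
    truth_ds = {}
    for key in taxonomy:
        mix = datum_mix[key.dataset] if isinstance(datum_mix, dict) else datum_mix
        hr = harvest_rates.get(key.dataset, HarvestTruth(0.0005, 0.001))
        if not isinstance(hr, HarvestTruth):
            hr = HarvestTruth(true_rate=float(hr), rough_rate=float(hr))
        log_psi = sum(effects[lev][key.label(lev)] for lev in effects)
        psi = float(np.exp(log_psi))
        h = hr.true_rate

        age_data = []
        for t in mix.ages:
            if mix.age_keep_prob < 1.0 and rng.random() > mix.age_keep_prob:
                continue
            phi = float(_true_annual_survival(true_params, psi, h, t)[()])
            est, prec = _noisy_datum(phi, mix.obs_logit_sd, rng)
            age_data.append(AgeSpecificDatum(age=int(t), estimate=est, precision=prec))

        range_data = []
        for t1, t2 in mix.range_specs:
            if t2 is not None and t2 < t1:
                raise ValueError(f"impossible range ({t1}, {t2}) in datum mix")
            t2_closed = t2 if t2 is not None else config.max_age
            phi = range_survival(true_params, psi, h, t1, t2_closed,
                                 use_harvest=config.range_weights_use_harvest)
            est, prec = _noisy_datum(phi, mix.obs_logit_sd, rng)
            range_data.append(AgeRangeDatum(age_lo=int(t1),
                                            age_hi=None if t2 is None else int(t2),
                                            estimate=est, precision=prec))

        catch_data = []
        for ci in range(mix.n_cohorts):
            p = catch_cell_probs(true_params, psi, h, mix.catch_ages,
                                 first_catch_age=config.first_catch_age,
                                 use_harvest=config.range_weights_use_harvest)
            total = int(rng.poisson(mix.catch_total_mean))
            total = max(total, 1)
            counts = rng.multinomial(total, p)
            catch_data.append(CatchAtAgeDatum(cohort=f"c{ci + 1}", counts=tuple(counts)))

        datasets.append(Dataset(
            key=key,
            harvest=HarvestSpec(rough_rate=hr.rough_rate),
            age_data=tuple(age_data),
            range_data=tuple(range_data),
            catch_data=tuple(catch_data),
        ))
        truth_ds[key.dataset] = {"psi": psi, "log_psi": float(log_psi),
                                 "harvest_rate": h}

    truth = {
        "params": {"a": true_params.a, "b": true_params.b, "c": true_params.c},
        "level_sds": {k: float(v) for k, v in level_sds.items() if v > 0},
        "effects": effects,
        "datasets": truth_ds,
        "seed": seed,
    }
    return DatasetCollection(datasets), truth


# ---------------------------------------------------------------------------
# standard study designs


def _study_taxonomy(n_datasets: int, n_species: int, n_subfamilies: int = 2,
                    datasets_per_study: int = 1) -> list[TaxonomyKey]:
    """A balanced nested taxonomy: species split over subfamilies, one or
    more datasets per study, studies split over species."""
    keys = []
    n_studies = max(1, (n_datasets + datasets_per_study - 1) // datasets_per_study)
    for d in range(n_datasets):
        st = d // datasets_per_study
        sp = st % n_species
        sf = sp % n_subfamilies
        keys.append(TaxonomyKey(
            subfamily=f"subfam{sf + 1}",
            species=f"species{sp + 1}",
            study=f"study{st + 1}",
            dataset=f"ds{d + 1}",
        ))
    return keys


def simulate_study(
    seed: int | None = None,
    n_datasets: int = 8,
    n_species: int = 4,
    true_params: RAWParams = DEFAULT_TRUE_PARAMS,
    level_sds: dict | None = None,
    datum_mix: DatumMix | None = None,
    harvested_fraction: float = 0.5,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[DatasetCollection, dict]:
    """The standard simulation study: species- and dataset-level variation
    (SD 0.2 each) around the phocid-scale RAW truth, a mix of harvested
    (true h = 0.08, rough 0.1) and unharvested (true h = 0.0005, rough
    0.001) populations, and all three record types per dataset."""
    if level_sds is None:
        level_sds = {"species": 0.2, "dataset": 0.2}
    taxonomy = _study_taxonomy(n_datasets, n_species)
    harvest = {}
    for j, key in enumerate(taxonomy):
        if j < round(harvested_fraction * len(taxonomy)):
            harvest[key.dataset] = HarvestTruth(true_rate=0.08, rough_rate=0.1)
        else:
            harvest[key.dataset] = HarvestTruth(true_rate=0.0005, rough_rate=0.001)
    return generate_collection(true_params, taxonomy, level_sds, harvest,
                               datum_mix=datum_mix, seed=seed, config=config)


_FIXTURE_TAXONOMY = [
    TaxonomyKey("Phocinae", "Phoca_hispida", "study1", "ds1"),
    TaxonomyKey("Phocinae", "Phoca_hispida", "study1", "ds2"),
    TaxonomyKey("Phocinae", "Phoca_hispida", "study2", "ds3"),
    TaxonomyKey("Phocinae", "Erignathus_barbatus", "study3", "ds4"),
    TaxonomyKey("Phocinae", "Erignathus_barbatus", "study3", "ds5"),
    TaxonomyKey("Monachinae", "Leptonychotes_weddellii", "study4", "ds6"),
    TaxonomyKey("Monachinae", "Leptonychotes_weddellii", "study5", "ds7"),
    TaxonomyKey("Monachinae", "Mirounga_leonina", "study6", "ds8"),
]

FIXTURE_MANIFEST = {
    "n_datasets": 8, "n_studies": 6, "n_species": 4, "n_subfamilies": 2,
    "n_age_records": 8 * 10, "n_range_records": 8 * 2, "n_catch_cohorts": 8,
}


def phocid_fixture(seed: int = 20181016) -> tuple[DatasetCollection, dict]:
    """A deterministic phocid-like mini-collection used across the test
    suite: 2 subfamilies, 4 species, 6 studies, 8 datasets, all three
    record types, generated with variation at all four levels."""
    level_sds = {"subfamily": 0.1, "species": 0.2, "study": 0.1, "dataset": 0.2}
    harvest = {}
    for j, key in enumerate(_FIXTURE_TAXONOMY):
        if j % 2 == 0:
            harvest[key.dataset] = HarvestTruth(true_rate=0.08, rough_rate=0.1)
        else:
            harvest[key.dataset] = HarvestTruth(true_rate=0.0005, rough_rate=0.001)
    return generate_collection(
        DEFAULT_TRUE_PARAMS, _FIXTURE_TAXONOMY, level_sds, harvest,
        datum_mix=DatumMix(), seed=seed,
    )
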