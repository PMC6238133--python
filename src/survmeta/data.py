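"""Dataset containers and the delimited-text interchange schema.

A *dataset* is the unit of analysis: one taxonomically labelled collection
of mortality observations (typically one sex/time-period of one study) with
a rough harvest rate.  Three record types are supported:

``age``    an annual survival estimate for a single integer age;
``range``  a survival estimate spanning ages [t1, t2] (t2 may be open,
           e.g. "5+", written as a missing t2);
``catch``  one cohort's harvest count at one age (long form: one row per
           age, grouped by ``cohort``);
``meta``   a data-free declaration of a dataset (taxonomy + harvest only),
           used e.g. to build a prior for a population with no data.

The canonical flat-file schema has one row per record with columns

    dataset_id, study_id, species, subfamily, type,
    age, t1, t2, cohort, estimate, count,
    se, ci_lo, ci_hi, ci_level, n, h_rough

Schema violations are reported with 1-based file row numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .hazard import LEVELS

__all__ = [
    "TaxonomyKey",
    "PrecisionInfo",
    "AgeSpecificDatum",
    "AgeRangeDatum",
    "CatchAtAgeDatum",
    "HarvestSpec",
    "Dataset",
    "DatasetCollection",
    "SchemaError",
    "read_collection",
    "write_collection",
]

SCHEMA_COLUMNS = [
    "dataset_id", "study_id", "species", "subfamily", "type",
    "age", "t1", "t2", "cohort", "estimate", "count",
    "se", "ci_lo", "ci_hi", "ci_level", "n", "h_rough",
]

RECORD_TYPES = {"age", "range", "catch", "meta"}


class SchemaError(ValueError):
    """Input file violates the canonical schema; message carries row numbers."""


@dataclass(frozen=True)
class TaxonomyKey:
    """Nested taxonomy labels for one dataset (subfamily > species > study > dataset)."""

    subfamily: str
    species: str
    study: str
    dataset: str

    def label(self, level: str) -> str:
        return getattr(self, level)


@dataclass(frozen=True)
class PrecisionInfo:
    """How the literature reported uncertainty for one survival estimate.

    At most one route is populated: a standard error, a confidence interval
    (with its level), or a sample size; all-``None`` means no information
    was reported and the conservative default applies.
    """

    se: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    ci_level: float | None = None
    n: float | None = None

    def kind(self) -> str:
        if self.se is not None:
            return "se"
        if self.ci_lo is not None or self.ci_hi is not None:
            return "ci"
        if self.n is not None:
            return "n"
        return "none"


NO_PRECISION = PrecisionInfo()


@dataclass(frozen=True)
class AgeSpecificDatum:
    """A reported annual survival probability for one integer age class."""

    age: int
    estimate: float
    precision: PrecisionInfo = NO_PRECISION
    tau: float | None = None  # resolved logit-scale precision (set at model build)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if not (0.0 < self.estimate < 1.0):
            raise ValueError(f"survival estimate must lie in (0, 1), got {self.estimate}")


@dataclass(frozen=True)
class AgeRangeDatum:
    """A reported survival probability over ages [age_lo, age_hi].

    ``age_hi = None`` marks an open-ended range ("5+"), closed at the
    configured maximum age when the likelihood is built.
    """

    age_lo: int
    age_hi: int | None
    estimate: float
    precision: PrecisionInfo = NO_PRECISION
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.age_lo < 0:
            raise ValueError(f"t1 must be >= 0, got {self.age_lo}")
        if self.age_hi is not None and self.age_hi < self.age_lo:
            raise ValueError(f"age range requires t1 <= t2, got [{self.age_lo}, {self.age_hi}]")
        if not (0.0 < self.estimate < 1.0):
            raise ValueError(f"survival estimate must lie in (0, 1), got {self.estimate}")


@dataclass(frozen=True)
class CatchAtAgeDatum:
    """One cohort's harvest counts by age at death.

    ``counts[j]`` is the number of animals harvested at age
    ``first_catch_age + j`` (the age convention comes from the analysis
    config; counts start at age 1 by default).
    """

    cohort: str
    counts: tuple

    def __post_init__(self) -> None:
        counts = tuple(int(x) for x in self.counts)
        if any(x < 0 for x in counts):
            raise ValueError("catch counts must be non-negative")
        if sum(counts) <= 0:
            raise ValueError(f"cohort {self.cohort!r}: total catch must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class HarvestSpec:
    """Rough harvest-rate input h~_d; the model's h_d gets a Uniform(0, 2*h~_d) prior."""

    rough_rate: float
    harvested: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.rough_rate <= 0.5):
            raise ValueError(
                f"rough harvest rate must lie in (0, 0.5] so that 2*h~ <= 1, got "
                f"{self.rough_rate}; use an arbitrarily small value (e.g. 0.001) "
                "for unharvested populations"
            )


@dataclass(frozen=True)
class Dataset:
    """All observations for one dataset plus its taxonomy and harvest input."""

    key: TaxonomyKey
    harvest: HarvestSpec
    age_data: tuple = ()
    range_data: tuple = ()
    catch_data: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_data", tuple(self.age_data))
        object.__setattr__(self, "range_data", tuple(self.range_data))
        object.__setattr__(self, "catch_data", tuple(self.catch_data))

    @property
    def dataset_id(self) -> str:
        return self.key.dataset

    @property
    def n_records(self) -> int:
        return len(self.age_data) + len(self.range_data) + len(self.catch_data)

    def max_observed_age(self, first_catch_age: int = 1) -> int:
        ages = [0]
        ages += [d.age for d in self.age_data]
        ages += [d.age_hi for d in self.range_data if d.age_hi is not None]
        ages += [d.age_lo for d in self.range_data]
        ages += [first_catch_age + len(d.counts) - 1 for d in self.catch_data]
        return int(max(ages))


class DatasetCollection:
    """An ordered collection of datasets with validated nested taxonomy."""

    def __init__(self, datasets: Iterable[Dataset]):
        self.datasets: list[Dataset] = list(datasets)
        if not self.datasets:
            raise ValueError("empty dataset collection")
        ids = [d.dataset_id for d in self.datasets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate dataset id(s): {sorted(dupes)}")
        self._check_nesting()

    def _check_nesting(self) -> None:
        parent_of = {"dataset": "study", "study": "species", "species": "subfamily"}
        for child, parent in parent_of.items():
            seen: dict[str, str] = {}
            for ds in self.datasets:
                c, p = ds.key.label(child), ds.key.label(parent)
                if c in seen and seen[c] != p:
                    raise SchemaError(
                        f"non-nested taxonomy: {child} {c!r} appears under both "
                        f"{parent} {seen[c]!r} and {parent} {p!r}"
                    )
                seen[c] = p

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, i: int) -> Dataset:
        return self.datasets[i]

    def get(self, dataset_id: str) -> Dataset:
        for ds in self.datasets:
            if ds.dataset_id == dataset_id:
                return ds
        raise KeyError(dataset_id)

    def groups(self, level: str) -> list[str]:
        """Distinct group labels at a level, in first-appearance order."""
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        out: list[str] = []
        for ds in self.datasets:
            lab = ds.key.label(level)
            if lab not in out:
                out.append(lab)
        return out

    def species_of(self, species: str) -> list[Dataset]:
        return [d for d in self.datasets if d.key.species == species]

    def with_dataset(self, dataset: Dataset) -> "DatasetCollection":
        return DatasetCollection(self.datasets + [dataset])

    def census(self) -> dict:
        return {
            "n_datasets": len(self.datasets),
            "n_studies": len(self.groups("study")),
            "n_species": len(self.groups("species")),
            "n_subfamilies": len(self.groups("subfamily")),
            "n_age_records": sum(len(d.age_data) for d in self.datasets),
            "n_range_records": sum(len(d.range_data) for d in self.datasets),
            "n_catch_cohorts": sum(len(d.catch_data) for d in self.datasets),
        }


# ---------------------------------------------------------------------------
# flat-file reader / writer


def _opt(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return v


def _truncate_estimate(x: float, eps: float, where: str) -> float:
    if x <= 0.0 or x >= 1.0:
        lo, hi = eps, 1.0 - eps
        warnings.warn(
            f"{where}: survival estimate {x} outside (0, 1); truncated to "
            f"[{lo}, {hi}] so its logit stays finite"
        )
        return float(np.clip(x, lo, hi))
    return float(x)


def read_collection(path_or_buf, estimate_truncation: float = 1e-6) -> DatasetCollection:
    """Read a collection from the canonical CSV schema.

    Raises :class:`SchemaError` with 1-based row numbers on violations.
    Precision (tau) is *not* resolved here; that happens when a model is
    built, under a specific analysis configuration.
    """
    df = pd.read_csv(path_or_buf, dtype={"dataset_id": str, "study_id": str,
                                         "species": str, "subfamily": str,
                                         "type": str, "cohort": str})
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    problems: list[str] = []
    per_ds: dict[str, dict] = {}
    order: list[str] = []

    for i, row in df.iterrows():
        rowno = i + 2  # header is row 1
        rtype = _opt(row, "type")
        if rtype not in RECORD_TYPES:
            problems.append(f"row {rowno}: unknown record type {rtype!r}")
            continue
        did = _opt(row, "dataset_id")
        if did is None:
            problems.append(f"row {rowno}: dataset_id is required")
            continue
        labels = {}
        for col, lev in (("study_id", "study"), ("species", "species"), ("subfamily", "subfamily")):
            v = _opt(row, col)
            if v is None:
                problems.append(f"row {rowno}: {col} is required")
            labels[lev] = v
        h = _opt(row, "h_rough")
        try:
            key = TaxonomyKey(subfamily=labels["subfamily"], species=labels["species"],
                              study=labels["study"], dataset=did)
        except TypeError:
            continue

        if did not in per_ds:
            if h is None:
                problems.append(f"row {rowno}: h_rough is required on the first row of dataset {did!r}")
                h = 0.001
            try:
                harvest = HarvestSpec(rough_rate=float(h))
            except ValueError as e:
                problems.append(f"row {rowno}: {e}")
                harvest = HarvestSpec(rough_rate=0.001)
            per_ds[did] = {"key": key, "harvest": harvest, "age": [], "range": [],
                           "catch": {}}
            order.append(did)
        else:
            if per_ds[did]["key"] != key:
                problems.append(
                    f"row {rowno}: dataset {did!r} carries inconsistent taxonomy labels"
                )
            if h is not None and not np.isclose(float(h), per_ds[did]["harvest"].rough_rate):
                problems.append(f"row {rowno}: dataset {did!r} carries conflicting h_rough values")

        rec = per_ds[did]
        try:
            if rtype == "meta":
                pass
            elif rtype == "catch":
                age = _opt(row, "age")
                cnt = _opt(row, "count")
                coh = _opt(row, "cohort")
                if age is None or cnt is None or coh is None:
                    problems.append(f"row {rowno}: catch rows need cohort, age and count")
                else:
                    rec["catch"].setdefault(str(coh), {})[int(age)] = int(cnt)
            else:
                est = _opt(row, "estimate")
                if est is None:
                    problems.append(f"row {rowno}: {rtype} rows need an estimate")
                    continue
                est = _truncate_estimate(float(est), estimate_truncation, f"row {rowno}")
                prec = PrecisionInfo(
                    se=None if _opt(row, "se") is None else float(row["se"]),
                    ci_lo=None if _opt(row, "ci_lo") is None else float(row["ci_lo"]),
                    ci_hi=None if _opt(row, "ci_hi") is None else float(row["ci_hi"]),
                    ci_level=None if _opt(row, "ci_level") is None else float(row["ci_level"]),
                    n=None if _opt(row, "n") is None else float(row["n"]),
                )
                if prec.kind() == "ci":
                    lo, hi = prec.ci_lo, prec.ci_hi
                    if lo is None or hi is None or lo >= hi:
                        problems.append(f"row {rowno}: inconsistent confidence interval ({lo}, {hi})")
                        continue
                    if not (lo <= est <= hi):
                        problems.append(
                            f"row {rowno}: estimate {est} lies outside its confidence interval ({lo}, {hi})"
                        )
                        continue
                if rtype == "age":
                    age = _opt(row, "age")
                    if age is None:
                        problems.append(f"row {rowno}: age rows need an age")
                        continue
                    rec["age"].append(AgeSpecificDatum(age=int(age), estimate=est, precision=prec))
                else:  # range
                    t1 = _opt(row, "t1")
                    t2 = _opt(row, "t2")
                    if t1 is None:
                        problems.append(f"row {rowno}: range rows need t1")
                        continue
                    rec["range"].append(
                        AgeRangeDatum(age_lo=int(t1),
                                      age_hi=None if t2 is None else int(t2),
                                      estimate=est, precision=prec)
                    )
        except (ValueError, TypeError) as e:
            problems.append(f"row {rowno}: {e}")

    if problems:
        raise SchemaError("input violates the canonical schema:\n  " + "\n  ".join(problems))

    datasets = []
    for did in order:
        rec = per_ds[did]
        catch_data = []
        for coh, by_age in rec["catch"].items():
            ages = sorted(by_age)
            first, last = ages[0], ages[-1]
            if first < 1:
                raise SchemaError(
                    f"dataset {did!r} cohort {coh!r}: catch ages must be >= 1 "
                    "(age-0 animals are not in the standing harvested age structure)"
                )
            # re-anchor to age 1 by zero-padding; the analysis config's
            # first_catch_age governs interpretation downstream
            counts = [0] * (first - 1) + [by_age.get(a, 0) for a in range(first, last + 1)]
            catch_data.append(CatchAtAgeDatum(cohort=coh, counts=tuple(counts)))
        datasets.append(Dataset(key=rec["key"], harvest=rec["harvest"],
                                age_data=tuple(rec["age"]), range_data=tuple(rec["range"]),
                                catch_data=tuple(catch_data)))
    return DatasetCollection(datasets)


def write_collection(collection: DatasetCollection, path_or_buf) -> None:
    """Write a collection in the canonical CSV schema (inverse of read_collection)."""
    rows = []

    def base(ds: Dataset) -> dict:
        return {
            "dataset_id": ds.key.dataset, "study_id": ds.key.study,
            "species": ds.key.species, "subfamily": ds.key.subfamily,
            "h_rough": ds.harvest.rough_rate,
        }

    for ds in collection:
        if ds.n_records == 0:
            rows.append({**base(ds), "type": "meta"})
        for d in ds.age_data:
            p = d.precision
            rows.append({**base(ds), "type": "age", "age": d.age, "estimate": d.estimate,
                         "se": p.se, "ci_lo": p.ci_lo, "ci_hi": p.ci_hi,
                         "ci_level": p.ci_level, "n": p.n})
        for d in ds.range_data:
            p = d.precision
            rows.append({**base(ds), "type": "range", "t1": d.age_lo, "t2": d.age_hi,
                         "estimate": d.estimate, "se": p.se, "ci_lo": p.ci_lo,
                         "ci_hi": p.ci_hi, "ci_level": p.ci_level, "n": p.n})
        for d in ds.catch_data:
            for j, cnt in enumerate(d.counts):
                rows.append({**base(ds), "type": "catch", "cohort": d.cohort,
                             "age": 1 + j, "count": cnt})
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    df.to_csv(path_or_buf, index=False)
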