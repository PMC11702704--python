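"""Cohort data model: dogs, condition records, inclusion filtering, life stages.

The cohort is stored as two tables mirroring the on-disk CSV contract:

``dogs``
    one row per dog — ``id, age_years, weight_lbs, sex, breed``

``conditions``
    long format, one row per (dog, condition) record —
    ``dog_id, condition_id, condition_name, category, onset_month``
    where ``onset_month`` is a calendar month index (``year*12 + month-1``)
    or NaN when the owner reported no onset date.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEX_CATEGORIES = ("spayed female", "neutered male", "intact female", "intact male")
BREED_CATEGORIES = ("purebred", "mixed")
LIFE_STAGES = ("puppy", "young adult", "mature adult", "senior")

DOGS_COLUMNS = ["id", "age_years", "weight_lbs", "sex", "breed"]
CONDITIONS_COLUMNS = ["dog_id", "condition_id", "condition_name", "category", "onset_year_month"]

_YM_RE = re.compile(r"^(\d{4})-(\d{2})$")


def month_index(year_month: str) -> int:
    """Convert ``"YYYY-MM"`` to a month index (year*12 + month-1)."""
    m = _YM_RE.match(str(year_month))
    if not m:
        raise ValueError(f"onset date {year_month!r} is not in YYYY-MM format")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {year_month!r}")
    return year * 12 + (month - 1)


def month_str(index: int) -> str:
    """Inverse of :func:`month_index`."""
    index = int(index)
    return f"{index // 12:04d}-{index % 12 + 1:02d}"


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dog:
    """A single dog's covariates and condition history."""

    id: object
    age: float
    weight: float
    sex: str
    breed_background: str
    conditions: frozenset = frozenset()
    onsets: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.age > 0 and np.isfinite(self.age)):
            raise ValueError(f"dog {self.id}: age must be positive, got {self.age}")
        if not (self.weight > 0 and np.isfinite(self.weight)):
            raise ValueError(f"dog {self.id}: weight must be positive, got {self.weight}")
        if self.sex not in SEX_CATEGORIES:
            raise ValueError(f"dog {self.id}: unknown sex category {self.sex!r}")
        if self.breed_background not in BREED_CATEGORIES:
            raise ValueError(f"dog {self.id}: unknown breed background {self.breed_background!r}")
        if not set(self.onsets) <= set(self.conditions):
            raise ValueError(f"dog {self.id}: onset recorded for a condition the dog does not have")


@dataclass
class Cohort:
    """Dog table + long condition table + filter provenance."""

    dogs: pd.DataFrame
    conditions: pd.DataFrame
    filter_log: list = field(default_factory=list)

    def __post_init__(self):
        self.dogs = self.dogs.reset_index(drop=True)
        self.conditions = self.conditions.reset_index(drop=True)
        if self.dogs["id"].duplicated().any():
            raise ValueError("duplicate dog ids")
        unknown = set(self.conditions["dog_id"]) - set(self.dogs["id"])
        if unknown:
            raise ValueError(f"condition records for unknown dogs: {sorted(unknown)[:5]}")
        if (self.dogs["age_years"] <= 0).any() or (self.dogs["weight_lbs"] <= 0).any():
            raise ValueError("age and weight must be strictly positive")

    @property
    def n_dogs(self) -> int:
        return len(self.dogs)

    @property
    def condition_ids(self) -> list:
        return sorted(self.conditions["condition_id"].unique())

    @property
    def catalog(self) -> pd.DataFrame:
        """Per-condition id, name, body-system category and case count."""
        if self.conditions.empty:
            return pd.DataFrame(columns=["condition_id", "condition_name", "category", "n_cases"])
        grp = (
            self.conditions.groupby("condition_id")
            .agg(
                condition_name=("condition_name", "first"),
                category=("category", "first"),
                n_cases=("dog_id", "nunique"),
            )
            .reset_index()
            .sort_values("condition_id", ignore_index=True)
        )
        return grp

    def indicator_matrix(self, condition_ids: Iterable | None = None):
        """Dense boolean (n_dogs, K) matrix of condition indicators.

        Returns ``(matrix, condition_ids)`` with columns in the order of
        ``condition_ids`` (defaults to all conditions, sorted).
        """
        ids = list(condition_ids) if condition_ids is not None else self.condition_ids
        col = {c: j for j, c in enumerate(ids)}
        row = {d: i for i, d in enumerate(self.dogs["id"])}
        mat = np.zeros((self.n_dogs, len(ids)), dtype=bool)
        sub = self.conditions[self.conditions["condition_id"].isin(col)]
        mat[
            sub["dog_id"].map(row).to_numpy(),
            sub["condition_id"].map(col).to_numpy(),
        ] = True
        return mat, ids

    def onset_matrix(self, condition_ids: Iterable | None = None):
        """(n_dogs, K) float matrix of onset month indices, NaN when undated/absent."""
        ids = list(condition_ids) if condition_ids is not None else self.condition_ids
        col = {c: j for j, c in enumerate(ids)}
        row = {d: i for i, d in enumerate(self.dogs["id"])}
        mat = np.full((self.n_dogs, len(ids)), np.nan)
        sub = self.conditions[self.conditions["condition_id"].isin(col)]
        mat[
            sub["dog_id"].map(row).to_numpy(),
            sub["condition_id"].map(col).to_numpy(),
        ] = sub["onset_month"].to_numpy(dtype=float)
        return mat, ids

    def subset_dogs(self, keep_ids) -> "Cohort":
        keep = set(keep_ids)
        return Cohort(
            self.dogs[self.dogs["id"].isin(keep)].copy(),
            self.conditions[self.conditions["dog_id"].isin(keep)].copy(),
            list(self.filter_log),
        )

    def dog(self, dog_id) -> Dog:
        row = self.dogs[self.dogs["id"] == dog_id]
        if row.empty:
            raise KeyError(dog_id)
        row = row.iloc[0]
        recs = self.conditions[self.conditions["dog_id"] == dog_id]
        onsets = {
            r.condition_id: int(r.onset_month)
            for r in recs.itertuples()
            if pd.notna(r.onset_month)
        }
        return Dog(
            id=row["id"],
            age=float(row["age_years"]),
            weight=float(row["weight_lbs"]),
            sex=row["sex"],
            breed_background=row["breed"],
            conditions=frozenset(recs["condition_id"]),
            onsets=onsets,
        )


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------

def apply_inclusion_criteria(cohort: Cohort, min_cases: int = 60) -> Cohort:
    """Keep conditions with >= ``min_cases`` dogs, then dogs with >= 1 retained
    condition.

    A single condition-then-dog pass: the case threshold is NOT re-checked
    after dog removal (the cohort is defined by one fixed condition set). The
    filter log records whether a second pass would have changed the result.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    counts = cohort.conditions.groupby("condition_id")["dog_id"].nunique()
    keep_conditions = set(counts[counts >= min_cases].index)
    cond = cohort.conditions[cohort.conditions["condition_id"].isin(keep_conditions)]
    keep_dogs = set(cond["dog_id"])
    dogs = cohort.dogs[cohort.dogs["id"].isin(keep_dogs)]
    cond = cond[cond["dog_id"].isin(keep_dogs)]

    recount = cond.groupby("condition_id")["dog_id"].nunique() if not cond.empty else pd.Series(dtype=int)
    second_pass_would_change = bool((recount < min_cases).any())

    log = list(cohort.filter_log)
    log.append(
        {
            "rule": f"condition >= {min_cases} cases, then dogs with >= 1 retained condition",
            "conditions_before": int(cohort.conditions["condition_id"].nunique()),
            "conditions_after": int(len(keep_conditions)),
            "dogs_before": int(cohort.n_dogs),
            "dogs_after": int(len(keep_dogs)),
            "second_pass_would_change": second_pass_would_change,
        }
    )
    return Cohort(dogs.copy(), cond.copy(), log)


# ---------------------------------------------------------------------------
# Medical-history span
# ---------------------------------------------------------------------------

def medical_history_span(dog: Dog) -> int:
    """Months between a dog's latest and earliest reported condition onsets.

    A proxy for the observation window of the dog's medical history; 0 for a
    single dated condition. Raises if the dog has no dated onsets.
    """
    if not dog.onsets:
        raise ValueError(f"dog {dog.id}: span undefined (no dated onsets)")
    vals = list(dog.onsets.values())
    return int(max(vals) - min(vals))


def medical_history_spans(cohort: Cohort) -> pd.Series:
    """Span in months for every dog with >= 1 dated onset, indexed by dog id."""
    dated = cohort.conditions.dropna(subset=["onset_month"])
    if dated.empty:
        return pd.Series(dtype=float, name="span_months")
    grp = dated.groupby("dog_id")["onset_month"]
    return (grp.max() - grp.min()).astype(float).rename("span_months")


# ---------------------------------------------------------------------------
# Life stages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeStageTable:
    """Age cutoffs (years) for puppy/young adult/mature adult/senior by weight class.

    ``weight_breaks`` are the upper bounds (lbs) of all but the last weight
    class; ``age_cutoffs[i]`` are the (puppy_end, young_adult_end,
    mature_adult_end) ages for class ``i``. Intervals are left-closed,
    right-open in both weight and age; ages at or beyond the last cutoff are
    senior.
    """

    weight_breaks: tuple = (20.0, 50.0, 90.0)
    age_cutoffs: tuple = (
        (0.75, 6.0, 12.0),   # < 20 lbs
        (0.75, 5.5, 11.0),   # 20-50 lbs
        (1.0, 5.0, 9.5),     # 50-90 lbs
        (1.25, 4.5, 8.0),    # >= 90 lbs
    )

    def __post_init__(self):
        if len(self.age_cutoffs) != len(self.weight_breaks) + 1:
            raise ValueError("need one cutoff row per weight class")
        if list(self.weight_breaks) != sorted(self.weight_breaks):
            raise ValueError("weight breaks must be increasing")
        for row in self.age_cutoffs:
            if not (0 < row[0] < row[1] < row[2]):
                raise ValueError(f"age cutoffs must be strictly increasing and positive: {row}")

    def weight_class(self, weight: float) -> int:
        if weight <= 0:
            raise ValueError("weight must be positive")
        return int(np.searchsorted(np.asarray(self.weight_breaks), weight, side="right"))

    def stage(self, age: float, weight: float) -> str:
        if age <= 0:
            raise ValueError("age must be positive")
        cuts = self.age_cutoffs[self.weight_class(weight)]
        return LIFE_STAGES[int(np.searchsorted(np.asarray(cuts), age, side="right"))]


#: Stand-in defaults approximating the DAP veterinary life-stage guidelines
#: (small dogs mature later into seniority, giant breeds earlier). The exact
#: published age x weight cutoffs are not shipped here; override via config.
DEFAULT_LIFE_STAGE_TABLE = LifeStageTable()


def assign_life_stage(dog: Dog, table: LifeStageTable = DEFAULT_LIFE_STAGE_TABLE) -> str:
    """Life stage from the dog's weight class and age (senior if beyond table)."""
    return table.stage(dog.age, dog.weight)


def assign_life_stages(cohort: Cohort, table: LifeStageTable = DEFAULT_LIFE_STAGE_TABLE) -> pd.Series:
    """Vectorized life-stage assignment; Series indexed by dog id."""
    wclass = np.searchsorted(np.asarray(table.weight_breaks), cohort.dogs["weight_lbs"].to_numpy(), side="right")
    cuts = np.asarray(table.age_cutoffs)[wclass]  # (n, 3)
    idx = (cohort.dogs["age_years"].to_numpy()[:, None] >= cuts).sum(axis=1)
    return pd.Series(
        np.asarray(LIFE_STAGES, dtype=object)[idx],
        index=cohort.dogs["id"].to_numpy(),
        name="life_stage",
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def cohort_summary(cohort: Cohort, top_k: int = 20) -> dict:
    """Descriptive summary: conditions-per-dog histogram, multimorbidity
    fraction (>= 3 concurrent conditions), top-k condition frequencies and
    medical-history span by age."""
    if cohort.n_dogs == 0:
        raise ValueError("empty cohort")
    per_dog = (
        cohort.conditions.groupby("dog_id")["condition_id"].nunique()
        .reindex(cohort.dogs["id"], fill_value=0)
    )
    hist = per_dog.value_counts().sort_index()
    catalog = cohort.catalog
    top = catalog.sort_values(["n_cases", "condition_id"], ascending=[False, True]).head(top_k)
    spans = medical_history_spans(cohort)
    age = cohort.dogs.set_index("id")["age_years"]
    span_by_age = None
    if not spans.empty:
        bins = pd.cut(age.loc[spans.index], bins=[0, 3, 6, 9, 12, 15, 100])
        span_by_age = spans.groupby(bins, observed=True).median()
    return {
        "n_dogs": int(cohort.n_dogs),
        "n_conditions": int(len(catalog)),
        "conditions_per_dog": hist,
        "multimorbidity_fraction": float((per_dog >= 3).mean()),
        "top_conditions": top,
        "median_span_months_by_age": span_by_age,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, dogs_path, conditions_path) -> None:
    dogs = cohort.dogs[DOGS_COLUMNS]
    dogs.to_csv(dogs_path, index=False)
    cond = cohort.conditions.copy()
    cond["onset_year_month"] = [
        month_str(v) if pd.notna(v) else "" for v in cond["onset_month"]
    ]
    cond = cond.sort_values(["dog_id", "condition_id"], ignore_index=True)
    cond[CONDITIONS_COLUMNS].to_csv(conditions_path, index=False)


def read_cohort(dogs_path, conditions_path) -> Cohort:
    """Read the dogs.csv / conditions.csv pair with strict header validation."""
    dogs = pd.read_csv(dogs_path)
    if list(dogs.columns) != DOGS_COLUMNS:
        raise ValueError(f"dogs file must have columns {DOGS_COLUMNS}, got {list(dogs.columns)}")
    bad_sex = set(dogs["sex"]) - set(SEX_CATEGORIES)
    if bad_sex:
        raise ValueError(f"unknown sex categories: {sorted(bad_sex)}")
    bad_breed = set(dogs["breed"]) - set(BREED_CATEGORIES)
    if bad_breed:
        raise ValueError(f"unknown breed values: {sorted(bad_breed)}")
    cond = pd.read_csv(conditions_path, keep_default_na=False)
    if list(cond.columns) != CONDITIONS_COLUMNS:
        raise ValueError(
            f"conditions file must have columns {CONDITIONS_COLUMNS}, got {list(cond.columns)}"
        )
    cond["onset_month"] = [
        float(month_index(v)) if v else np.nan for v in cond["onset_year_month"]
    ]
    cond = cond.drop(columns=["onset_year_month"])
    return Cohort(dogs, cond)
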