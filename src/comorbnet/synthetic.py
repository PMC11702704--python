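"""Synthetic dog cohorts with planted comorbidity structure.

Generates cohorts with the statistical structure the comorbidity analysis
assumes: covariates (age, weight, sex/reproductive status, breed background)
drawn from distributions calibrated to the marginal summaries of a large
owner-reported survey cohort, condition indicators drawn from per-condition
logistic models, optional planted pairwise dependence (a conditional log-odds
boost delta on condition z when the dog has condition y), and month-resolution
onset dates with optional planted temporal ordering (onset of z follows onset
of y by a uniform lag). The planted structure is returned as a
:class:`SyntheticTruth` so recovery can be scored exactly.

Note the planted ``delta`` is a *conditional* log-odds shift (z given y,
holding covariates fixed), not a marginal odds ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import SEX_CATEGORIES, Cohort, month_index
from .risk import design_matrix, model_terms

#: 20 body-system categories used to label synthetic conditions
BODY_SYSTEMS = (
    "skin", "eye", "ear/nose/throat", "mouth/dental/oral", "bone/orthopedic",
    "brain/neurologic", "cardiac", "respiratory", "gastrointestinal",
    "liver/pancreas", "kidney/urinary", "reproductive", "endocrine", "cancer",
    "infection/parasites", "immune-mediated", "hematopoietic", "congenital",
    "toxin consumption", "trauma",
)

#: survey close used as the observation endpoint for onset dates
DEFAULT_SURVEY_MONTH = month_index("2021-12")


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal covariate distributions.

    Defaults are calibrated to the survey cohort's summaries: age ~ gamma with
    median ~7.3y (target median 7.75, IQR 4.08-11.00 — a two-parameter gamma
    cannot match the slightly left-skewed target quartiles exactly); weight ~
    log-normal least-squares calibrated to median 50.9 / IQR 25-69 lbs; sex
    mix 46.81% spayed F / 45.83% neutered M / 2.58% intact F / 4.79% intact M;
    breed background ~50/50.
    """

    age_shape: float = 2.3981
    age_scale: float = 3.5065
    age_min: float = 0.1
    age_max: float = 25.0
    weight_log_mean: float = 3.7943
    weight_log_sd: float = 0.7526
    weight_min: float = 2.0
    weight_max: float = 250.0
    sex_probs: tuple = (0.4681, 0.4583, 0.0258, 0.0479)  # order of SEX_CATEGORIES
    mixed_prob: float = 0.5

    def __post_init__(self):
        p = np.asarray(self.sex_probs, dtype=float)
        # printed survey percentages sum to 100.01%; accept rounding slack
        if len(p) != 4 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-3:
            raise ValueError("sex_probs must be 4 non-negative values summing to 1")
        object.__setattr__(self, "sex_probs", tuple(p / p.sum()))
        if not 0 <= self.mixed_prob <= 1:
            raise ValueError("mixed_prob must be a probability")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``coefficients`` is an (n_conditions, 7) array of true logistic
    coefficients in design order [intercept, age, weight, breed_mixed,
    sex contrasts vs spayed female]. ``planted_pairs`` are (y, z, delta>=0)
    triples adding ``delta`` to z's logit when the dog has y;
    ``planted_directions`` are (y, z, max_lag_months) forcing onset(z) =
    onset(y) + Uniform(0, max_lag). Every planted direction must also be a
    planted pair (ordering implies co-occurrence).
    """

    n_dogs: int
    n_conditions: int
    coefficients: np.ndarray
    covariates: CovariateSpec = CovariateSpec()
    planted_pairs: tuple = ()
    planted_directions: tuple = ()
    min_onset_age: float = 0.0
    survey_month: int = DEFAULT_SURVEY_MONTH
    seed: int = 0
    condition_names: tuple | None = None
    categories: tuple | None = None

    def __post_init__(self):
        if self.n_dogs < 1 or self.n_conditions < 1:
            raise ValueError("n_dogs and n_conditions must be >= 1")
        beta = np.asarray(self.coefficients, dtype=float)
        if beta.shape != (self.n_conditions, 7):
            raise ValueError(f"coefficients must have shape ({self.n_conditions}, 7)")
        if not np.all(np.isfinite(beta)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", beta)
        valid = set(range(self.n_conditions))
        for y, z, delta in self.planted_pairs:
            if y not in valid or z not in valid or y == z:
                raise ValueError(f"planted pair ({y},{z}) references invalid condition ids")
            if delta < 0:
                raise ValueError("planted pair delta must be >= 0")
        pair_set = {frozenset((y, z)) for y, z, _ in self.planted_pairs}
        for y, z, lag in self.planted_directions:
            if y not in valid or z not in valid or y == z:
                raise ValueError(f"planted direction ({y},{z}) references invalid ids")
            if lag <= 0:
                raise ValueError("planted direction max lag must be > 0")
            if frozenset((y, z)) not in pair_set:
                raise ValueError(
                    f"planted direction ({y},{z}) must also be a planted pair"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: recovery targets for tests."""

    coefficients: np.ndarray
    dependent_pairs: dict = field(default_factory=dict)   # frozenset({y,z}) -> delta
    directed_pairs: dict = field(default_factory=dict)    # (y, z) -> max_lag months
    seed: int = 0

    def is_planted(self, y, z) -> bool:
        return frozenset((y, z)) in self.dependent_pairs


def default_coefficients(
    n_conditions: int,
    seed: int = 0,
    prevalence_range: tuple = (0.05, 0.25),
    frac_age_positive: float = 0.8,
    covariates: CovariateSpec = CovariateSpec(),
) -> np.ndarray:
    """Realistic true coefficient matrix for a synthetic condition set.

    Age effects are positive for ``frac_age_positive`` of conditions (risk for
    most conditions rises with age), weight effects are small per-lb shifts,
    breed and sex effects are modest. Intercepts are solved so that each
    condition's approximate prevalence lands uniformly in
    ``prevalence_range`` at the covariate means.
    """
    rng = np.random.default_rng(seed)
    beta = np.zeros((n_conditions, 7))
    pos = rng.random(n_conditions) < frac_age_positive
    beta[:, 1] = np.where(pos, 1, -1) * rng.uniform(0.02, 0.12, n_conditions)
    beta[:, 2] = rng.normal(0.0, 0.004, n_conditions)
    beta[:, 3] = rng.normal(0.0, 0.25, n_conditions)
    beta[:, 4:7] = rng.normal(0.0, 0.15, (n_conditions, 3))
    target = rng.uniform(*prevalence_range, n_conditions)
    mean_age = covariates.age_shape * covariates.age_scale
    mean_weight = float(np.exp(covariates.weight_log_mean + covariates.weight_log_sd**2 / 2))
    sexp = np.asarray(covariates.sex_probs[1:])  # contrasts vs spayed female
    mean_x = np.array([1.0, mean_age, mean_weight, covariates.mixed_prob, *sexp])
    beta[:, 0] = logit(target) - beta[:, 1:] @ mean_x[1:]
    return beta


def default_catalog(n_conditions: int) -> pd.DataFrame:
    """Synthetic condition names with body-system categories assigned cyclically."""
    ids = np.arange(n_conditions)
    return pd.DataFrame(
        {
            "condition_id": ids,
            "condition_name": [f"condition_{i:03d}" for i in ids],
            "category": [BODY_SYSTEMS[i % len(BODY_SYSTEMS)] for i in ids],
        }
    )


def _draw_covariates(n: int, spec: CovariateSpec, rng) -> pd.DataFrame:
    age = np.clip(
        rng.gamma(spec.age_shape, spec.age_scale, n), spec.age_min, spec.age_max
    )
    weight = np.clip(
        np.exp(rng.normal(spec.weight_log_mean, spec.weight_log_sd, n)),
        spec.weight_min,
        spec.weight_max,
    )
    sex = rng.choice(np.asarray(SEX_CATEGORIES, dtype=object), size=n, p=spec.sex_probs)
    breed = np.where(rng.random(n) < spec.mixed_prob, "mixed", "purebred")
    return pd.DataFrame(
        {
            "id": [f"dog_{i:06d}" for i in range(n)],
            "age_years": np.round(age, 3),
            "weight_lbs": np.round(weight, 2),
            "sex": sex,
            "breed": breed,
        }
    )


def _condition_order(config: GeneratorConfig) -> list:
    """Topological order so a planted pair's source y is generated before z."""
    deps = {c: set() for c in range(config.n_conditions)}
    for y, z, _ in config.planted_pairs:
        deps[z].add(y)
    try:
        return list(TopologicalSorter(deps).static_order())
    except Exception as exc:  # CycleError
        raise ValueError(f"planted pairs must form a DAG: {exc}") from exc


def generate_cohort(config: GeneratorConfig) -> tuple:
    """Generate a cohort and its ground truth.

    Indicators are Bernoulli with logit(p) = x'beta plus the planted delta
    boosts; onset ages are uniform between ``min_onset_age`` and the dog's
    current age; planted directions overwrite onset(z) with onset(y) plus a
    Uniform(0, max_lag) month lag. Dogs with zero conditions are retained —
    the cohort module's inclusion filter removes them, as in the survey
    analysis. Identical config (including seed) reproduces the cohort exactly.
    """
    rng = np.random.default_rng(config.seed)
    dogs = _draw_covariates(config.n_dogs, config.covariates, rng)
    X = design_matrix(dogs).to_numpy()

    boosts = {}  # z -> list of (y, delta)
    for y, z, delta in config.planted_pairs:
        boosts.setdefault(z, []).append((y, delta))

    indicators = np.zeros((config.n_dogs, config.n_conditions), dtype=bool)
    for c in _condition_order(config):
        eta = X @ config.coefficients[c]
        for y, delta in boosts.get(c, ()):
            eta = eta + delta * indicators[:, y]
        indicators[:, c] = rng.random(config.n_dogs) < expit(eta)

    # onset dates: uniform onset age within [min_onset_age, current age]
    age = dogs["age_years"].to_numpy()
    onset = np.full((config.n_dogs, config.n_conditions), np.nan)
    for c in range(config.n_conditions):
        has = indicators[:, c]
        n_has = int(has.sum())
        if n_has == 0:
            continue
        lo = np.minimum(config.min_onset_age, age[has])
        onset_age = rng.uniform(lo, age[has])
        onset[has, c] = config.survey_month - np.round((age[has] - onset_age) * 12.0)

    for y, z, max_lag in config.planted_directions:
        both = indicators[:, y] & indicators[:, z]
        n_both = int(both.sum())
        if n_both == 0:
            continue
        lag = np.round(rng.uniform(0.0, max_lag, n_both))
        onset[both, z] = np.minimum(onset[both, y] + lag, config.survey_month)

    catalog = default_catalog(config.n_conditions)
    if config.condition_names is not None:
        catalog["condition_name"] = list(config.condition_names)
    if config.categories is not None:
        catalog["category"] = list(config.categories)
    names = catalog["condition_name"].to_numpy()
    cats = catalog["category"].to_numpy()

    d_idx, c_idx = np.nonzero(indicators)
    conditions = pd.DataFrame(
        {
            "dog_id": dogs["id"].to_numpy()[d_idx],
            "condition_id": c_idx,
            "condition_name": names[c_idx],
            "category": cats[c_idx],
            "onset_month": onset[d_idx, c_idx],
        }
    )
    truth = SyntheticTruth(
        coefficients=config.coefficients.copy(),
        dependent_pairs={frozenset((y, z)): d for y, z, d in config.planted_pairs},
        directed_pairs={(y, z): lag for y, z, lag in config.planted_directions},
        seed=config.seed,
    )
    return Cohort(dogs, conditions), truth


def null_cohort(config: GeneratorConfig) -> tuple:
    """Generate a cohort under the null: conditions independent given covariates."""
    if config.planted_pairs or config.planted_directions:
        raise ValueError("null_cohort requires empty planted_pairs and planted_directions")
    return generate_cohort(config)


def true_probability_matrix(config: GeneratorConfig, cohort: Cohort) -> np.ndarray:
    """(n_dogs, K) matrix of TRUE marginal per-dog probabilities (no planted
    boosts) — the oracle for calibration checks on null cohorts."""
    X = design_matrix(cohort.dogs).to_numpy()
    return expit(X @ config.coefficients.T)


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "coefficients": np.asarray(truth.coefficients).tolist(),
        "dependent_pairs": [
            {"pair": sorted(int(i) for i in k), "delta": float(v)}
            for k, v in sorted(truth.dependent_pairs.items(), key=lambda kv: sorted(kv[0]))
        ],
        "directed_pairs": [
            {"source": int(y), "target": int(z), "max_lag_months": float(l)}
            for (y, z), l in sorted(truth.directed_pairs.items())
        ],
        "seed": int(truth.seed),
        "terms": model_terms(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        dependent_pairs={
            frozenset(p["pair"]): p["delta"] for p in payload["dependent_pairs"]
        },
        directed_pairs={
            (p["source"], p["target"]): p["max_lag_months"]
            for p in payload["directed_pairs"]
        },
        seed=payload["seed"],
    )
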