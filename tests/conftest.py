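import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import comorbnet as cn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_cohort(dog_rows, condition_rows):
    """Hand-build a cohort from (id, age, weight, sex, breed) and
    (dog_id, condition_id, onset_month) tuples."""
    dogs = pd.DataFrame(dog_rows, columns=["id", "age_years", "weight_lbs", "sex", "breed"])
    cond = pd.DataFrame(condition_rows, columns=["dog_id", "condition_id", "onset_month"])
    cond["condition_name"] = cond["condition_id"].map(lambda c: f"condition_{c:03d}")
    cond["category"] = cond["condition_id"].map(lambda c: cn.synthetic.BODY_SYSTEMS[c % 20])
    return cn.Cohort(dogs, cond[["dog_id", "condition_id", "condition_name",
                                 "category", "onset_month"]])


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium cohort with one planted dependent+directed pair (0 -> 1)."""
    cfg = cn.GeneratorConfig(
        n_dogs=8000, n_conditions=6,
        coefficients=cn.default_coefficients(6, seed=11),
        planted_pairs=((0, 1, 1.5),),
        planted_directions=((0, 1, 6.0),),
        seed=11,
    )
    cohort, truth = cn.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def planted_models(planted_cohort):
    _, cohort, _ = planted_cohort
    included = cn.apply_inclusion_criteria(cohort, min_cases=60)
    models = cn.fit_all_models(included)
    return included, models


@pytest.fixture(scope="session")
def null_cohort_small():
    cfg = cn.GeneratorConfig(
        n_dogs=6000, n_conditions=6,
        coefficients=cn.default_coefficients(6, seed=23), seed=23,
    )
    cohort, truth = cn.null_cohort(cfg)
    return cfg, cohort, truth
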