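"""Per-condition logistic risk models.

One plain maximum-likelihood logistic regression per health condition:
indicator ~ intercept + age + weight + breed background + sex (4 categories,
3 contrasts against a reference). The fitted per-dog probabilities are the
plug-in inputs of the Poisson-binomial comorbidity test. No interactions, no
regularization — the minimum-case inclusion rule (one-in-ten heuristic, >= 60
cases for 6 predictors) is the overfitting guard.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import SEX_CATEGORIES, Cohort, Dog

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_SEX = "spayed female"

#: bound beyond which a fitted log-odds coefficient is treated as evidence of
#: (quasi-)separation and the model flagged non-converged
_SEPARATION_BOUND = 30.0


def model_terms(reference_sex: str = DEFAULT_REFERENCE_SEX) -> list:
    """Design-matrix column names: intercept + 6 predictors."""
    if reference_sex not in SEX_CATEGORIES:
        raise ValueError(f"unknown reference sex {reference_sex!r}")
    contrasts = [s for s in SEX_CATEGORIES if s != reference_sex]
    return ["intercept", "age", "weight", "breed_mixed"] + [f"sex:{s}" for s in contrasts]


def design_matrix(dogs: pd.DataFrame, reference_sex: str = DEFAULT_REFERENCE_SEX) -> pd.DataFrame:
    """(n, 7) design matrix: intercept, age (years), weight (lbs), mixed-breed
    indicator, and three sex-category indicators vs ``reference_sex``."""
    terms = model_terms(reference_sex)
    X = pd.DataFrame(index=dogs.index)
    X["intercept"] = 1.0
    X["age"] = dogs["age_years"].astype(float)
    X["weight"] = dogs["weight_lbs"].astype(float)
    X["breed_mixed"] = (dogs["breed"] == "mixed").astype(float)
    for t in terms[4:]:
        X[t] = (dogs["sex"] == t.split(":", 1)[1]).astype(float)
    if X.isna().any().any():
        raise ValueError("missing covariate values")
    return X[terms]


@dataclass
class RiskModel:
    """Fitted logistic model for one condition."""

    condition_id: object
    terms: list
    params: np.ndarray          # beta0..beta6
    bse: np.ndarray             # Wald standard errors
    pvalues: np.ndarray         # Wald p-values
    converged: bool
    n_cases: int
    n_obs: int
    reference_sex: str = DEFAULT_REFERENCE_SEX

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.params

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))


def _fit(condition_id, y: np.ndarray, X: np.ndarray, terms, reference_sex) -> RiskModel:
    y = np.asarray(y, dtype=float)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise ValueError(
            f"condition {condition_id}: outcome is constant ({n_cases}/{len(y)} cases)"
        )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=100)
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            pvalues = np.asarray(res.pvalues, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # separation / singular Hessian
            params = np.full(X.shape[1], np.nan)
            bse = np.full(X.shape[1], np.nan)
            pvalues = np.full(X.shape[1], np.nan)
            converged = False
    if converged and (not np.all(np.isfinite(params)) or np.max(np.abs(params)) > _SEPARATION_BOUND):
        converged = False
    if not converged:
        logger.warning("condition %s: logistic fit did not converge (flagged)", condition_id)
    return RiskModel(
        condition_id=condition_id,
        terms=list(terms),
        params=params,
        bse=bse,
        pvalues=pvalues,
        converged=converged,
        n_cases=n_cases,
        n_obs=len(y),
        reference_sex=reference_sex,
    )


def fit_condition_model(
    cohort: Cohort, condition_id, reference_sex: str = DEFAULT_REFERENCE_SEX
) -> RiskModel:
    """Fit the logistic model for a single condition."""
    ind, ids = cohort.indicator_matrix([condition_id])
    X = design_matrix(cohort.dogs, reference_sex)
    return _fit(condition_id, ind[:, 0], X.to_numpy(), X.columns, reference_sex)


def fit_all_models(
    cohort: Cohort,
    condition_ids=None,
    reference_sex: str = DEFAULT_REFERENCE_SEX,
) -> dict:
    """Fit one model per condition (design matrix built once); returns an
    ordered mapping condition_id -> RiskModel including non-converged fits."""
    ind, ids = cohort.indicator_matrix(condition_ids)
    X = design_matrix(cohort.dogs, reference_sex)
    Xv = X.to_numpy()
    return {
        c: _fit(c, ind[:, j], Xv, X.columns, reference_sex) for j, c in enumerate(ids)
    }


def predict_probability(model: RiskModel, dog: Dog) -> float:
    """Inverse-logit of the dog's linear predictor; strictly inside (0, 1)."""
    if not model.converged:
        raise ValueError(f"model for condition {model.condition_id} did not converge")
    x = [1.0, dog.age, dog.weight, 1.0 if dog.breed_background == "mixed" else 0.0]
    for t in model.terms[4:]:
        x.append(1.0 if dog.sex == t.split(":", 1)[1] else 0.0)
    return float(expit(np.dot(x, model.params)))


def probability_matrix(models, cohort: Cohort) -> tuple:
    """(n_dogs, K) matrix of fitted probabilities for the converged models.

    Returns ``(P, condition_ids)``; non-converged models are dropped (they are
    excluded from all pairwise testing downstream).
    """
    models = list(models.values()) if isinstance(models, dict) else list(models)
    converged = [m for m in models if m.converged]
    if not converged:
        raise ValueError("no converged models")
    ref = converged[0].reference_sex
    X = design_matrix(cohort.dogs, ref).to_numpy()
    P = np.column_stack([m.predict(X) for m in converged])
    return P, [m.condition_id for m in converged]


@dataclass
class CoefficientSummary:
    """Counts of significant coefficients per covariate, with sign breakdown."""

    by_term: pd.DataFrame       # term, n_models, n_significant, frac_positive_significant
    by_category: pd.DataFrame   # term x category significant counts

    def fraction_positive(self, term: str) -> float:
        row = self.by_term.set_index("term").loc[term]
        return float(row["frac_positive_significant"])


def summarize_coefficients(
    models, catalog: pd.DataFrame | None = None, alpha: float = 0.05
) -> CoefficientSummary:
    """Summarize Wald significance and sign of each covariate across models."""
    models = list(models.values()) if isinstance(models, dict) else list(models)
    models = [m for m in models if m.converged]
    if not models:
        raise ValueError("no converged models to summarize")
    cat_map = {}
    if catalog is not None:
        cat_map = dict(zip(catalog["condition_id"], catalog["category"]))
    rows, cat_rows = [], []
    terms = models[0].terms
    for j, t in enumerate(terms):
        if t == "intercept":
            continue
        sig = np.array([m.pvalues[j] < alpha for m in models])
        pos = np.array([m.params[j] > 0 for m in models])
        n_sig = int(sig.sum())
        rows.append(
            {
                "term": t,
                "n_models": len(models),
                "n_significant": n_sig,
                "frac_positive_significant": float(pos[sig].mean()) if n_sig else np.nan,
            }
        )
        for m, s, p in zip(models, sig, pos):
            if s and cat_map:
                cat_rows.append({"term": t, "category": cat_map.get(m.condition_id, "unknown"),
                                 "positive": bool(p)})
    by_cat = (
        pd.DataFrame(cat_rows).groupby(["term", "category"]).agg(
            n_significant=("positive", "size"), n_positive=("positive", "sum")
        ).reset_index()
        if cat_rows
        else pd.DataFrame(columns=["term", "category", "n_significant", "n_positive"])
    )
    return CoefficientSummary(by_term=pd.DataFrame(rows), by_category=by_cat)


def export_coefficients(models) -> pd.DataFrame:
    """Tidy coefficient table (condition_id, term, estimate, se, p, converged)."""
    models = list(models.values()) if isinstance(models, dict) else list(models)
    rows = []
    for m in models:
        for j, t in enumerate(m.terms):
            rows.append(
                {
                    "condition_id": m.condition_id,
                    "term": t,
                    "estimate": m.params[j],
                    "se": m.bse[j],
                    "p": m.pvalues[j],
                    "converged": m.converged,
                }
            )
    return pd.DataFrame(rows)
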