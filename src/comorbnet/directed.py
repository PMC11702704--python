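"""Time-directed comorbidity testing.

For an ordered condition pair y -> z the test asks whether, among dogs that
have both conditions with dated onsets, y's onset precedes z's onset within a
window of W months more often than chance. Under the null, for each eligible
dog the probability of the directed-in-window event is the product of

* the direction term  p_y / (p_y + p_z)  (which condition comes first,
  from the fitted marginal probabilities), and
* the window term  (W/S)(2 - W/S) for span S > W, else 1  (the chance two
  uniform onsets on the dog's medical-history span fall within W months),

and the count of dogs realizing the event is Poisson-binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, medical_history_spans
from .pbc import bonferroni, pbc_pvalue
from .risk import probability_matrix

DEFAULT_WINDOW_MONTHS = 12.0


def direction_probability(p_y, p_z):
    """P(y's onset precedes z's | dog has both) = p_y / (p_y + p_z)."""
    p_y = np.asarray(p_y, dtype=float)
    p_z = np.asarray(p_z, dtype=float)
    tot = p_y + p_z
    if (tot <= 0).any():
        raise ValueError("p_y + p_z must be positive")
    out = p_y / tot
    return float(out) if out.ndim == 0 else out


def window_probability(span, w):
    """P(two uniform onsets on a span of S months fall within W months):
    (W/S)(2 - W/S) if S > W, else 1."""
    span = np.asarray(span, dtype=float)
    w = float(w)
    if w <= 0:
        raise ValueError("window W must be positive")
    if (span < 0).any():
        raise ValueError("span must be non-negative")
    with np.errstate(all="ignore"):
        ratio = w / np.where(span > 0, span, 1.0)
        out = np.where(span > w, ratio * (2.0 - ratio), 1.0)
    return float(out) if out.ndim == 0 else out


def directed_event_probability(p_y, p_z, span, w):
    """Per-dog probability that y occurs within W months before z."""
    return direction_probability(p_y, p_z) * window_probability(span, w)


def observed_directed_count(cohort: Cohort, y, z, w: float = DEFAULT_WINDOW_MONTHS) -> tuple:
    """(eligible, k_dir): dogs with both conditions dated, and those with
    onset(y) strictly before onset(z) and a gap <= W months.

    Same-month onsets are ties — counted in neither direction (month
    resolution cannot order them).
    """
    if y == z:
        raise ValueError("y and z must differ")
    if w <= 0:
        raise ValueError("window W must be positive")
    onsets, _ = cohort.onset_matrix([y, z])
    both = ~np.isnan(onsets).any(axis=1)
    gap = onsets[both, 1] - onsets[both, 0]
    k_dir = int(((gap > 0) & (gap <= w)).sum())
    return int(both.sum()), k_dir


def pairwise_directed(
    cohort: Cohort,
    models,
    w: float = DEFAULT_WINDOW_MONTHS,
    alpha: float = 0.01,
    span_mode: str = "history",
    probabilities: np.ndarray | None = None,
    condition_ids=None,
) -> pd.DataFrame:
    """Directed scan over all ordered pairs of (converged-model) conditions.

    For each ordered pair (y, z) with at least one eligible dog (both
    conditions present, both onsets dated), per-eligible-dog directed-event
    probabilities are combined into Poisson-binomial moments and an
    upper-tail P-value on k_dir; Bonferroni uses m = number of ordered tests
    actually performed (2 per tested unordered pair). The full table is
    returned regardless of significance.

    ``span_mode="history"`` uses each dog's whole medical-history span in the
    window term (the default proxy); ``"pair"`` uses the pair's own onset gap.
    """
    if w <= 0:
        raise ValueError("window W must be positive")
    if span_mode not in ("history", "pair"):
        raise ValueError("span_mode must be 'history' or 'pair'")
    if probabilities is None:
        P, ids = probability_matrix(models, cohort)
    else:
        P, ids = np.asarray(probabilities, dtype=float), list(condition_ids)
    K = len(ids)
    if K < 2:
        raise ValueError("need at least 2 conditions")
    onsets, _ = cohort.onset_matrix(ids)
    if np.isnan(onsets).all():
        raise ValueError("no dated onsets in cohort")
    spans = medical_history_spans(cohort)
    span_vec = spans.reindex(cohort.dogs["id"]).to_numpy(dtype=float)
    catalog = cohort.catalog.set_index("condition_id")

    rows = []
    for i in range(K):
        for j in range(i + 1, K):
            eligible = ~np.isnan(onsets[:, i]) & ~np.isnan(onsets[:, j])
            n_elig = int(eligible.sum())
            for (a, b) in ((i, j), (j, i)):
                row = {
                    "source": ids[a],
                    "target": ids[b],
                    "name_source": catalog["condition_name"].get(ids[a]),
                    "name_target": catalog["condition_name"].get(ids[b]),
                    "category_source": catalog["category"].get(ids[a]),
                    "category_target": catalog["category"].get(ids[b]),
                    "window_months": w,
                    "eligible": n_elig,
                }
                if n_elig == 0:
                    row.update(observed=0, expected=np.nan, variance=np.nan,
                               statistic=np.nan, p_raw=np.nan)
                else:
                    gap = onsets[eligible, b] - onsets[eligible, a]
                    k_dir = int(((gap > 0) & (gap <= w)).sum())
                    if span_mode == "history":
                        s = span_vec[eligible]
                    else:
                        s = np.abs(gap)
                    q = directed_event_probability(
                        P[eligible, a], P[eligible, b], s, w
                    )
                    mu = float(q.sum())
                    var = float((q * (1 - q)).sum())
                    skew = float((q * (1 - q) * (1 - 2 * q)).sum())
                    if var > 0:
                        p_raw = pbc_pvalue(k_dir, mu, var, skew=skew)
                        stat = (k_dir - mu) / np.sqrt(var)
                    else:
                        p_raw, stat = np.nan, np.nan
                    row.update(observed=k_dir, expected=mu, variance=var,
                               statistic=stat, p_raw=p_raw)
                rows.append(row)

    table = pd.DataFrame(rows)
    tested = table["p_raw"].notna()
    m_tests = int(tested.sum())
    table["p_adjusted"] = np.nan
    if m_tests:
        table.loc[tested, "p_adjusted"] = bonferroni(table.loc[tested, "p_raw"], m_tests)
    table["included"] = (
        tested
        & (table["p_adjusted"] < alpha)
        & (table["observed"] > table["expected"])
    )
    table.attrs["n_tests"] = m_tests
    table.attrs["alpha"] = alpha
    table.attrs["window_months"] = w
    return table
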