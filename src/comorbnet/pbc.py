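"""Poisson-binomial comorbidity (PBC) test, undirected variant.

Under the null that two conditions y, z occur independently given covariates,
each dog d co-develops both with probability P{y,z in d} = P(y in d) P(z in d)
(the product of its fitted per-condition probabilities), so the number of
dogs with both conditions is Poisson-binomial. The test compares the observed
co-occurrence count with that null via an upper-tail P-value.

Tail evaluation defaults to the refined normal approximation (continuity
correction plus an Edgeworth skewness term), which tracks the exact
dynamic-programming tail to < 0.01 absolute even at n = 15; the plain normal
tail is available via ``skew=0.0, continuity=False``. An exact convolution
oracle is provided for small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .risk import probability_matrix

#: documented size limit for the O(n^2) exact convolution oracle
EXACT_TAIL_LIMIT = 5000


def joint_probability(p_y, p_z):
    """Per-dog probability of having both conditions: the product p_y * p_z."""
    p_y = np.asarray(p_y, dtype=float)
    p_z = np.asarray(p_z, dtype=float)
    if ((p_y < 0) | (p_y > 1) | (p_z < 0) | (p_z > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    out = p_y * p_z
    return float(out) if out.ndim == 0 else out


def pbc_moments(joint_probs) -> tuple:
    """Mean and variance of the Poisson-binomial co-occurrence count:
    mu = sum p, sigma^2 = sum p(1-p)."""
    p = np.asarray(joint_probs, dtype=float)
    if p.size == 0:
        warnings.warn("empty probability sequence; moments are (0, 0)")
        return 0.0, 0.0
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    return float(p.sum()), float((p * (1 - p)).sum())


def pbc_skew_term(joint_probs) -> float:
    """Third central moment sum p(1-p)(1-2p), used by the refined tail."""
    p = np.asarray(joint_probs, dtype=float)
    return float((p * (1 - p) * (1 - 2 * p)).sum())


def pbc_pvalue(k, mu, var, tail: str = "upper", *, skew: float = 0.0,
               continuity: bool = True):
    """Normal-approximation tail probability of the Poisson-binomial count.

    ``tail="upper"`` gives P(X >= k), ``"lower"`` gives P(X <= k). With the
    default continuity correction the evaluation point is k -/+ 0.5; passing
    the third-central-moment term via ``skew`` adds the Edgeworth skewness
    refinement. ``skew=0.0, continuity=False`` is the plain normal tail
    (symmetric: k = mu gives 0.5).
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if (var <= 0).any():
        raise ValueError("variance must be positive (degenerate null)")
    sd = np.sqrt(var)
    gamma = np.asarray(skew, dtype=float) / sd**3
    if tail == "upper":
        x = (k - (0.5 if continuity else 0.0) - mu) / sd
        G = stats.norm.cdf(x) + gamma * (1 - x * x) * stats.norm.pdf(x) / 6.0
        p = 1.0 - G
    elif tail == "lower":
        x = (k + (0.5 if continuity else 0.0) - mu) / sd
        p = stats.norm.cdf(x) + gamma * (1 - x * x) * stats.norm.pdf(x) / 6.0
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def exact_poisson_binomial_tail(probs, k: int) -> float:
    """Exact P(X >= k) for a Poisson-binomial count by dynamic-programming
    convolution; O(n^2), limited to n <= EXACT_TAIL_LIMIT."""
    p = np.asarray(probs, dtype=float)
    n = p.size
    if n > EXACT_TAIL_LIMIT:
        raise ValueError(f"exact tail limited to n <= {EXACT_TAIL_LIMIT}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    if k < 0 or k > n:
        raise ValueError(f"k must be in [0, {n}]")
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1:i + 2] = pmf[1:i + 2] * (1 - pi) + pmf[:i + 1] * pi
        pmf[0] *= 1 - pi
    return float(pmf[int(k):].sum())


def pearson_sign(indicator_y, indicator_z) -> float:
    """Pearson correlation of two binary indicator vectors (the sign check)."""
    y = np.asarray(indicator_y, dtype=float)
    z = np.asarray(indicator_z, dtype=float)
    if y.shape != z.shape:
        raise ValueError("indicator vectors must have equal length")
    if y.std() == 0 or z.std() == 0:
        raise ValueError("constant indicator: correlation undefined")
    return float(np.corrcoef(y, z)[0, 1])


@dataclass(frozen=True)
class BaselineResult:
    """Unadjusted binomial co-occurrence test (population incidence product)."""

    pair: tuple
    expected: float
    p_value: float


def binomial_baseline(counts: tuple, k: int, pair: tuple = (None, None)) -> BaselineResult:
    """Covariate-blind baseline: expected co-occurrence N (Cy/N)(Cz/N) and the
    upper-tail binomial P-value P(X >= k) at success probability CyCz/N^2."""
    c_y, c_z, n = counts
    if n <= 0:
        raise ValueError("N must be positive")
    if not (0 <= c_y <= n and 0 <= c_z <= n):
        raise ValueError("case counts must be in [0, N]")
    q = (c_y / n) * (c_z / n)
    expected = n * q
    p = float(stats.binom.sf(k - 1, n, q))
    return BaselineResult(pair=pair, expected=float(expected), p_value=p)


def bonferroni(p_raw, m: int):
    """Bonferroni family-wise adjustment: min(1, m * p)."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * m)


def pairwise_comorbidity(
    cohort: Cohort,
    models,
    alpha: float = 0.001,
    probabilities: np.ndarray | None = None,
    condition_ids=None,
) -> pd.DataFrame:
    """Scan all unordered pairs of (converged-model) conditions.

    For every pair: observed co-occurrence count over ALL included dogs,
    Poisson-binomial mean/variance from the per-dog joint probabilities,
    refined-normal upper-tail p_raw, Bonferroni p_adjusted with m = C(K, 2),
    Pearson indicator correlation, and the inclusion flag
    ``p_adjusted < alpha AND pearson_r > 0 AND observed > expected``. The full
    table is returned regardless of significance.

    ``probabilities`` (n_dogs x K, matching ``condition_ids``) may be supplied
    to skip refitting; otherwise they come from the fitted models.
    """
    if probabilities is None:
        P, ids = probability_matrix(models, cohort)
    else:
        P, ids = np.asarray(probabilities, dtype=float), list(condition_ids)
    K = len(ids)
    if K < 2:
        raise ValueError("need at least 2 conditions to test pairs")
    X, _ = cohort.indicator_matrix(ids)
    Xf = X.astype(float)

    k_mat = Xf.T @ Xf                      # observed co-occurrence counts
    M1 = P.T @ P                           # mu
    P2 = P * P
    S2 = P2.T @ P2                         # sum (p_y p_z)^2
    P3 = P2 * P
    S3 = P3.T @ P3                         # sum (p_y p_z)^3
    var = M1 - S2
    skew = M1 - 3 * S2 + 2 * S3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R = np.corrcoef(Xf.T)

    catalog = cohort.catalog.set_index("condition_id")
    m_tests = comb(K, 2)
    iu, ju = np.triu_indices(K, k=1)
    k_obs = k_mat[iu, ju]
    mu = M1[iu, ju]
    v = var[iu, ju]
    ok = v > 0
    p_raw = np.ones_like(mu)
    p_raw[ok] = pbc_pvalue(k_obs[ok], mu[ok], v[ok], skew=skew[iu, ju][ok])
    p_adj = bonferroni(p_raw, m_tests)
    r = R[iu, ju]
    with np.errstate(invalid="ignore"):
        included = (p_adj < alpha) & (r > 0) & (k_obs > mu) & ok

    ids_arr = np.asarray(ids, dtype=object)
    table = pd.DataFrame(
        {
            "condition_y": ids_arr[iu],
            "condition_z": ids_arr[ju],
            "name_y": catalog["condition_name"].reindex(ids_arr[iu]).to_numpy(),
            "name_z": catalog["condition_name"].reindex(ids_arr[ju]).to_numpy(),
            "category_y": catalog["category"].reindex(ids_arr[iu]).to_numpy(),
            "category_z": catalog["category"].reindex(ids_arr[ju]).to_numpy(),
            "observed": k_obs.astype(int),
            "expected": mu,
            "variance": v,
            "statistic": np.where(v > 0, (k_obs - mu) / np.sqrt(np.where(v > 0, v, 1.0)), np.nan),
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "pearson_r": r,
            "included": included,
        }
    )
    table.attrs["n_tests"] = m_tests
    table.attrs["alpha"] = alpha
    return table
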