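"""Poisson-binomial comorbidity test: moments, tails, scan behavior."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import comorbnet as cn
from comorbnet.pbc import bonferroni


def brute_force_tail(probs, k):
    """P(X >= k) by full outcome enumeration (oracle, n <= 12)."""
    total = 0.0
    n = len(probs)
    for bits in itertools.product([0, 1], repeat=n):
        if sum(bits) >= k:
            pr = 1.0
            for b, p in zip(bits, probs):
                pr *= p if b else 1 - p
            total += pr
    return total


class TestJointProbability:
    def test_examples(self):
        assert cn.joint_probability(0.5, 0.5) == 0.25
        assert cn.joint_probability(0.0, 0.7) == 0.0
        assert cn.joint_probability(0.2, 0.3) == pytest.approx(0.06)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            cn.joint_probability(1.2, 0.5)


class TestMoments:
    def test_examples(self):
        assert cn.pbc_moments([0.25, 0.25]) == (0.5, 0.375)
        assert cn.pbc_moments([0.0, 0.0]) == (0.0, 0.0)

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert cn.pbc_moments([]) == (0.0, 0.0)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 1000)
        mu, var = cn.pbc_moments(p)
        draws = (rng.random((4000, 1000)) < p).sum(axis=1)
        se_mean = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - mu) < 3 * se_mean
        assert abs(draws.var() - var) < 4 * var / np.sqrt(len(draws))


class TestExactTail:
    def test_examples(self):
        assert cn.exact_poisson_binomial_tail([0.5, 0.5], 2) == pytest.approx(0.25)
        assert cn.exact_poisson_binomial_tail([0.3, 0.9, 0.2], 0) == 1.0
        assert cn.exact_poisson_binomial_tail([0.1, 0.2, 0.3], 1) == pytest.approx(0.496)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            p = rng.uniform(0, 1, 8)
            for k in range(9):
                assert cn.exact_poisson_binomial_tail(p, k) == pytest.approx(
                    brute_force_tail(p, k), abs=1e-12)

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            cn.exact_poisson_binomial_tail([0.5], 2)
        with pytest.raises(ValueError):
            cn.exact_poisson_binomial_tail([0.5], -1)


class TestPValue:
    def test_plain_normal_symmetry_at_mean(self):
        assert cn.pbc_pvalue(10.0, 10.0, 4.0, skew=0.0, continuity=False) == 0.5

    def test_plain_normal_quantile(self):
        sd = 3.0
        p = cn.pbc_pvalue(10 + 1.959964 * sd, 10.0, sd**2, skew=0.0, continuity=False)
        assert p == pytest.approx(0.025, abs=1e-6)

    def test_lower_tail_complements_upper(self):
        up = cn.pbc_pvalue(12, 10, 4, skew=0.0, continuity=False)
        lo = cn.pbc_pvalue(12, 10, 4, tail="lower", skew=0.0, continuity=False)
        assert up + lo == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            cn.pbc_pvalue(1, 1.0, 0.0)

    def test_refined_tail_tracks_exact_small_n(self):
        """Refined normal approximation within 0.02 of the exact tail at n=15."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0.05, 0.5, 15)
            mu, var = cn.pbc_moments(p)
            skew = cn.pbc_skew_term(p)
            for k in range(16):
                approx = cn.pbc_pvalue(k, mu, var, skew=skew)
                exact = cn.exact_poisson_binomial_tail(p, k)
                assert abs(approx - exact) <= 0.02

    def test_refined_tail_tracks_exact_mu_at_least_5(self):
        """For n <= 500 and mu >= 5 the approximation stays within 0.02."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(50, 500))
            p = rng.uniform(0.02, 0.4, n)
            mu, var = cn.pbc_moments(p)
            assert mu >= 5
            skew = cn.pbc_skew_term(p)
            for k in range(0, n + 1, max(1, n // 40)):
                assert abs(cn.pbc_pvalue(k, mu, var, skew=skew)
                           - cn.exact_poisson_binomial_tail(p, k)) <= 0.02


class TestPearsonSign:
    def test_examples(self):
        assert cn.pearson_sign([1, 0, 1, 1], [1, 0, 1, 1]) == pytest.approx(1.0)
        assert cn.pearson_sign([1, 0, 1, 0], [0, 1, 0, 1]) == pytest.approx(-1.0)

    def test_independent_vectors_small_r(self):
        rng = np.random.default_rng(0)
        a = rng.random(10000) < 0.3
        b = rng.random(10000) < 0.4
        assert abs(cn.pearson_sign(a, b)) < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            cn.pearson_sign([1, 1, 1], [0, 1, 0])


class TestBinomialBaseline:
    def test_expected_count(self):
        res = cn.binomial_baseline((10, 20, 100), 5)
        assert res.expected == pytest.approx(2.0)

    def test_degenerate_full_overlap(self):
        res = cn.binomial_baseline((50, 50, 50), 50)
        assert res.expected == pytest.approx(50.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_summation(self):
        from math import comb
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(10, 40))
            cy, cz = rng.integers(0, n + 1, 2)
            k = int(rng.integers(0, n + 1))
            q = (cy / n) * (cz / n)
            brute = sum(comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(k, n + 1))
            assert cn.binomial_baseline((cy, cz, n), k).p_value == pytest.approx(brute, abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError):
            cn.binomial_baseline((1, 1, 0), 0)


@given(p=st.floats(0, 1), m=st.integers(1, 1000))
def test_bonferroni_bounds(p, m):
    adj = float(bonferroni(p, m))
    assert p <= adj <= 1.0


class TestPairwiseScan:
    def test_copied_condition_is_extreme_and_included(self, planted_models):
        cohort, _ = planted_models
        twin = cohort.conditions[cohort.conditions["condition_id"] == 0].copy()
        twin["condition_id"] = 99
        twin["condition_name"] = "condition_copy"
        import pandas as pd
        cohort2 = cn.Cohort(cohort.dogs.copy(),
                            pd.concat([cohort.conditions, twin], ignore_index=True))
        models = cn.fit_all_models(cohort2)
        edges = cn.pairwise_comorbidity(cohort2, models)
        row = edges[(edges.condition_y == 0) & (edges.condition_z == 99)].iloc[0]
        c0 = int((cohort2.conditions["condition_id"] == 0).sum())
        assert row.observed == c0
        assert row.statistic > 10
        assert row.included

    def test_invariants_on_scan(self, planted_models):
        cohort, models = planted_models
        edges = cn.pairwise_comorbidity(cohort, models)
        counts = cohort.catalog.set_index("condition_id")["n_cases"]
        for r in edges.itertuples():
            assert 0 <= r.observed <= min(counts[r.condition_y], counts[r.condition_z])
            assert r.variance <= r.expected + 1e-9
            assert 0 <= r.p_raw <= 1
            assert r.p_adjusted >= r.p_raw - 1e-12
        assert edges.attrs["n_tests"] == len(edges)

    def test_permutation_invariance(self, planted_models):
        cohort, _ = planted_models
        rng = np.random.default_rng(1)
        perm = rng.permutation(cohort.n_dogs)
        shuffled = cn.Cohort(cohort.dogs.iloc[perm].reset_index(drop=True),
                             cohort.conditions.sample(frac=1, random_state=2),
                             list(cohort.filter_log))
        a = cn.pairwise_comorbidity(cohort, cn.fit_all_models(cohort))
        b = cn.pairwise_comorbidity(shuffled, cn.fit_all_models(shuffled))
        key = ["condition_y", "condition_z"]
        a = a.sort_values(key, ignore_index=True)
        b = b.sort_values(key, ignore_index=True)
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], rtol=1e-8)

    def test_planted_pair_detected(self, planted_models, planted_cohort):
        cohort, models = planted_models
        _, _, truth = planted_cohort
        edges = cn.pairwise_comorbidity(cohort, models)
        for pair in truth.dependent_pairs:
            y, z = sorted(pair)
            row = edges[(edges.condition_y == y) & (edges.condition_z == z)].iloc[0]
            assert row.included

    def test_needs_two_conditions(self, planted_models):
        cohort, models = planted_models
        with pytest.raises(ValueError):
            cn.pairwise_comorbidity(cohort, {0: models[0]})


def test_confounded_pair_flagged_by_baseline_not_pbc():
    """Two conditions sharing a strong age effect but conditionally
    independent: the covariate-blind binomial test fires, the adjusted
    Poisson-binomial test does not."""
    beta = np.zeros((2, 7))
    beta[:, 1] = 0.25                             # strong shared age effect
    beta[:, 0] = -1.8 - 0.25 * 8.4                # prevalence ~0.15 at mean age
    cfg = cn.GeneratorConfig(n_dogs=10000, n_conditions=2,
                             coefficients=beta, seed=6)
    cohort, _ = cn.null_cohort(cfg)
    ind, _ = cohort.indicator_matrix([0, 1])
    k = int(np.sum(ind[:, 0] & ind[:, 1]))
    base = cn.binomial_baseline((int(ind[:, 0].sum()), int(ind[:, 1].sum()),
                                 cohort.n_dogs), k)
    assert base.p_value < 0.001
    models = cn.fit_all_models(cohort)
    edges = cn.pairwise_comorbidity(cohort, models)
    assert edges.iloc[0]["p_raw"] > 0.05
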