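import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from htnprs._glmm import SeparationError, fit_logistic_ml, pql_kinship
from htnprs.assoc import (
    ancestry_strata,
    assign_deciles,
    cochran_q,
    compute_auc,
    decile_trend,
    fit_logistic,
    stratum_effects_joint,
    top_bottom_decile_or,
)
from htnprs.genodata import KinshipGraph


class TestFitLogistic:
    def test_two_by_two_table_matches_cross_product_ratio(self):
        # exposed: 20 cases / 10 controls; unexposed: 10 cases / 20 controls
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [20, 10, 10, 20])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [20, 10, 10, 20])
        est = fit_logistic(y, x)
        assert est.beta == pytest.approx(np.log(4.0), abs=1e-8)

    def test_wald_interface(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(500)
        y = (rng.random(500) < expit(0.8 * z)).astype(float)
        est = fit_logistic(y, z)
        assert est.or_point == pytest.approx(np.exp(est.beta))
        lo, hi = est.ci
        assert lo == pytest.approx(np.exp(est.beta - 1.959963984540054 * est.se))
        assert lo < est.or_point < hi

    def test_null_betas_rarely_exceed_three_se(self):
        rng = np.random.default_rng(42)
        n, hits = 2000, 0
        reps = 60
        for _ in range(reps):
            z = rng.standard_normal(n)
            y = (rng.random(n) < 0.4).astype(float)
            est = fit_logistic(y, z)
            hits += abs(est.beta) < 3 * est.se
        assert hits >= reps - 1

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(20), np.random.default_rng(0).standard_normal(20))

    def test_covariates_with_factors_and_missing(self):
        rng = np.random.default_rng(3)
        n = 300
        z = rng.standard_normal(n)
        covars = pd.DataFrame(
            {
                "age": rng.uniform(30, 70, n),
                "site": rng.choice(["a", "b"], n),
                "constant_col": np.ones(n),
            }
        )
        covars.loc[:4, "age"] = np.nan
        y = (rng.random(n) < expit(0.5 * z)).astype(float)
        est = fit_logistic(y, z, covars)
        assert est.n == n - 5

    def test_kinship_variance_zero_matches_plain_logistic(self):
        rng = np.random.default_rng(5)
        n = 150
        ids = [f"s{i}" for i in range(n)]
        kin = KinshipGraph.from_pairs([(ids[0], ids[1], 0.25), (ids[2], ids[3], 0.25)], ids)
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.7 * z)).astype(float)
        plain = fit_logistic(y, z)
        mixed = fit_logistic(y, z, kinship=kin, sample_ids=ids, variance_component=0.0)
        assert mixed.beta == pytest.approx(plain.beta, abs=1e-6)
        assert mixed.se == pytest.approx(plain.se, abs=1e-6)

    def test_kinship_model_profiles_variance(self):
        rng = np.random.default_rng(6)
        n = 200
        ids = [f"s{i}" for i in range(n)]
        pairs = [(ids[i], ids[i + 1], 0.25) for i in range(0, 60, 2)]
        kin = KinshipGraph.from_pairs(pairs, ids)
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.6 * z)).astype(float)
        est = fit_logistic(y, z, kinship=kin, sample_ids=ids)
        assert np.isfinite(est.beta) and est.se > 0
        assert est.sigma2 >= 0


class TestSeparation:
    def test_separation_raises(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic_ml(np.column_stack([np.ones(40), x]), y)


def brute_force_auc(y, s):
    cases = s[y == 1]
    controls = s[y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestComputeAuc:
    def test_perfect_separation_gives_one(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.2, 0.1])
        assert compute_auc(y, s) == 1.0

    def test_hand_example(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.3, 0.4, 0.1])
        assert compute_auc(y, s) == pytest.approx(0.75)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n).astype(float)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            assert compute_auc(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_null_score_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 1000).astype(float)
        s = rng.standard_normal(1000)
        assert abs(compute_auc(y, s) - 0.5) < 0.05

    def test_unrelated_restriction_and_edge_check(self):
        ids = ["a", "b", "c", "d"]
        kin = KinshipGraph.from_pairs([("a", "b", 0.25)], ids)
        y = np.array([1, 0, 1, 0])
        s = np.array([0.9, 0.1, 0.8, 0.2])
        auc = compute_auc(y, s, unrelated={"a", "c", "d"}, sample_ids=ids, kinship=kin)
        assert auc == 1.0
        with pytest.raises(ValueError):
            compute_auc(y, s, unrelated={"a", "b"}, sample_ids=ids, kinship=kin)

    def test_one_class_empty_errors(self):
        with pytest.raises(ValueError):
            compute_auc(np.ones(5), np.arange(5.0))


class TestCochranQ:
    def test_identical_betas_give_zero(self):
        q, df, p = cochran_q(np.array([0.2, 0.2, 0.2]), np.diag([0.01, 0.02, 0.03]))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_hand_computed_two_strata(self):
        q, df, p = cochran_q(np.array([0.1, 0.3]), np.diag([0.01, 0.01]))
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_diagonal_matches_textbook_fixed_effects_q(self):
        rng = np.random.default_rng(0)
        betas = rng.normal(0.3, 0.1, 4)
        ses = rng.uniform(0.05, 0.2, 4)
        w = 1 / ses**2
        pooled = np.sum(w * betas) / np.sum(w)
        q_textbook = np.sum(w * (betas - pooled) ** 2)
        q, df, _ = cochran_q(betas, np.diag(ses**2))
        assert q == pytest.approx(q_textbook)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(1)
        betas = rng.normal(0, 1, 3)
        a = rng.normal(size=(3, 3))
        cov = a @ a.T + 0.5 * np.eye(3)
        q1, _, _ = cochran_q(betas, cov)
        q2, _, _ = cochran_q(betas + 5.0, cov)
        assert q1 == pytest.approx(q2)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            cochran_q(np.array([0.1, 0.2]), np.zeros((2, 2)))


class TestStratumEffects:
    def test_joint_model_recovers_stratum_specific_slopes(self):
        rng = np.random.default_rng(7)
        n = 4000
        strata = np.repeat(["g1", "g2"], n // 2)
        z = rng.standard_normal(n)
        beta = np.where(strata == "g1", 0.3, 0.9)
        y = (rng.random(n) < expit(beta * z)).astype(float)
        labels, betas, cov = stratum_effects_joint(y, z, strata)
        assert labels == ["g1", "g2"]
        assert betas[0] == pytest.approx(0.3, abs=0.15)
        assert betas[1] == pytest.approx(0.9, abs=0.15)
        q, df, p = cochran_q(betas, cov)
        assert df == 1
        assert p < 0.01  # heterogeneity present by construction


class TestDeciles:
    def test_assign_deciles_balanced(self):
        d = assign_deciles(np.arange(100, dtype=float), seed=0)
        assert sorted(np.bincount(d)[1:]) == [10] * 10
        # decile 10 holds the largest values
        assert set(np.where(d == 10)[0]) == set(range(90, 100))

    def test_equal_counts_give_zero_slope(self):
        prs = np.arange(100, dtype=float)
        cats = np.array(["X"] * 100)
        trend = decile_trend(prs, cats, seed=0)
        slope, p = trend["X"]
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_counts_recover_slope(self):
        # construct categories so A appears 10*d times in decile d: exact line
        prs = np.arange(1000, dtype=float)
        deciles = assign_deciles(prs, seed=0)
        cats = np.array(["B"] * 1000)
        for d in range(1, 11):
            members = np.where(deciles == d)[0]
            cats[members[: 10 * d]] = "A"
        trend = decile_trend(prs, cats, seed=0)
        slope, p = trend["A"]
        assert slope == pytest.approx(10.0)
        assert p < 1e-8

    def test_requires_ten_samples(self):
        with pytest.raises(ValueError):
            decile_trend(np.arange(5, dtype=float), np.array(["A"] * 5))


class TestTopBottomDecile:
    def test_null_or_near_one(self):
        rng = np.random.default_rng(0)
        n = 5000
        prs = rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(float)
        est = top_bottom_decile_or(prs, y, seed=0)
        assert abs(est.beta) < 3 * est.se

    def test_tail_contrast_exceeds_per_sd_or(self):
        rng = np.random.default_rng(1)
        n = 20000
        prs = rng.standard_normal(n)
        y = (rng.random(n) < expit(-0.5 + 0.7 * prs)).astype(float)
        per_sd = fit_logistic(y, prs)
        tails = top_bottom_decile_or(prs, y, seed=0)
        assert tails.or_point > per_sd.or_point

    def test_complete_separation_in_tails_raises(self):
        prs = np.arange(100, dtype=float)
        y = (prs >= 50).astype(float)  # top decile all cases, bottom all controls
        with pytest.raises(SeparationError):
            top_bottom_decile_or(prs, y, seed=0)


class TestAncestryStrata:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["afr", "eur"])

    def test_dominant_ancestry_labeled(self):
        labels = ancestry_strata(self._frame([[0.9, 0.1]]), threshold=0.8)
        assert labels.iloc[0] == "afr"

    def test_admixed_sample_unlabeled(self):
        labels = ancestry_strata(self._frame([[0.5, 0.5]]), threshold=0.8)
        assert pd.isna(labels.iloc[0])

    def test_tie_at_half_threshold_unlabeled(self):
        labels = ancestry_strata(self._frame([[0.5, 0.5]]), threshold=0.5)
        assert pd.isna(labels.iloc[0])

    def test_unique_qualifier_at_low_threshold(self):
        labels = ancestry_strata(self._frame([[0.6, 0.4]]), threshold=0.5)
        assert labels.iloc[0] == "afr"

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            ancestry_strata(self._frame([[0.7, 0.6]]))
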