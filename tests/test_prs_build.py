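import numpy as np
import pytest

from htnprs.genodata import GenotypeDataset
from htnprs.prs_build import (
    P_THRESHOLDS,
    PRSValues,
    TuningParams,
    apply_threshold,
    build_candidates,
    clump,
    cohort_standardize,
    default_grid,
    prssum,
    score,
    score_grid,
    standardize,
)
from htnprs.sumstats import SumStats, VariantKey

from conftest import make_record, make_variant, random_genotypes


class TestDefaultGrid:
    def test_cardinality_is_108(self):
        assert len(default_grid()) == 12 * 3 * 3

    def test_contains_genome_wide_corner(self):
        assert TuningParams(5e-8, 0.1, 1000.0) in default_grid()

    def test_contains_permissive_corner(self):
        assert TuningParams(0.5, 0.3, 250.0) in default_grid()

    def test_param_validation(self):
        with pytest.raises(ValueError):
            TuningParams(0.0, 0.1, 500.0)
        with pytest.raises(ValueError):
            TuningParams(0.1, 1.0, 500.0)
        with pytest.raises(ValueError):
            TuningParams(0.1, 0.1, 0.0)


def _correlated_dataset():
    """Three variants: A at 100 kb, B at 150 kb (r² with A ~ 0.5+), C at 900 kb."""
    rng = np.random.default_rng(0)
    a = rng.binomial(2, 0.5, 400).astype(float)
    noise = rng.binomial(2, 0.5, 400).astype(float)
    b = np.where(rng.random(400) < 0.8, a, noise)  # strong LD with A
    c = rng.binomial(2, 0.4, 400).astype(float)
    variants = [make_variant(100_000), make_variant(150_000, "C", "T"), make_variant(900_000, "G", "T")]
    g = GenotypeDataset([f"s{i}" for i in range(400)], variants, np.column_stack([a, b, c]))
    return g, variants


class TestClump:
    def test_correlated_neighbor_removed_distant_kept(self):
        g, (va, vb, vc) = _correlated_dataset()
        ss = SumStats(
            "HTN",
            [
                make_record(100_000, p=1e-9),
                make_record(150_000, p=1e-8, ea="C", oa="T"),
                make_record(900_000, p=1e-7, ea="G", oa="T"),
            ],
        )
        kept = clump(ss, g, r2_max=0.1, window_kb=250.0)
        assert kept == {va, vc}

    def test_single_variant_is_its_own_index(self):
        g, (va, _, _) = _correlated_dataset()
        ss = SumStats("HTN", [make_record(100_000, p=1e-9)])
        assert clump(ss, g, 0.1, 250.0) == {va}

    def test_low_ld_pair_both_retained(self):
        g, (va, _, vc) = _correlated_dataset()
        ss = SumStats(
            "HTN",
            [make_record(100_000, p=1e-9), make_record(900_000, p=1e-7, ea="G", oa="T")],
        )
        kept = clump(ss, g, r2_max=0.1, window_kb=1000.0)
        assert kept == {va, vc}

    def test_retained_counts_monotone_in_parameters(self, small_cohort):
        from htnprs.synthdata import simulate_sumstats
        from htnprs.sumstats import harmonize_alleles

        cohort = small_cohort
        ss = simulate_sumstats(cohort["cfg"], cohort["truth"], "HTN")
        ss, _ = harmonize_alleles(ss, cohort["genotypes"].variants)
        g = cohort["genotypes"]
        n_tight = len(clump(ss, g, 0.1, 1000.0))
        n_loose = len(clump(ss, g, 0.3, 1000.0))
        n_narrow = len(clump(ss, g, 0.1, 250.0))
        assert n_tight <= n_loose        # lower r2_max removes more
        assert n_tight <= n_narrow       # wider window removes more


def brute_force_clump(ss, g, r2_max, window_kb):
    """Independent oracle: explicit list-based greedy with pairwise Pearson r²."""
    remaining = sorted(ss.records, key=lambda r: (r.pvalue, r.key.chrom, r.key.pos))
    kept = set()
    while remaining:
        index = remaining.pop(0)
        kept.add(index.key)
        survivors = []
        xi = g.dosages[:, g.variant_index(index.key)]
        for r in remaining:
            same_chrom = r.key.chrom == index.key.chrom
            close = abs(r.key.pos - index.key.pos) <= window_kb * 1000.0
            if same_chrom and close:
                xj = g.dosages[:, g.variant_index(r.key)]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    r2 = 0.0
                else:
                    r2 = np.corrcoef(xi, xj)[0, 1] ** 2
                if r2 > r2_max:
                    continue
            survivors.append(r)
        remaining = survivors
    return kept


class TestClumpOracle:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n_var = int(rng.integers(2, 50))
            g = random_genotypes(rng, n_samples=60, n_variants=n_var, chroms=("1", "2"))
            ss = SumStats(
                "HTN",
                [
                    make_record(v.pos, p=float(rng.uniform(1e-10, 1)), chrom=v.chrom)
                    for v in g.variants
                ],
            )
            r2_max = float(rng.choice([0.1, 0.2, 0.3]))
            window = float(rng.choice([100.0, 250.0, 500.0]))
            assert clump(ss, g, r2_max, window) == brute_force_clump(ss, g, r2_max, window)


class TestApplyThreshold:
    def test_filters_by_p(self):
        ss = SumStats("HTN", [make_record(100, p=1e-9, beta=0.3), make_record(200, p=1e-7, beta=0.1, ea="C", oa="T")])
        retained = {r.key for r in ss.records}
        w = apply_threshold(ss, retained, 1e-8)
        assert list(w.values()) == [0.3]

    def test_permissive_threshold_keeps_all(self):
        ss = SumStats("HTN", [make_record(100, p=0.2), make_record(200, p=0.4, ea="C", oa="T")])
        assert len(apply_threshold(ss, {r.key for r in ss.records}, 0.5)) == 2

    def test_empty_result_flagged_not_raised(self):
        ss = SumStats("HTN", [make_record(100, p=1e-4)])
        assert apply_threshold(ss, {ss.records[0].key}, 5e-8) == {}


class TestScore:
    def _tiny(self):
        va, vc = make_variant(100), make_variant(300, "C", "T")
        g = GenotypeDataset(["s1"], [va, vc], np.array([[2.0, 1.0]]))
        return g, va, vc

    def test_dot_product(self):
        g, va, vc = self._tiny()
        prs = score(g, {va: 0.2, vc: -0.1})
        assert prs.raw[0] == pytest.approx(0.3)

    def test_missing_dosage_mean_imputed(self):
        va, vc = make_variant(100), make_variant(300, "C", "T")
        g = GenotypeDataset(
            ["s1", "s2", "s3", "s4"],
            [va, vc],
            np.array([[np.nan, 1.0], [0.0, 1.0], [1.0, 1.0], [0.0, 1.0]]),
        )
        # freq(va) over non-missing = 0.25/... mean(0,1,0)/2 = 1/6; imputed = 2*1/6
        prs = score(g, {va: 0.2, vc: -0.1})
        assert prs.raw[0] == pytest.approx(2 * (1 / 6) * 0.2 - 0.1)

    def test_empty_weights_score_zero(self):
        g, *_ = self._tiny()
        assert score(g, {}).raw[0] == 0.0

    def test_absent_variant_raises(self):
        g, va, _ = self._tiny()
        with pytest.raises(KeyError):
            score(g, {make_variant(999): 1.0})

    def test_linearity(self):
        rng = np.random.default_rng(1)
        g = random_genotypes(rng, 50, 10)
        w1 = {v: float(rng.normal()) for v in g.variants[:6]}
        w2 = {v: float(rng.normal()) for v in g.variants[:6]}
        sum_w = {v: w1[v] + w2[v] for v in w1}
        np.testing.assert_allclose(score(g, sum_w).raw, score(g, w1).raw + score(g, w2).raw)
        np.testing.assert_allclose(score(g, {v: 3 * w1[v] for v in w1}).raw, 3 * score(g, w1).raw)

    def test_score_grid_matches_per_candidate_score(self, small_cohort):
        from htnprs.synthdata import simulate_sumstats
        from htnprs.sumstats import harmonize_alleles

        cohort = small_cohort
        g = cohort["genotypes"]
        ss = simulate_sumstats(cohort["cfg"], cohort["truth"], "SBP")
        ss, _ = harmonize_alleles(ss, g.variants)
        cands = build_candidates(ss, g)
        fast = score_grid(g, ss, cands)
        for c, f in zip(cands[::7], fast[::7]):
            np.testing.assert_allclose(f.raw, score(g, c.weights).raw, atol=1e-9)


class TestStandardize:
    def test_affine_transform(self):
        prs = PRSValues(["a"], np.array([1.3]))
        out = standardize(prs, mean=0.3, sd=0.5)
        assert out.standardized[0] == pytest.approx(2.0)

    def test_own_constants_give_mean0_sd1(self):
        rng = np.random.default_rng(0)
        prs = PRSValues([f"s{i}" for i in range(100)], rng.normal(5, 2, 100))
        out = cohort_standardize(prs)
        assert abs(out.standardized.mean()) < 1e-10
        assert out.standardized.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_smaller_group_sd_inflates_scores(self):
        prs = PRSValues(["a", "b"], np.array([1.0, 3.0]))
        full = standardize(prs, 0.0, 2.0, "full-cohort")
        group = standardize(prs, 0.0, 1.0, "group:g1")
        assert np.all(np.abs(group.standardized) >= np.abs(full.standardized))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            standardize(PRSValues(["a"], np.array([1.0])), 0.0, 0.0)


class TestPRSsum:
    def _component(self, values):
        prs = PRSValues([f"s{i}" for i in range(len(values))], np.array(values, dtype=float))
        return standardize(prs, 0.0, 1.0)

    def test_elementwise_sum_before_restandardization(self):
        comps = [self._component([0.5, 0.0]), self._component([-1.0, 0.0]), self._component([2.0, 0.0])]
        total = np.sum([c.standardized for c in comps], axis=0)
        assert total[0] == pytest.approx(1.5)
        out = prssum(comps)
        assert out.raw[0] == pytest.approx(1.5)

    def test_single_component_identity_up_to_standardization(self):
        c = self._component([0.5, -0.5, 1.0])
        out = prssum([c])
        np.testing.assert_allclose(out.raw, c.standardized)

    def test_order_invariant(self):
        comps = [self._component([0.5, 1.0, 2.0]), self._component([-1.0, 0.3, 0.1])]
        np.testing.assert_allclose(prssum(comps).standardized, prssum(comps[::-1]).standardized)

    def test_mismatched_samples_rejected(self):
        a = self._component([1.0, 2.0])
        b = PRSValues(["x", "y"], np.array([1.0, 2.0]))
        b = standardize(b, 0.0, 1.0)
        with pytest.raises(ValueError):
            prssum([a, b])

    def test_unstandardized_component_rejected(self):
        with pytest.raises(ValueError):
            prssum([PRSValues(["a"], np.array([1.0]))])


class TestGridMonotonicity:
    def test_weight_count_nondecreasing_in_threshold(self, small_cohort):
        from htnprs.synthdata import simulate_sumstats
        from htnprs.sumstats import harmonize_alleles

        cohort = small_cohort
        g = cohort["genotypes"]
        ss = simulate_sumstats(cohort["cfg"], cohort["truth"], "HTN")
        ss, _ = harmonize_alleles(ss, g.variants)
        cands = build_candidates(ss, g)
        by_family = {}
        for c in cands:
            by_family.setdefault((c.params.r2_max, c.params.window_kb), []).append(c)
        for fam in by_family.values():
            fam.sort(key=lambda c: c.params.p_threshold)
            sizes = [c.n_snps for c in fam]
            assert sizes == sorted(sizes)
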