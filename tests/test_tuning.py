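import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from htnprs.genodata import KinshipGraph
from htnprs.prs_build import PRSCandidate, PRSValues, TuningParams, standardize
from htnprs.tuning import (
    effect_cv,
    gws_prs,
    select_cv_prs,
    select_pval_prs,
    split_kinship_folds,
)
from htnprs.sumstats import SumStats

from conftest import make_record, make_variant


class TestSplitKinshipFolds:
    def test_singletons_split_evenly(self):
        ids = [f"s{i}" for i in range(10)]
        k = KinshipGraph.from_pairs([], ids)
        folds = split_kinship_folds(ids, k, n_folds=5, seed=0)
        sizes = pd.Series(folds.assignment).value_counts()
        assert sorted(sizes) == [2] * 5

    def test_components_each_to_own_fold(self):
        # components sized 3, 3, 2, 1, 1 with K=5: largest-first balancing
        pairs = [("a1", "a2", 0.3), ("a2", "a3", 0.3),
                 ("b1", "b2", 0.3), ("b2", "b3", 0.3),
                 ("c1", "c2", 0.3)]
        ids = ["a1", "a2", "a3", "b1", "b2", "b3", "c1", "c2", "d", "e"]
        k = KinshipGraph.from_pairs(pairs, ids)
        folds = split_kinship_folds(ids, k, n_folds=5, seed=0)
        a = folds.assignment
        assert a["a1"] == a["a2"] == a["a3"]
        assert a["b1"] == a["b2"] == a["b3"]
        assert a["c1"] == a["c2"]
        assert len({a["a1"], a["b1"], a["c1"]}) == 3  # big components spread out

    def test_relatives_never_cross_folds(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(60)]
        pairs = [(ids[i], ids[i + 1], 0.25) for i in range(0, 40, 2)]
        k = KinshipGraph.from_pairs(pairs, ids)
        folds = split_kinship_folds(ids, k, n_folds=5, seed=4)
        for a, b, _ in [(p[0], p[1], None) for p in pairs]:
            assert folds.assignment[a] == folds.assignment[b]

    def test_oversized_component_warns_but_proceeds(self, caplog):
        ids = [f"s{i}" for i in range(6)]
        pairs = [(ids[i], ids[i + 1], 0.3) for i in range(4)]  # component of 5
        k = KinshipGraph.from_pairs(pairs, ids)
        with caplog.at_level("WARNING"):
            folds = split_kinship_folds(ids, k, n_folds=5, seed=0)
        assert "exceeds" in caplog.text
        assert len(folds.assignment) == 6

    def test_fewer_than_two_folds_rejected(self):
        with pytest.raises(ValueError):
            split_kinship_folds(["a"], KinshipGraph.from_pairs([], ["a"]), n_folds=1)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestEffectCV:
    @given(
        st.lists(st.floats(0.05, 5.0), min_size=2, max_size=10),
        st.floats(0.01, 50.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_property(self, betas, c):
        betas = np.asarray(betas)
        assert effect_cv(c * betas) == pytest.approx(effect_cv(betas), rel=1e-6, abs=1e-12)

    def test_zero_variance(self):
        assert effect_cv([0.5] * 5) == 0.0

    def test_hand_computed_value(self):
        # sd = sqrt(0.005), mean = 0.5 -> cv = 0.1414...
        assert effect_cv([0.4, 0.5, 0.6, 0.5, 0.5]) == pytest.approx(np.sqrt(0.005) / 0.5)

    def test_nonpositive_mean_disqualifies(self):
        assert effect_cv([-0.1, 0.1, 0.0, 0.0, 0.0]) == np.inf
        assert effect_cv([-0.2, -0.3]) == np.inf

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        betas = rng.uniform(0.2, 0.8, 5)
        for c in (0.1, 2.0, 17.0):
            assert effect_cv(c * betas) == pytest.approx(effect_cv(betas))

    def test_too_few_estimates_error(self):
        with pytest.raises(ValueError):
            effect_cv([0.5])


def _selection_setup(seed=0, n=600, betas=(0.8, 0.3)):
    """Two synthetic candidates with different true effects on one outcome."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    k = KinshipGraph.from_pairs([], ids)
    folds = split_kinship_folds(ids, k, n_folds=5, seed=seed)
    z1 = rng.standard_normal(n)
    z2 = 0.3 * z1 + np.sqrt(1 - 0.09) * rng.standard_normal(n)
    y = (rng.random(n) < expit(betas[0] * z1 + betas[1] * z2)).astype(float)
    cands = [
        PRSCandidate("HTN", TuningParams(1e-6, 0.1, 500.0), {make_variant(100): 0.1}),
        PRSCandidate("HTN", TuningParams(1e-4, 0.1, 500.0), {make_variant(200, "C", "T"): 0.1}),
    ]
    scores = [
        standardize(PRSValues(ids, z1), 0.0, 1.0),
        standardize(PRSValues(ids, z2), 0.0, 1.0),
    ]
    return cands, scores, folds, y, ids


class TestSelectCV:
    def test_single_candidate_chosen(self):
        cands, scores, folds, y, ids = _selection_setup()
        sel = select_cv_prs(cands[:1], scores[:1], folds, y, None, ids)
        assert sel.chosen == cands[0].params
        assert sel.criterion == "CV"

    def test_argmin_cv_chosen(self):
        cands, scores, folds, y, ids = _selection_setup()
        sel = select_cv_prs(cands, scores, folds, y, None, ids)
        table = sel.table.set_index("p_threshold")
        chosen_cv = table.loc[sel.chosen.p_threshold, "cv"]
        assert chosen_cv == table["cv"].min()

    def test_degenerate_candidates_disqualified(self):
        cands, scores, folds, y, ids = _selection_setup()
        cands[0] = PRSCandidate("HTN", cands[0].params, {})
        sel = select_cv_prs(cands, scores, folds, y, None, ids)
        assert sel.chosen == cands[1].params

    def test_all_degenerate_raises(self):
        cands, scores, folds, y, ids = _selection_setup()
        empty = [PRSCandidate("HTN", c.params, {}) for c in cands]
        with pytest.raises(ValueError):
            select_cv_prs(empty, scores, folds, y, None, ids)

    def test_chosen_row_exists_in_table(self):
        cands, scores, folds, y, ids = _selection_setup(seed=3)
        sel = select_cv_prs(cands, scores, folds, y, None, ids)
        row = sel.table[
            (sel.table.p_threshold == sel.chosen.p_threshold)
            & (sel.table.r2_max == sel.chosen.r2_max)
            & (sel.table.window_kb == sel.chosen.window_kb)
        ]
        assert len(row) == 1

    def test_deterministic_given_inputs(self):
        cands, scores, folds, y, ids = _selection_setup(seed=9)
        a = select_cv_prs(cands, scores, folds, y, None, ids)
        b = select_cv_prs(cands, scores, folds, y, None, ids)
        assert a.chosen == b.chosen
        pd.testing.assert_frame_equal(a.table, b.table)


class TestSelectPval:
    def test_stronger_candidate_wins(self):
        cands, scores, folds, y, ids = _selection_setup(betas=(1.0, 0.1))
        sel = select_pval_prs(cands, scores, y, None, ids)
        assert sel.chosen == cands[0].params
        assert sel.criterion == "PVAL"

    def test_tie_broken_by_smaller_p_threshold(self):
        cands, scores, folds, y, ids = _selection_setup()
        scores[1] = scores[0]  # identical scores -> identical p-values
        cands[1] = PRSCandidate("HTN", TuningParams(1e-2, 0.1, 500.0), cands[1].weights)
        sel = select_pval_prs(cands, scores, y, None, ids)
        assert sel.chosen.p_threshold == 1e-6

    def test_all_degenerate_raises(self):
        cands, scores, folds, y, ids = _selection_setup()
        empty = [PRSCandidate("HTN", c.params, {}) for c in cands]
        with pytest.raises(ValueError):
            select_pval_prs(empty, scores, y, None, ids)


class TestGwsPrs:
    def test_fixed_parameters_and_grid_consistency(self, small_cohort):
        from htnprs.prs_build import build_candidates
        from htnprs.sumstats import harmonize_alleles
        from htnprs.synthdata import simulate_sumstats

        cohort = small_cohort
        g = cohort["genotypes"]
        ss = simulate_sumstats(cohort["cfg"], cohort["truth"], "HTN")
        ss, _ = harmonize_alleles(ss, g.variants)
        cand = gws_prs(ss, g)
        assert cand.params == TuningParams(5e-8, 0.1, 1000.0)
        grid_cell = [
            c for c in build_candidates(ss, g) if c.params == TuningParams(5e-8, 0.1, 1000.0)
        ][0]
        assert cand.weights == grid_cell.weights

    def test_no_significant_variants_degenerate(self):
        g_records = [make_record(100, p=1e-6)]
        ss = SumStats("HTN", g_records)
        import numpy as np
        from htnprs.genodata import GenotypeDataset

        g = GenotypeDataset(
            ["a", "b", "c"], [g_records[0].key], np.array([[0.0], [1.0], [2.0]])
        )
        cand = gws_prs(ss, g)
        assert cand.degenerate
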