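from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from snowballpipe import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleGroups,
    evaluate_external_sets,
    inhibitor_response_comparison,
    log2_fold_change,
    matched_background,
    overrepresentation_test,
    percent_overlap,
    shrna_comparison,
    simulate_inhibitor_response,
    simulate_shrna_screen,
    wilcoxon_rank_sum,
)
from test_simulate import _toy_truth


def _expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"G{i}" for i in range(values.shape[0])],
        columns=[f"S{j}" for j in range(values.shape[1])]))


def _groups(n_mut, n_wt):
    return SampleGroups({f"S{j}": ("MUT" if j < n_mut else "WT")
                         for j in range(n_mut + n_wt)})


class TestFoldChange:
    def test_arithmetic(self):
        # MUT log2(x+1) values {4,4}, WT {2,2} -> FC = 2
        expr = _expr([[15.0, 15.0, 3.0, 3.0]])
        fc = log2_fold_change(expr, _groups(2, 2))
        assert fc.loc["G0", "log2_fc"] == pytest.approx(2.0, rel=1e-12)
        assert fc.loc["G0", "abs_log2_fc"] == pytest.approx(2.0, rel=1e-12)

    def test_identical_means_give_zero(self):
        expr = _expr([[5.0, 7.0, 7.0, 5.0]])
        assert log2_fold_change(expr, _groups(2, 2)).loc["G0", "log2_fc"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_label_swap_negates(self, rng):
        expr = _expr(rng.gamma(2, 50, size=(10, 8)))
        groups = _groups(4, 4)
        a = log2_fold_change(expr, groups)["log2_fc"]
        b = log2_fold_change(expr, groups.swapped())["log2_fc"]
        assert np.allclose(a.to_numpy(), -b.to_numpy())


class TestMatchedBackground:
    def _levels(self, rng, n=200):
        return pd.Series(rng.uniform(0, 10, size=n),
                         index=[f"G{i}" for i in range(n)])

    def test_determinism(self, rng):
        levels = self._levels(rng)
        targets = set(levels.index[:20])
        universe = set(levels.index)
        a = matched_background(targets, levels, universe, 50, seed=3)
        b = matched_background(targets, levels, universe, 50, seed=3)
        assert a == b and len(a) == 50

    def test_range_constraint_enforced(self, rng):
        levels = self._levels(rng)
        high = levels[levels >= 8].index
        targets = set(high[: len(high) // 2])  # all high-expressed
        bg = matched_background(targets, levels, set(levels.index), 10, seed=1)
        lo = levels.loc[sorted(targets)].min()
        assert all(levels[g] >= lo for g in bg)
        assert bg.isdisjoint(targets)

    def test_vacuous_constraint_is_simple_random_sample(self, rng):
        levels = self._levels(rng)
        idx = levels.sort_values().index
        targets = {idx[0], idx[-1]}  # span the full range
        bg = matched_background(targets, levels, set(levels.index), 150, seed=2)
        assert len(bg) == 150

    def test_short_pool_returns_all_eligible(self, rng):
        levels = self._levels(rng, n=30)
        targets = set(levels.index[:25])
        bg = matched_background(targets, levels, set(levels.index), 20, seed=1)
        assert len(bg) <= 5


class TestWilcoxonRankSum:
    def test_small_sample_exact_p(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p == pytest.approx(1 / 3, rel=1e-12)
        assert res.direction == "background_greater"

    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1.0, 1.0, 2.0], [2.0, 1.0, 1.0])
        assert res.p == 1.0

    def test_all_values_identical(self):
        res = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p == 1.0 and res.direction == "tied"
        assert res.statistic == 3.0  # null mean of U

    @pytest.mark.parametrize("n_a,n_b", [(1, 3), (2, 2), (2, 4), (3, 3), (4, 4)])
    def test_exact_branch_matches_enumeration(self, n_a, n_b, rng):
        """For tie-free samples the p equals the enumeration over all
        C(n_a+n_b, n_a) rank assignments."""
        pooled = rng.normal(size=n_a + n_b)
        while np.unique(pooled).size < pooled.size:  # pragma: no cover
            pooled = rng.normal(size=n_a + n_b)
        a, b = pooled[:n_a], pooled[n_a:]
        res = wilcoxon_rank_sum(a, b)
        ranks = pd.Series(pooled).rank().to_numpy()
        observed_u = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        mean_u = n_a * n_b / 2
        count = 0
        total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
            count += abs(u - mean_u) >= abs(observed_u - mean_u) - 1e-12
            total += 1
        assert res.p == pytest.approx(count / total, rel=1e-10)

    def test_power_under_large_shift(self, rng):
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            a = local.normal(2.0, 1.0, size=50)
            b = local.normal(0.0, 1.0, size=50)
            hits += wilcoxon_rank_sum(a, b).p < 1e-6
        assert hits >= 19


class TestSetEvaluations:
    def test_planted_set_significant(self, small_cohort):
        expr, _, groups, truth = small_cohort
        fc = log2_fold_change(expr, groups)
        sets = GeneSetCollection({"planted": set(truth.responsive_genes)})
        results = {r.name: r for r in evaluate_external_sets(
            fc, expr, groups, sets, n_background=60, seed=9)}
        assert results["planted:abs_log2_fc"].p < 0.01
        assert results["planted:abs_log2_fc"].direction == "set_greater"

    def test_random_set_on_null_cohort_not_significant(self):
        """Without planted effects a random gene set rarely differs from
        its matched background on either read-out."""
        from snowballpipe import SimulationConfig, simulate_cohort
        hits = 0
        for seed in range(10):
            config = SimulationConfig(n_genes=150, n_modules=2, module_size=20,
                                      n_responsive_modules=0, mean_shift=0.0,
                                      n_loci=10, seed=seed)
            expr, _, groups, _ = simulate_cohort(config)
            fc = log2_fold_change(expr, groups)
            rng = np.random.default_rng(seed)
            pick = set(rng.choice(expr.gene_ids, size=20, replace=False))
            results = evaluate_external_sets(
                fc, expr, groups, GeneSetCollection({"random": pick}),
                n_background=60, seed=seed)
            hits += any(r.p < 0.05 for r in results)
        assert hits <= 2

    def test_set_absent_from_matrix_skipped(self, small_cohort):
        expr, _, groups, _ = small_cohort
        fc = log2_fold_change(expr, groups)
        sets = GeneSetCollection({"ghost": {"NOT_A_GENE"}})
        assert evaluate_external_sets(fc, expr, groups, sets, seed=1) == []

    def test_singleton_set_flagged_small_n(self, small_cohort):
        expr, _, groups, _ = small_cohort
        fc = log2_fold_change(expr, groups)
        sets = GeneSetCollection({"one": {expr.gene_ids[0]}})
        results = evaluate_external_sets(fc, expr, groups, sets,
                                         n_background=30, seed=2)
        assert all(r.small_n for r in results)


class TestInhibitorComparison:
    def test_planted_reversal_detected(self):
        truth = _toy_truth(n_up=100, n_down=100, n_null=2000)
        paired = simulate_inhibitor_response(truth, reversal=0.8, noise_sd=0.4,
                                             seed=6)
        sets = GeneSetCollection({"targets": set(truth.responsive_genes)})
        (res,) = inhibitor_response_comparison(paired, sets, n_controls=1500, seed=1)
        assert res.p < 1e-4 and res.direction == "set_greater"

    def test_null_reversal_usually_not_significant(self):
        hits = 0
        for seed in range(10):
            truth = _toy_truth(n_up=50, n_down=50, n_null=500)
            paired = simulate_inhibitor_response(truth, reversal=0.0,
                                                 noise_sd=0.4, seed=seed)
            sets = GeneSetCollection({"targets": set(truth.responsive_genes)})
            (res,) = inhibitor_response_comparison(paired, sets,
                                                   n_controls=400, seed=seed)
            hits += res.p < 0.05
        assert hits <= 1

    def test_control_request_capped_with_warning(self, caplog):
        truth = _toy_truth(n_up=5, n_down=5, n_null=50)
        paired = simulate_inhibitor_response(truth, seed=2)
        sets = GeneSetCollection({"targets": set(truth.responsive_genes)})
        with caplog.at_level("WARNING"):
            (res,) = inhibitor_response_comparison(paired, sets,
                                                   n_controls=5000, seed=1)
        assert res.n_background == 50

    def test_missing_after_values_dropped(self):
        truth = _toy_truth()
        paired = simulate_inhibitor_response(truth, seed=2)
        paired.loc[paired.index[:3], "expr_after"] = np.nan
        sets = GeneSetCollection({"targets": set(truth.responsive_genes)})
        (res,) = inhibitor_response_comparison(paired, sets, n_controls=10, seed=1)
        assert res.status == "ok"


class TestShrnaComparison:
    def test_directional_significance_with_planted_effect(self):
        truth = _toy_truth(n_up=100, n_down=100, n_null=2000)
        screen = simulate_shrna_screen(truth, effect=1.0, noise_sd=0.5, seed=3)
        results = {r.name: r for r in shrna_comparison(
            screen, set(truth.down_genes), set(truth.up_genes),
            n_controls=1500, seed=4)}
        down = results["down_targets_vs_controls"]
        up = results["up_targets_vs_controls"]
        assert down.p < 1e-6 and down.direction == "set_greater"
        assert up.p < 1e-6 and up.direction == "background_greater"

    def test_zero_effect_usually_not_significant(self):
        hits = 0
        for seed in range(10):
            truth = _toy_truth(n_up=50, n_down=50, n_null=500)
            screen = simulate_shrna_screen(truth, effect=0.0, noise_sd=0.5,
                                           seed=seed)
            results = shrna_comparison(screen, set(truth.down_genes),
                                       set(truth.up_genes),
                                       n_controls=400, seed=seed)
            hits += any(r.p < 0.05 for r in results)
        assert hits <= 2

    def test_empty_set_after_intersection_skipped(self):
        truth = _toy_truth(n_up=5, n_down=5, n_null=20)
        screen = simulate_shrna_screen(truth, seed=1)
        results = shrna_comparison(screen, {"ABSENT1", "ABSENT2"},
                                   set(truth.up_genes), n_controls=10, seed=1)
        down = next(r for r in results if r.name == "down_targets_vs_controls")
        assert down.status.startswith("skipped")


class TestOverlapAndEnrichment:
    def test_headline_overlap_percentage(self):
        """213 of 711 primary-tumor targets replicated -> 30%."""
        set_a = {f"T{i}" for i in range(711)}
        set_b = {f"T{i}" for i in range(213)} | {f"X{i}" for i in range(800)}
        count, percent = percent_overlap(set_a, set_b, denominator="a")
        assert count == 213
        assert round(percent) == 30

    def test_disjoint_and_subset_cases(self):
        assert percent_overlap({"A"}, {"B"}) == (0, 0.0)
        count, percent = percent_overlap({"A", "B"}, {"A", "B", "C"},
                                         denominator="a")
        assert count == 2 and percent == 100.0

    def test_count_symmetric_in_denominator_choice(self, rng):
        a = {f"G{i}" for i in rng.choice(100, 30, replace=False)}
        b = {f"G{i}" for i in rng.choice(100, 40, replace=False)}
        assert percent_overlap(a, b, "a")[0] == percent_overlap(a, b, "b")[0]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            percent_overlap(set(), {"A"})

    def test_hypergeometric_matches_brute_force_tail(self):
        """5 of 10 hits in a 20-gene annotation over a 100-gene universe."""
        from math import comb
        universe = {f"G{i}" for i in range(100)}
        annotation = {f"G{i}" for i in range(20)}
        hits = {f"G{i}" for i in range(5)} | {f"G{i}" for i in range(50, 55)}
        overlap, p = overrepresentation_test(hits, annotation, universe)
        assert overlap == 5
        expected = sum(comb(20, k) * comb(80, 10 - k) for k in range(5, 11)) \
            / comb(100, 10)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_degenerate_cases(self):
        universe = {f"G{i}" for i in range(30)}
        overlap, p = overrepresentation_test(universe, universe, universe)
        assert overlap == 30 and p == pytest.approx(1.0)
        overlap, p = overrepresentation_test(
            {"G0"}, {f"G{i}" for i in range(1, 30)}, universe)
        assert overlap == 0 and p == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test({"Z"}, {"A"}, {"A", "B"})
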