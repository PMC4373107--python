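import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from snowballpipe import (
    ExpressionMatrix,
    SampleGroups,
    SimulationConfig,
    detect_modules,
    finalize_targets,
    module_association_test,
    pick_soft_threshold,
    simulate_cohort,
    tom_matrix,
)
from snowballpipe.network import ModuleAssignment, TomMatrix, _adjacency, scale_free_fit
from snowballpipe.snowball import gower_center, permutation_pvalue
from scipy.spatial.distance import pdist, squareform


def _expr_from_log2(log2_values, prefix="G"):
    values = np.clip(2.0 ** np.asarray(log2_values) - 1.0, 0.0, None)
    genes = [f"{prefix}{i:03d}" for i in range(values.shape[0])]
    samples = [f"S{j:03d}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _two_block_expr(rng, block=25, n=60, loading=0.95):
    f1, f2 = rng.normal(size=(2, n))
    noise_sd = np.sqrt(1 - loading**2)
    rows = [5 + loading * f1 + rng.normal(scale=noise_sd, size=n) for _ in range(block)]
    rows += [5 + loading * f2 + rng.normal(scale=noise_sd, size=n) for _ in range(block)]
    return _expr_from_log2(np.array(rows))


def _heterogeneous_two_block(rng, block=100, n=60):
    """Two modules with spread-out gene loadings, as real modules have."""
    rows = []
    for f in rng.normal(size=(2, n)):
        for _ in range(block):
            loading = rng.uniform(0.3, 0.98)
            noise = rng.normal(scale=np.sqrt(1 - loading**2), size=n)
            rows.append(5 + loading * f + noise)
    return _expr_from_log2(np.array(rows))


def _brute_force_tom(adj):
    n = adj.shape[0]
    k = adj.sum(axis=0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n))
            tom[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


class TestTomMatrix:
    def test_matches_brute_force_formula(self, rng):
        """5-gene TOM equals the direct formula evaluated entrywise."""
        expr = _expr_from_log2(rng.normal(5, 1, size=(5, 30)))
        tom = tom_matrix(expr, power=2)
        adj = _adjacency(expr, 2).to_numpy()
        assert np.allclose(tom.values.to_numpy(), _brute_force_tom(adj), atol=1e-12)

    def test_bounds_symmetry_and_unit_diagonal(self, rng):
        expr = _expr_from_log2(rng.normal(5, 1, size=(30, 40)))
        tom = tom_matrix(expr, power=6).values.to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_correlated_pair_separates_from_outsiders(self, rng):
        n = 50
        shared = rng.normal(size=n)
        rows = [5 + shared + rng.normal(scale=0.1, size=n),
                5 + shared + rng.normal(scale=0.1, size=n)]
        rows += [5 + rng.normal(size=n) for _ in range(6)]
        tom = tom_matrix(_expr_from_log2(np.array(rows)), power=6).values.to_numpy()
        assert tom[0, 1] > tom[0, 2:].max()
        assert tom[0, 1] > tom[1, 2:].max()

    def test_too_few_genes_rejected(self, rng):
        expr = _expr_from_log2(rng.normal(5, 1, size=(2, 20)))
        with pytest.raises(ValueError, match="at least 3"):
            tom_matrix(expr, power=6)

    def test_constant_gene_rejected(self, rng):
        log2 = rng.normal(5, 1, size=(5, 20))
        log2[2] = 4.0
        with pytest.raises(ValueError, match="constant"):
            tom_matrix(_expr_from_log2(log2), power=6)


class TestSoftThreshold:
    def test_single_candidate_power_returned(self, rng):
        expr = _expr_from_log2(rng.normal(5, 1, size=(25, 30)))
        assert pick_soft_threshold(expr, powers=[6]) == 6

    def test_modular_data_saturates_early(self):
        for seed in range(5):
            expr = _heterogeneous_two_block(np.random.default_rng(seed))
            assert pick_soft_threshold(expr) <= 6

    def test_independent_genes_fall_back_to_max_r2(self, rng, caplog):
        expr = _expr_from_log2(rng.normal(5, 1, size=(40, 30)))
        with caplog.at_level("INFO", logger="snowballpipe.network"):
            power = pick_soft_threshold(expr, powers=range(1, 7), r2_target=0.995)
        assert power in range(1, 7)
        assert "falling back" in caplog.text

    def test_scale_free_fit_in_unit_interval(self, rng):
        expr = _two_block_expr(rng)
        fit = scale_free_fit(_adjacency(expr, 6))
        assert 0.0 <= fit <= 1.0


class TestDetectModules:
    def test_recovers_planted_blocks(self, rng):
        expr = _two_block_expr(rng)
        tom = tom_matrix(expr, power=6)
        assignment = detect_modules(tom, min_module_size=10, cut_height=0.85)
        planted = [0] * 25 + [1] * 25
        assert len(assignment.module_ids) == 2
        assert adjusted_rand_score(planted, assignment.modules.to_numpy()) >= 0.95

    def test_independent_genes_left_unassigned(self, rng):
        expr = _expr_from_log2(rng.normal(5, 1, size=(40, 50)))
        assignment = detect_modules(tom_matrix(expr, power=6), min_module_size=10,
                                    cut_height=0.2)
        assert (assignment.modules == 0).all()

    def test_degenerate_cut_gives_single_module(self, rng):
        expr = _expr_from_log2(rng.normal(5, 1, size=(12, 30)))
        assignment = detect_modules(tom_matrix(expr, power=6), min_module_size=1,
                                    cut_height=1 - 1e-9)
        assert assignment.module_ids == [1]
        assert (assignment.modules == 1).all()

    def test_gene_order_invariance(self, rng):
        expr = _two_block_expr(rng)
        tom = tom_matrix(expr, power=6)
        perm = rng.permutation(len(tom.gene_ids))
        genes = [tom.gene_ids[i] for i in perm]
        tom_perm = TomMatrix(values=tom.values.loc[genes, genes], power=6)
        a = detect_modules(tom, 10, 0.85).modules
        b = detect_modules(tom_perm, 10, 0.85).modules
        assert (a.loc[genes].to_numpy() == b.loc[genes].to_numpy()).all()

    def test_bad_cut_height_rejected(self, rng):
        expr = _expr_from_log2(rng.normal(5, 1, size=(12, 30)))
        with pytest.raises(ValueError, match="cut_height"):
            detect_modules(tom_matrix(expr, power=6), 10, 1.5)


class TestModuleAssociation:
    def test_duplicated_gene_pair_reduces_to_univariate(self, rng):
        """A module made of one gene duplicated gives the same permutation p
        as the univariate test on that gene (identical seed and perms)."""
        x = np.concatenate([rng.normal(6.0, 1, 8), rng.normal(5.0, 1, 8)])
        expr = _expr_from_log2(np.vstack([x, x]))
        labels = {s: ("MUT" if i < 8 else "WT")
                  for i, s in enumerate(expr.sample_ids)}
        groups = SampleGroups(labels)
        f_pair, p_pair = module_association_test(
            expr, expr.gene_ids, groups, n_perm=199, seed=5)
        z = (x - x.mean()) / x.std(ddof=1)
        kernel = gower_center(squareform(pdist(z[:, None])))
        f_uni, p_uni = permutation_pvalue(
            kernel, groups.indicator(expr.sample_ids), n_perm=199, seed=5)
        assert f_pair == pytest.approx(f_uni, rel=1e-10)
        assert p_pair == pytest.approx(p_uni)

    def test_responsive_module_detected(self):
        hits = 0
        for seed in range(10):
            config = SimulationConfig(n_genes=40, n_modules=2, module_size=20,
                                      n_responsive_modules=1, mean_shift=1.5,
                                      n_loci=10, seed=seed)
            expr, _, groups, truth = simulate_cohort(config)
            _, p = module_association_test(expr, truth.responsive_genes, groups,
                                           n_perm=99, seed=seed)
            hits += p <= 0.05
        assert hits >= 9

    def test_missing_genes_listed(self, small_cohort):
        expr, _, groups, _ = small_cohort
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            module_association_test(expr, ["NOT_A_GENE", expr.gene_ids[0]], groups)


class TestFinalizeTargets:
    def _assignment(self, genes_by_module):
        modules = {}
        for mid, genes in genes_by_module.items():
            for g in genes:
                modules[g] = mid
        return ModuleAssignment(modules=pd.Series(modules, name="module"))

    def test_threshold_application(self, rng):
        expr = _expr_from_log2(rng.normal(5, 1, size=(6, 10)))
        genes = expr.gene_ids
        groups = SampleGroups({s: ("MUT" if i < 5 else "WT")
                               for i, s in enumerate(expr.sample_ids)})
        assignment = self._assignment({1: genes[:3], 2: genes[3:]})
        targets = finalize_targets(assignment, {1: 0.01, 2: 0.2}, expr, groups,
                                   module_alpha=0.05)
        assert set(targets.genes) == set(genes[:3])
        assert (targets.table["module"] == 1).all()

    def test_direction_matches_fold_change_sign(self, small_cohort):
        expr, _, groups, truth = small_cohort
        responsive = truth.genes[truth.genes["responsive"]]
        assignment = self._assignment(
            {1: list(responsive.index[responsive["direction"] == "up"]),
             2: list(responsive.index[responsive["direction"] == "down"])})
        targets = finalize_targets(assignment, {1: 0.001, 2: 0.001}, expr, groups)
        merged = targets.table.set_index("gene").join(truth.genes["direction"],
                                                      rsuffix="_true")
        agreement = (merged["direction"] == merged["direction_true"]).mean()
        assert agreement >= 0.95
        assert set(targets.up_genes).isdisjoint(targets.down_genes)
        assert len(targets.up_genes) + len(targets.down_genes) == len(targets.genes)

    def test_zero_fold_change_labeled_down_and_flagged(self):
        values = pd.DataFrame(
            {"S1": [3.0, 1.0], "S2": [3.0, 2.0], "S3": [3.0, 5.0], "S4": [3.0, 6.0]},
            index=["FLAT", "MOVES"])
        expr = ExpressionMatrix(values)
        groups = SampleGroups({"S1": "MUT", "S2": "MUT", "S3": "WT", "S4": "WT"})
        assignment = self._assignment({1: ["FLAT", "MOVES"]})
        targets = finalize_targets(assignment, {1: 0.01}, expr, groups)
        row = targets.table.set_index("gene").loc["FLAT"]
        assert row["direction"] == "down" and bool(row["zero_fc"])
        assert not targets.table.set_index("gene").loc["MOVES", "zero_fc"]
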