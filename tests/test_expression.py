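"""Normalization arithmetic, differential-test behaviour at the fold-change
boundary, exact Wilcoxon agreement, independence reporting and PCA
identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circage.expression import (ExpressionTable, circ_linear_independence,
                                circ_tpm, differential, gene_fpkm,
                                global_shift, pca)
from circage.synthdata import simulate_count_study


def make_expr(rows: dict, tissue="t", eps=0.0):
    libs = [f"{tissue}_{a}_r{i}" for a in ("young", "old") for i in (1, 2, 3)]
    values = pd.DataFrame(rows, index=libs).T
    design = pd.DataFrame([dict(library=l, tissue=tissue,
                                age=l.split("_")[1], replicate=int(l[-1]))
                           for l in libs])
    return ExpressionTable(values, design, pseudocount=eps)


class TestCircTPM:
    def _design(self, libs):
        return pd.DataFrame([dict(library=l, tissue="t", age="young",
                                  replicate=i) for i, l in enumerate(libs)])

    def test_formula(self):
        counts = pd.DataFrame({"l1": [5]}, index=["c1"])
        expr = circ_tpm(counts, {"l1": 10**6}, self._design(["l1"]))
        assert expr.values.loc["c1", "l1"] == 5.0

    def test_depth_scale_invariance(self):
        counts = pd.DataFrame({"l1": [5, 7], "l2": [10, 14]},
                              index=["c1", "c2"])
        expr = circ_tpm(counts, {"l1": 1000, "l2": 2000},
                        self._design(["l1", "l2"]))
        assert (expr.values["l1"] == expr.values["l2"]).all()

    def test_within_library_ratios_preserved(self):
        counts = pd.DataFrame({"l1": [3, 9]}, index=["c1", "c2"])
        expr = circ_tpm(counts, {"l1": 55555}, self._design(["l1"]))
        assert expr.values.loc["c2", "l1"] / expr.values.loc["c1", "l1"] \
            == pytest.approx(3.0)

    def test_zero_total_rejected(self):
        counts = pd.DataFrame({"l1": [5]}, index=["c1"])
        with pytest.raises(ValueError, match="N"):
            circ_tpm(counts, {"l1": 0}, self._design(["l1"]))


class TestDifferential:
    def test_exact_fold_change_boundary(self):
        expr = make_expr({"c1": [2, 2, 2, 3, 3, 3]})
        de = differential(expr, "t", pseudocount=0.0)
        row = de.loc["c1"]
        assert row.fold_change == 1.5
        # zero within-group variance, unequal means: p -> 0, so status is up
        assert row.status == "up"

    def test_identical_groups_unchanged(self):
        expr = make_expr({"c1": [4, 4, 4, 4, 4, 4]})
        de = differential(expr, "t", pseudocount=0.0)
        row = de.loc["c1"]
        assert row.fold_change == 1.0 and row.p_value == 1.0
        assert row.status == "unchanged" and row.flag == "zero-variance"

    def test_down_regulation_symmetric(self):
        expr = make_expr({"c1": [30, 32, 28, 10, 11, 9]})
        row = differential(expr, "t", pseudocount=0.0).loc["c1"]
        assert row.status == "down" and row.fold_change < 1 / 1.5

    def test_bh_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(5)
        rows = {f"c{i}": rng.poisson(20, 6) for i in range(50)}
        expr = make_expr({k: list(map(float, v)) for k, v in rows.items()})
        de = differential(expr, "t", correct="BH")
        assert (de.p_adjusted >= de.p_value - 1e-12).all()

    def test_type_one_error_near_nominal(self):
        # 3v3 null on Poisson(30) counts: rejection rate within 3 binomial
        # SE of 0.05 (a smaller desk-scale version of the full calibration)
        rng = np.random.default_rng(11)
        mat, design, totals = simulate_count_study(
            1000, rng, mean_count=30.0, sigma_ln=0.0)
        expr = circ_tpm(mat, totals, design)
        de = differential(expr, "sim")
        rate = (de.p_value < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(de))
        assert abs(rate - 0.05) < 3 * se

    def test_power_monotone_in_fold_change(self):
        rng = np.random.default_rng(12)
        powers = []
        for fold in (1.5, 2.0, 3.0):
            mat, design, totals = simulate_count_study(
                400, rng, mean_count=40.0, sigma_ln=0.0, fold=fold)
            de = differential(circ_tpm(mat, totals, design), "sim")
            powers.append((de.status == "up").mean())
        assert powers[0] <= powers[1] <= powers[2]

    def test_requires_two_replicates(self):
        expr = make_expr({"c1": [1, 2, 3, 4, 5, 6]})
        sub = ExpressionTable(expr.values[["t_young_r1", "t_old_r1",
                                           "t_old_r2"]], expr.design)
        with pytest.raises(ValueError, match="replicates"):
            differential(sub, "t")


class TestGeneFPKM:
    def _bundle(self):
        from circage.genome import GeneModel, GenomeBundle, Transcript

        genes = [GeneModel("g1", "chr1", "+",
                           [Transcript("g1.t1", ((0, 500), (600, 1100)), None)]),
                 GeneModel("g2", "chr1", "+",
                           [Transcript("g2.t1", ((2000, 2500),), None)])]
        return GenomeBundle({"chr1": "A" * 3000}, genes)

    def test_formula(self):
        bundle = self._bundle()
        design = pd.DataFrame([dict(library="l1", tissue="t", age="young",
                                    replicate=1)])
        frag_genes = {"l1": {}}
        for i in range(10):
            frag_genes["l1"][f"f{i}"] = [frozenset({"g1"}), frozenset({"g1"})]
        for i in range(10, 1000):
            frag_genes["l1"][f"f{i}"] = [frozenset({"g2"}), frozenset({"g2"})]
        expr = gene_fpkm(frag_genes, bundle, design)
        # 10 fragments, union 1000 nt, 1000 assigned total
        assert expr.values.loc["g1", "l1"] == pytest.approx(
            10 * 1e9 / (1000 * 1000))

    def test_ambiguous_and_half_aligned_fragments_unassigned(self):
        bundle = self._bundle()
        design = pd.DataFrame([dict(library="l1", tissue="t", age="young",
                                    replicate=1)])
        frag_genes = {"l1": {
            "f1": [frozenset({"g1", "g2"}), frozenset({"g1", "g2"})],
            "f2": [frozenset({"g1"}), None],
            "f3": [frozenset({"g1"}), frozenset({"g1"})],
        }}
        expr = gene_fpkm(frag_genes, bundle, design)
        assert expr.values.loc["g2", "l1"] == 0.0
        assert expr.values.loc["g1", "l1"] > 0


class TestGlobalShift:
    @staticmethod
    def brute_force_p(x, y):
        """Exact two-sided Mann-Whitney p by full enumeration."""
        from itertools import combinations
        from math import comb

        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        n1 = len(x)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * len(y) / 2
        hits = sum(1 for idx in combinations(range(len(pooled)), n1)
                   if abs(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2 - mu)
                   >= abs(u_obs - mu) - 1e-9)
        return hits / comb(len(pooled), n1)

    def _expr_from_groups(self, young_vals, old_vals):
        ny, no = len(young_vals), len(old_vals)
        libs = [f"t_young_r{i}" for i in range(ny)] + \
               [f"t_old_r{i}" for i in range(no)]
        values = pd.DataFrame([list(young_vals) + list(old_vals)],
                              index=["c1"], columns=libs)
        design = pd.DataFrame([dict(library=l, tissue="t",
                                    age=l.split("_")[1], replicate=i)
                               for i, l in enumerate(libs)])
        return ExpressionTable(values, design)

    def test_complete_separation_matches_exact_enumeration(self):
        expr = self._expr_from_groups([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        res = global_shift(expr, "t")
        assert res.method == "exact"
        assert res.u_statistic == 25  # maximal U for 5v5
        assert res.p_value == pytest.approx(self.brute_force_p(
            np.array([6, 7, 8, 9, 10.0]), np.array([1, 2, 3, 4, 5.0])))

    @pytest.mark.parametrize("seed", range(30))
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ny, no = rng.integers(3, 7, size=2)
        y = rng.normal(size=ny)
        o = rng.normal(size=no) + rng.normal() * 0.5
        res = global_shift(self._expr_from_groups(y, o), "t")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(self.brute_force_p(o, y))

    def test_null_median_p_near_half(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            mat, design, totals = simulate_count_study(
                500, rng, mean_count=30.0, sigma_ln=0.0)
            ps.append(global_shift(circ_tpm(mat, totals, design),
                                   "sim").p_value)
        assert 0.25 < np.median(ps) < 0.75

    def test_upshift_detected(self):
        rng = np.random.default_rng(3)
        fold = np.ones(2000)
        fold[rng.choice(2000, 100, replace=False)] = 2.0
        mat, design, totals = simulate_count_study(
            2000, rng, mean_count=30.0, sigma_ln=0.0, fold=fold)
        res = global_shift(circ_tpm(mat, totals, design), "sim")
        assert res.p_value < 0.05 and res.z > 0

    def test_empty_group_rejected(self):
        expr = self._expr_from_groups([1.0], [2.0])
        empty = ExpressionTable(expr.values.iloc[0:0], expr.design)
        with pytest.raises(ValueError):
            global_shift(empty, "t")


class TestIndependence:
    def test_log2_point_for_circ_doubling(self):
        circ_de = pd.DataFrame(dict(log2_fold_change=[1.0],
                                    status=["up"]), index=["c1"])
        lin_de = pd.DataFrame(dict(log2_fold_change=[0.0],
                                   status=["unchanged"]), index=["g1"])
        rep = circ_linear_independence(circ_de, lin_de, {"c1": "g1"})
        row = rep.density_table.iloc[0]
        assert (row.log2_linear_fc, row.log2_circ_fc) == (0.0, 1.0)
        assert rep.n_circ_up == 1 and rep.n_circ_up_host_up == 0

    def test_ratio_invariance_when_both_double(self):
        circ = make_expr({"c1": [10, 10, 10, 20, 20, 20]})
        lin = make_expr({"g1": [100, 100, 100, 200, 200, 200]}, eps=0.0)
        circ_de = differential(circ, "t", pseudocount=0.0)
        lin_de = differential(lin, "t", pseudocount=0.0)
        rep = circ_linear_independence(circ_de, lin_de, {"c1": "g1"},
                                       circ_expr=circ, linear_expr=lin,
                                       tissue="t")
        assert rep.ratio_tests.iloc[0].p_value == 1.0

    def test_intergenic_counted_separately(self):
        circ_de = pd.DataFrame(dict(log2_fold_change=[1.0, 0.5],
                                    status=["up", "unchanged"]),
                               index=["c1", "c2"])
        lin_de = pd.DataFrame(dict(log2_fold_change=[0.0],
                                   status=["unchanged"]), index=["g1"])
        rep = circ_linear_independence(
            circ_de, lin_de, {"c1": "g1", "c2": "intergenic"})
        assert rep.n_intergenic == 1
        assert len(rep.density_table) == 1


class TestPCA:
    def _expr(self, values):
        libs = [f"l{i}" for i in range(values.shape[1])]
        design = pd.DataFrame([dict(library=l, tissue="t", age="young",
                                    replicate=i) for i, l in enumerate(libs)])
        return ExpressionTable(pd.DataFrame(
            values, index=[f"f{i}" for i in range(values.shape[0])],
            columns=libs), design)

    def test_duplicated_group_structure(self):
        a = np.array([10.0, 0.0, 5.0, 2.0])
        b = np.array([0.0, 10.0, 1.0, 8.0])
        expr = self._expr(np.column_stack([a, a, b, b]))
        res = pca(expr)
        s = res.scores["PC1"].to_numpy()
        assert np.sign(s[0]) == np.sign(s[1]) != np.sign(s[2])
        assert res.variance_fractions[0] == pytest.approx(1.0)
        assert res.variance_fractions[1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        expr = self._expr(rng.lognormal(size=(30, 6)))
        res = pca(expr)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_loadings_reconstruct_centered_data(self):
        rng = np.random.default_rng(2)
        expr = self._expr(rng.lognormal(size=(20, 5)))
        res = pca(expr)
        X = np.log10(expr.values.to_numpy().T + 1)
        X -= X.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, X, atol=1e-9)

    def test_constant_matrix_gives_zero_scores(self):
        expr = self._expr(np.full((10, 4), 3.0))
        res = pca(expr)
        assert np.allclose(res.scores.to_numpy(), 0.0)
        assert np.allclose(res.variance_fractions, 0.0)

    def test_single_library_rejected(self):
        expr = self._expr(np.ones((5, 2)))
        sub = ExpressionTable(expr.values[["l0"]], expr.design)
        with pytest.raises(ValueError):
            pca(sub)
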