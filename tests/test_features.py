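import numpy as np
import pytest

from stsisal.data import ExpressionMatrix, filter_genes
from stsisal.evaluate import align_types
from stsisal.features import (
    celltype_specific_features,
    initial_features,
    iterate_selection,
)


class TestInitialFeatures:
    def test_constant_gene_ranks_below_varying(self):
        Y = ExpressionMatrix(np.array([[3.0, 3.0, 3.0], [1.0, 5.0, 9.0]]),
                             ["const", "vary"], ["s1", "s2", "s3"])
        assert initial_features(Y, 1) == ["vary"]

    def test_cv_ranking_matches_direct_computation(self):
        vals = np.array([[1.0, 1.0, 1.0, 9.0],
                         [3.0, 3.0, 3.0, 3.0],
                         [0.0, 0.0, 4.0, 4.0]])
        Y = ExpressionMatrix(vals, ["a", "b", "c"],
                             [f"s{j}" for j in range(4)])
        cv = vals.std(axis=1, ddof=1) / vals.mean(axis=1)
        assert cv[0] == pytest.approx(4 / 3)
        expect = [x for _, x in sorted(zip(-cv, ["a", "b", "c"]))][:2]
        assert initial_features(Y, 2) == expect

    def test_zero_mean_genes_excluded(self):
        Y = ExpressionMatrix(np.array([[0.0, 0.0], [1.0, 2.0]]),
                             ["zero", "ok"], ["s1", "s2"])
        assert initial_features(Y, 2) == ["ok"]

    def test_n_init_equal_l_returns_all_rankable(self):
        rng = np.random.default_rng(0)
        Y = ExpressionMatrix(rng.random((10, 5)) + 0.1,
                             [f"g{i}" for i in range(10)],
                             [f"s{j}" for j in range(5)])
        assert sorted(initial_features(Y, 10)) == sorted(Y.gene_ids)

    def test_n_init_above_l_raises(self):
        Y = ExpressionMatrix(np.ones((2, 3)), ["a", "b"],
                             ["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            initial_features(Y, 5)


class TestCelltypeSpecificFeatures:
    def test_perfect_marker_ranks_first(self, rng):
        H = rng.dirichlet(np.ones(3), size=40).T          # (3, 40)
        vals = np.vstack([H[0],                            # pure type-1 gene
                          rng.random((5, 40))])
        Y = ExpressionMatrix(vals, ["marker"] + [f"g{i}" for i in range(5)],
                             [f"s{j}" for j in range(40)])
        lists = celltype_specific_features(Y, H, per_type=3)
        assert lists[0][0] == "marker"

    def test_constant_gene_never_outranks_true_marker(self, rng):
        # a flat gene has a one-vs-rest contrast near zero: below every
        # type's own marker (markers of *other* types score negative and
        # legitimately fall below it)
        H = rng.dirichlet(np.ones(3), size=50).T
        vals = np.vstack([H + 0.01 * rng.random((3, 50)),
                          np.full((1, 50), 2.0)])
        Y = ExpressionMatrix(vals, ["m0", "m1", "m2", "flat"],
                             [f"s{j}" for j in range(50)])
        lists = celltype_specific_features(Y, H, per_type=4)
        for k, lst in enumerate(lists):
            assert lst[0] == f"m{k}"
            assert lst.index("flat") > 0

    def test_degenerate_h_raises(self):
        H = np.vstack([np.full(20, 0.5), np.full(20, 0.5)])
        Y = ExpressionMatrix(np.ones((5, 20)) + np.arange(20) * 0.01,
                             [f"g{i}" for i in range(5)],
                             [f"s{j}" for j in range(20)])
        with pytest.raises(ValueError, match="rank"):
            celltype_specific_features(Y, H)

    def test_recovers_marker_blocks_on_simulation(self, small_truth):
        ref, truth = small_truth
        Yf = filter_genes(truth.Y)
        lists = celltype_specific_features(Yf, truth.P_true, per_type=20)
        kept = set(Yf.gene_ids)
        hits = []
        for k in range(3):  # lists are computed against the true H here
            surviving = {g for g, m in zip(ref.gene_ids, ref.marker_of)
                         if m == k and g in kept}
            top = lists[k][: min(20, len(surviving))]
            hits.append(sum(g in surviving for g in top) / len(top))
        assert min(hits) >= 0.8


class TestIterateSelection:
    def test_single_outer_iteration(self, small_truth):
        _, truth = small_truth
        Yf = filter_genes(truth.Y)
        res = iterate_selection(Yf, 3, max_outer=1, seed=0,
                                deconf_max_iter=100)
        assert res.n_outer_iter == 1
        assert len(res.rmse_trace) == 1

    def test_gene_list_always_below_1000(self, small_truth):
        _, truth = small_truth
        Yf = filter_genes(truth.Y)
        res = iterate_selection(Yf, 3, per_type=400, max_outer=2, seed=0,
                                deconf_max_iter=100)
        assert len(res.genes) < 1000
        assert set(res.genes) <= set(Yf.gene_ids)

    def test_noiseless_mixture_converges(self):
        rng = np.random.default_rng(2)
        M0 = rng.lognormal(0, 1, (150, 3))
        H0 = rng.dirichlet(np.ones(3), size=40).T
        Y = ExpressionMatrix(M0 @ H0, [f"g{i:03d}" for i in range(150)],
                             [f"s{j}" for j in range(40)])
        res = iterate_selection(Y, 3, n_init=150, per_type=50, seed=0)
        assert res.rmse_trace[-1] / Y.values.mean() < 1e-2

    def test_seeded_determinism_across_loop(self, small_truth):
        _, truth = small_truth
        Yf = filter_genes(truth.Y)
        a = iterate_selection(Yf, 3, max_outer=2, seed=9,
                              deconf_max_iter=60)
        b = iterate_selection(Yf, 3, max_outer=2, seed=9,
                              deconf_max_iter=60)
        assert a.genes == b.genes
        assert a.rmse_trace == b.rmse_trace

    def test_selected_genes_enriched_for_markers(self, small_truth):
        ref, truth = small_truth
        Yf = filter_genes(truth.Y)
        res = iterate_selection(Yf, 3, per_type=25, seed=1,
                                deconf_max_iter=200)
        markers = {g for g, m in zip(ref.gene_ids, ref.marker_of) if m >= 0}
        frac_sel = sum(g in markers for g in res.genes) / len(res.genes)
        frac_all = sum(g in markers for g in Yf.gene_ids) / Yf.n_genes
        assert frac_sel >= 2 * frac_all
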