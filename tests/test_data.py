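import numpy as np
import pytest

from stsisal.data import (
    ExpressionMatrix,
    filter_genes,
    load_matrix,
    log_normalize,
    row_normalize,
    save_matrix,
)


class TestExpressionMatrix:
    def test_rejects_negative_entry_with_coordinates(self):
        vals = np.array([[1.0, 2.0], [3.0, -1.0]])
        with pytest.raises(ValueError, match="negative entry"):
            ExpressionMatrix(vals, ["a", "b"], ["s1", "s2"])

    def test_rejects_duplicate_ids(self):
        vals = np.ones((2, 2))
        with pytest.raises(ValueError, match="duplicate gene id 'a'"):
            ExpressionMatrix(vals, ["a", "a"], ["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate spot id"):
            ExpressionMatrix(vals, ["a", "b"], ["s1", "s1"])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(np.ones((2, 2)), ["a"], ["s1", "s2"])


class TestLoadSave:
    def test_csv_round_trip_identity(self, small_matrix, tmp_path):
        p = tmp_path / "m.csv"
        save_matrix(small_matrix, p)
        back = load_matrix(p)
        np.testing.assert_array_equal(back.values, small_matrix.values)
        assert back.gene_ids == small_matrix.gene_ids
        assert back.spot_ids == small_matrix.spot_ids

    def test_tsv_round_trip_identity(self, small_matrix, tmp_path):
        p = tmp_path / "m.tsv"
        save_matrix(small_matrix, p)
        back = load_matrix(p)
        np.testing.assert_array_equal(back.values, small_matrix.values)

    def test_mtx_round_trip(self, small_matrix, tmp_path):
        p = tmp_path / "m.mtx"
        save_matrix(small_matrix, p, genes_path=tmp_path / "g.tsv",
                    spots_path=tmp_path / "s.tsv")
        back = load_matrix(p, genes_path=tmp_path / "g.tsv",
                           spots_path=tmp_path / "s.tsv")
        np.testing.assert_allclose(back.values, small_matrix.values)
        assert back.gene_ids == small_matrix.gene_ids

    def test_empty_csv_cell_loads_as_zero(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,s1,s2\na,1,\nb,,2\n")
        back = load_matrix(p)
        np.testing.assert_array_equal(back.values,
                                      [[1.0, 0.0], [0.0, 2.0]])

    def test_mtx_negative_entry_rejected(self, tmp_path):
        p = tmp_path / "m.mtx"
        p.write_text("%%MatrixMarket matrix coordinate real general\n"
                     "2 2 2\n1 1 1.0\n2 2 -1.0\n")
        (tmp_path / "g.tsv").write_text("a\nb\n")
        (tmp_path / "s.tsv").write_text("s1\ns2\n")
        with pytest.raises(ValueError, match="negative entry"):
            load_matrix(p, genes_path=tmp_path / "g.tsv",
                        spots_path=tmp_path / "s.tsv")

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            load_matrix(tmp_path / "nope.csv")


class TestLogNormalize:
    def test_single_support_column(self):
        Y = ExpressionMatrix(np.array([[5.0, 0.0], [0.0, 3.0]]),
                             ["a", "b"], ["s1", "s2"])
        out = log_normalize(Y, scale=100.0)
        assert out.values[0, 0] == pytest.approx(np.log1p(100.0))
        assert out.values[1, 0] == 0.0
        assert out.is_lognorm

    def test_known_value(self):
        # column [10, 10] at scale 20 -> both entries log1p(10) ~ 2.3979
        Y = ExpressionMatrix(np.array([[10.0], [10.0]]), ["a", "b"], ["s1"])
        out = log_normalize(Y, scale=20.0)
        np.testing.assert_allclose(out.values, np.log1p(10.0), atol=5e-5)
        assert round(float(out.values[0, 0]), 4) == 2.3979

    def test_zeros_stay_zero(self, small_matrix):
        out = log_normalize(small_matrix)
        assert ((small_matrix.values == 0) == (out.values == 0)).all()

    def test_all_zero_column_named_in_error(self):
        Y = ExpressionMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]),
                             ["a", "b"], ["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            log_normalize(Y)

    def test_double_application_rejected(self, small_matrix):
        out = log_normalize(small_matrix)
        with pytest.raises(ValueError):
            log_normalize(out)


class TestFilterGenes:
    @staticmethod
    def _fixture_fractions():
        """6 genes with detection fractions 0, .05, .06, .5, .99, 1 at S=100."""
        S = 100
        vals = np.zeros((6, S))
        for i, n_det in enumerate([0, 5, 6, 50, 99, 100]):
            vals[i, :n_det] = 1.0
        return ExpressionMatrix(vals, [f"g{i}" for i in range(6)],
                                [f"s{j}" for j in range(S)])

    def test_strict_bounds_on_fraction_fixture(self):
        Y = self._fixture_fractions()
        out = filter_genes(Y, 0.05, 1.0)
        # exactly the fractions 0.06, 0.5 and 0.99 survive: both bounds strict
        assert out.gene_ids == ["g2", "g3", "g4"]

    def test_fully_detected_gene_removed(self):
        Y = self._fixture_fractions()
        assert "g5" not in filter_genes(Y, 0.05, 1.0).gene_ids

    def test_idempotent(self):
        Y = self._fixture_fractions()
        once = filter_genes(Y)
        twice = filter_genes(once)
        assert twice.gene_ids == once.gene_ids
        np.testing.assert_array_equal(twice.values, once.values)

    def test_no_survivors_raises(self):
        Y = ExpressionMatrix(np.ones((2, 4)), ["a", "b"],
                             [f"s{j}" for j in range(4)])
        with pytest.raises(ValueError, match="loosen"):
            filter_genes(Y)

    def test_invalid_bounds(self, small_matrix):
        with pytest.raises(ValueError):
            filter_genes(small_matrix, 0.5, 0.5)


class TestRowNormalize:
    def test_proportional_scaling(self):
        Y = ExpressionMatrix(np.array([[2.0, 2.0, 4.0]]), ["a"],
                             ["s1", "s2", "s3"])
        out = row_normalize(Y)
        np.testing.assert_allclose(out.values, [[0.25, 0.25, 0.5]])
        assert out.row_scale[0] == 8.0

    def test_idempotent_on_normalized_rows(self):
        Y = ExpressionMatrix(np.array([[0.25, 0.25, 0.5]]), ["a"],
                             ["s1", "s2", "s3"])
        out = row_normalize(Y)
        np.testing.assert_allclose(out.values, Y.values)
        np.testing.assert_allclose(out.row_scale, [1.0])

    def test_random_matrix_row_sums_and_reconstruction(self, rng):
        vals = rng.random((50, 20)) + 1e-3
        Y = ExpressionMatrix(vals, [f"g{i}" for i in range(50)],
                             [f"s{j}" for j in range(20)])
        out = row_normalize(Y)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-10)
        recon = np.diag(out.row_scale) @ out.values
        np.testing.assert_allclose(recon, vals, rtol=1e-12)

    def test_zero_row_names_gene(self):
        Y = ExpressionMatrix(np.array([[1.0, 1.0], [0.0, 0.0]]),
                             ["a", "bad"], ["s1", "s2"])
        with pytest.raises(ValueError, match="bad"):
            row_normalize(Y)
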