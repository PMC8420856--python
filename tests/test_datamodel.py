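import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from serotensor import (KruskalFactors, factorization_size, fold, khatri_rao,
                        read_serology_tables, reconstruct, unfold)
from serotensor.datamodel import MaskedTensor


class TestUnfold:
    def test_zeros_map_to_zeros(self):
        out = unfold(np.zeros((2, 3, 4)), 1)
        assert out.shape == (3, 8)
        assert not out.any()

    def test_rank1_matches_khatri_rao_column(self):
        a = np.array([1.0, 2.0])
        b = np.array([1.0, 0.0, 1.0])
        c = np.array([1.0, 1.0])
        t = np.einsum("i,j,k->ijk", a, b, c)
        kr = khatri_rao([c[:, None], b[:, None]])
        np.testing.assert_allclose(unfold(t, 0), np.outer(a, kr[:, 0]))

    @pytest.mark.parametrize("mode", [0, 1, 2])
    def test_fold_unfold_roundtrip(self, mode, rng):
        t = rng.standard_normal((3, 4, 5))
        np.testing.assert_array_equal(fold(unfold(t, mode), mode, t.shape), t)

    @given(seed=hst.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_fold_unfold_identity_property(self, seed):
        g = np.random.default_rng(seed)
        shape = tuple(g.integers(1, 6, size=3))
        t = g.standard_normal(shape)
        for mode in range(3):
            np.testing.assert_array_equal(fold(unfold(t, mode), mode, shape), t)

    def test_invalid_mode_raises(self):
        with pytest.raises(ValueError):
            unfold(np.zeros((2, 2, 2)), 3)

    def test_mask_unfolds_identically(self, rng):
        t = rng.standard_normal((3, 4, 5))
        m = rng.random((3, 4, 5)) > 0.5
        out, om = unfold(t, 2, m)
        assert om.shape == out.shape
        np.testing.assert_array_equal(np.where(om, out, 0),
                                      unfold(np.where(m, t, 0), 2))


class TestKhatriRao:
    def test_single_input_unchanged(self, rng):
        a = rng.standard_normal((4, 2))
        np.testing.assert_array_equal(khatri_rao([a]), a)

    def test_one_column_inputs_collapse_to_kron(self):
        u = np.array([[1.0], [2.0]])
        v = np.array([[3.0], [4.0], [5.0]])
        np.testing.assert_allclose(khatri_rao([u, v]),
                                   np.kron(u, v))

    def test_matches_bruteforce_kron_columns(self, rng):
        A = rng.standard_normal((2, 2))
        B = rng.standard_normal((3, 2))
        out = khatri_rao([A, B])
        assert out.shape == (6, 2)
        for r in range(2):
            np.testing.assert_allclose(out[:, r], np.kron(A[:, r], B[:, r]))

    def test_mismatched_columns_raise(self, rng):
        with pytest.raises(ValueError):
            khatri_rao([rng.standard_normal((2, 2)), rng.standard_normal((3, 3))])

    def test_row_count_is_product(self, rng):
        mats = [rng.standard_normal((n, 3)) for n in (2, 3, 4)]
        assert khatri_rao(mats).shape == (24, 3)


class TestReconstruct:
    def test_empty_factors_give_zero(self):
        f = KruskalFactors(np.zeros((3, 0)), np.zeros((4, 0)), np.zeros((5, 0)))
        x, y = reconstruct(f)
        assert not x.any() and y is None

    def test_single_rank1_entry(self):
        f = KruskalFactors(np.array([[1.0], [2.0]]),
                           np.array([[1.0], [1.0]]),
                           np.array([[3.0], [0.0]]))
        x, _ = reconstruct(f)
        assert x[1, 0, 0] == pytest.approx(6.0)

    def test_matches_bruteforce_triple_sum(self, rng):
        R = 3
        A, B, C, D = (rng.standard_normal((n, R)) for n in (4, 5, 5, 3))
        f = KruskalFactors(A, B, C, D)
        x, y = reconstruct(f)
        expect = np.zeros((4, 5, 5))
        for r in range(R):
            for i in range(4):
                for j in range(5):
                    for k in range(5):
                        expect[i, j, k] += A[i, r] * B[j, r] * C[k, r]
        np.testing.assert_allclose(x, expect, atol=1e-10)
        np.testing.assert_allclose(y, sum(np.outer(A[:, r], D[:, r])
                                          for r in range(R)), atol=1e-10)


@pytest.mark.parametrize("sizes,R,expected", [
    ((181, 22, 39, 25), 6, 1602),
    ((438, 6, 11), 2, 910),
    ((10, 4, 5), 0, 0),
])
def test_factorization_size(rng, sizes, R, expected):
    mats = [rng.standard_normal((n, R)) for n in sizes]
    f = KruskalFactors(*mats[:3], mats[3] if len(sizes) == 4 else None)
    assert factorization_size(f) == expected


class TestReadSerologyTables:
    def _write(self, tmp_path, rows, name="long.csv",
               header="subject,receptor,antigen,value"):
        p = tmp_path / name
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def _full_rows(self):
        return [f"s{i},r{j},g{k},{i + 10 * j + 100 * k}"
                for i in range(2) for j in range(2) for k in range(2)]

    def test_full_long_table(self, tmp_path):
        p = self._write(tmp_path, self._full_rows())
        d, _ = read_serology_tables(p, min_receptors=1)
        assert d.tensor.shape == (2, 2, 2)
        assert d.tensor.mask.all()
        assert d.tensor.values[1, 0, 1] == pytest.approx(101.0)

    def test_missing_fiber_masks_it(self, tmp_path):
        rows = [r for r in self._full_rows() if not r.startswith("s0,r1,g1")
                and not r.startswith("s1,r1,g1")]
        p = self._write(tmp_path, rows)
        d, _ = read_serology_tables(p, min_receptors=1)
        assert not d.tensor.mask[:, 1, 1].any()
        assert d.tensor.mask.sum() == 6

    def test_sparse_antigen_removed(self, tmp_path):
        # antigen "rare" measured with only 2 of 3 receptors
        rows = [f"s{i},r{j},common,{1 + i + j}" for i in range(2) for j in range(3)]
        rows += [f"s{i},r{j},rare,{5 + i + j}" for i in range(2) for j in range(2)]
        p = self._write(tmp_path, rows)
        d, _ = read_serology_tables(p)
        assert d.tensor.antigen_ids == ["common"]
        assert d.provenance[0]["dropped_antigens"] == ["rare"]

    def test_duplicate_triple_raises(self, tmp_path):
        rows = self._full_rows() + ["s0,r0,g0,99"]
        p = self._write(tmp_path, rows)
        with pytest.raises(ValueError, match="duplicate"):
            read_serology_tables(p, min_receptors=1)

    def test_non_numeric_value_raises(self, tmp_path):
        rows = self._full_rows()
        rows[3] = "s0,r1,g1,oops"
        p = self._write(tmp_path, rows)
        with pytest.raises(ValueError, match="non-numeric"):
            read_serology_tables(p, min_receptors=1)

    def test_row_order_invariance(self, tmp_path, rng):
        rows = self._full_rows()
        p1 = self._write(tmp_path, rows, "a.csv")
        p2 = self._write(tmp_path, [rows[i] for i in rng.permutation(len(rows))],
                         "b.csv")
        d1, _ = read_serology_tables(p1, min_receptors=1)
        d2, _ = read_serology_tables(p2, min_receptors=1)
        np.testing.assert_array_equal(d1.tensor.values, d2.tensor.values)
        assert d1.tensor.subject_ids == d2.tensor.subject_ids

    def test_wide_format_splits_on_first_dot(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("subject,FcgRIIa.H131.gp120,FcgRIIa.H131.p24\n"
                     "s0,1.5,2.5\ns1,3.5,4.5\n")
        d, _ = read_serology_tables(p, wide=True, split_first=False,
                                    min_receptors=1)
        assert d.tensor.receptor_ids == ["FcgRIIa.H131"]
        assert sorted(d.tensor.antigen_ids) == ["gp120", "p24"]

    def test_coupled_table_aligns_subjects(self, tmp_path):
        p = self._write(tmp_path, self._full_rows())
        g = tmp_path / "glycans.csv"
        g.write_text("subject,feature,value\ns0,G1F,1.0\ns2,G1F,2.0\n")
        d, _ = read_serology_tables(p, g, min_receptors=1)
        # s2 only in glycan table: fully-unobserved tensor rows
        assert d.tensor.subject_ids == ["s0", "s1", "s2"]
        assert not d.tensor.mask[2].any()
        assert d.matrix.mask[0, 0] and not d.matrix.mask[1, 0]


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        MaskedTensor(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool),
                     ["a", "a"], ["r1", "r2"], ["g1", "g2"])
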